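"""Multi-predictor models of minimum development time.

The response is ln minimum development time; predictors are ln dry mass,
optimal developmental temperature (T_opt), taxonomic order, and their
interactions. The full-factorial model is fit by OLS or PGLS, nonsignificant
interactions are removed backward (highest interaction order first, partial
F-tests against the nested model), variance is apportioned by sequential
(Type-I) sums of squares, and the final model is used to predict development
time for a standardized 1 mg insect at chosen T_opt values.

Categorical coding is treatment contrasts with the alphabetically first
order as reference, so raw order coefficients are coding-dependent;
F-tests, partial R^2 and predictions are coding-invariant and are what
downstream checks rely on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrices
from scipy import stats

from . import phylogls
from .allofit import RegressionFit, sma_fit
from .datamodel import reconcile_tree

__all__ = [
    "AnovaRow",
    "EliminationStep",
    "FactorialFit",
    "FULL_TERMS",
    "PGLS_TERMS",
    "fit_factorial",
    "backward_eliminate",
    "sequential_partial_r2",
    "predict_standardized",
    "binned_sma",
    "covariate_independence_check",
    "subset_min_species",
]

#: entry order of the full-factorial OLS model
FULL_TERMS = [
    "ln_mass",
    "t_opt",
    "order",
    "ln_mass:t_opt",
    "ln_mass:order",
    "t_opt:order",
    "ln_mass:t_opt:order",
]

#: the PGLS factorial excludes the t_opt:order interaction (and with it the
#: three-way, by marginality) because it is singular against the
#: phylogenetic structure — order membership is itself a clade effect.
PGLS_TERMS = ["ln_mass", "t_opt", "order", "ln_mass:t_opt", "ln_mass:order"]


@dataclass(frozen=True)
class AnovaRow:
    term: str
    ss: float
    df1: int
    df2: int
    F: float
    p: float
    partial_r2: float | None = None


@dataclass(frozen=True)
class EliminationStep:
    term: str
    F: float
    df1: int
    df2: int
    p: float
    dropped: bool


@dataclass
class FactorialFit:
    """A fitted factorial model plus everything needed to refit nested versions."""

    estimator: str  # "OLS" | "PGLS"
    terms: list[str]
    fit: phylogls.GLSFit
    design_info: object
    table: pd.DataFrame
    V: np.ndarray | None  # None means identity (OLS)
    structure: phylogls.CorrelationStructure | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.fit.n

    @property
    def r2(self) -> float:
        """Classical R^2 on the whitened scale (1 - RSS/SST of the null fit)."""
        sst = _null_rss(self.table, self.V)
        return 1.0 - self.fit.rss_whitened / sst


def _check_marginality(terms: list[str]) -> None:
    present = set(terms)
    for term in terms:
        factors = term.split(":")
        if len(factors) < 2:
            continue
        for k in range(1, len(factors)):
            for sub in itertools.combinations(factors, k):
                if ":".join(sub) not in present:
                    raise ValueError(
                        f"term {term!r} present without its constituent "
                        f"{':'.join(sub)!r} (marginality violation)"
                    )


def _patsy_term(term: str) -> str:
    return ":".join("C(order)" if f == "order" else f for f in term.split(":"))


def _formula(response: str, terms: list[str]) -> str:
    rhs = " + ".join(_patsy_term(t) for t in terms) if terms else "1"
    return f"{response} ~ {rhs}"


def _design(table: pd.DataFrame, terms: list[str], response: str = "ln_tdev"):
    y_mat, X_mat = dmatrices(_formula(response, terms), table, return_type="dataframe")
    return (
        np.asarray(y_mat).ravel(),
        np.asarray(X_mat),
        list(X_mat.columns),
        X_mat.design_info,
    )


def _fit_terms(
    table: pd.DataFrame,
    terms: list[str],
    V: np.ndarray | None,
    response: str = "ln_tdev",
) -> phylogls.GLSFit:
    y, X, names, _ = _design(table, terms, response)
    Vm = np.eye(len(y)) if V is None else V
    return phylogls.gls_fit(X, y, Vm, names, drop_aliased=True)


def _null_rss(table: pd.DataFrame, V: np.ndarray | None, response: str = "ln_tdev") -> float:
    return _fit_terms(table, [], V, response).rss_whitened


def _tree_matrix(table: pd.DataFrame, tree, structure) -> np.ndarray:
    """Correlation/covariance matrix for the table's species, in row order."""
    mapping = reconcile_tree(tree, list(table["species"]))
    labels = [mapping[s] for s in table["species"]]
    V, _ = phylogls.structure_matrix(tree, structure, labels, corr_form=True)
    return V


def fit_factorial(
    table: pd.DataFrame,
    terms: list[str] | None = None,
    estimator: str = "OLS",
    tree=None,
    structure: phylogls.CorrelationStructure | None = None,
    alpha_bounds: tuple[float, float] = (1e-3, 1e3),
) -> FactorialFit:
    """Fit the factorial model of ln T_dev on mass, T_opt and order.

    For PGLS a tree is required; if no structure is given, all four
    candidate evolutionary models are fit to this design and the lowest-AIC
    one is kept. A single-order table silently cannot support order terms:
    they are dropped with a note and the model reduces to mass x T_opt.
    """
    notes: list[str] = []
    if terms is None:
        terms = list(PGLS_TERMS if estimator == "PGLS" else FULL_TERMS)
    terms = list(terms)
    if table["order"].nunique() < 2 and any("order" in t.split(":") for t in terms):
        terms = [t for t in terms if "order" not in t.split(":")]
        notes.append("single order present; order terms dropped")
    _check_marginality(terms)

    if estimator == "OLS":
        fit = _fit_terms(table, terms, None)
        return FactorialFit("OLS", terms, fit, _design(table, terms)[3], table, None, None, notes)
    if estimator != "PGLS":
        raise ValueError(f"unknown estimator {estimator!r}")
    if tree is None:
        raise ValueError("PGLS requires a tree")

    y, X, names, dinfo = _design(table, terms)
    mapping = reconcile_tree(tree, list(table["species"]))
    labels = [mapping[s] for s in table["species"]]
    if structure is None:
        candidates = phylogls.fit_candidates(
            tree, X, y, names, labels, alpha_bounds, drop_aliased=True
        )
        best = phylogls.select_structure(candidates)
        structure = best.structure
        notes.append(f"structure selected by AIC: {structure.label()}")
    V, _ = phylogls.structure_matrix(tree, structure, labels, corr_form=True)
    fit = phylogls.gls_fit(
        X, y, V, names, structure,
        alpha_estimated=structure.kind == "OU", drop_aliased=True,
    )
    return FactorialFit("PGLS", terms, fit, dinfo, table, V, structure, notes)


def _term_f_test(ffit: FactorialFit, term: str) -> AnovaRow:
    """Partial F-test for dropping ``term`` from the fitted model."""
    reduced_terms = [t for t in ffit.terms if t != term]
    full = ffit.fit
    reduced = _fit_terms(ffit.table, reduced_terms, ffit.V)
    df1 = (reduced.df_resid) - (full.df_resid)
    df2 = full.df_resid
    ss = reduced.rss_whitened - full.rss_whitened
    F = (ss / df1) / (full.rss_whitened / df2)
    p = float(stats.f.sf(F, df1, df2))
    return AnovaRow(term=term, ss=ss, df1=df1, df2=df2, F=float(F), p=p)


def _removable(terms: list[str]) -> list[str]:
    """Interactions not contained in any higher-order interaction still present."""
    out = []
    for t in terms:
        factors = set(t.split(":"))
        if len(factors) < 2:
            continue
        contained = any(
            t != other and factors < set(other.split(":")) for other in terms
        )
        if not contained:
            out.append(t)
    return out


def backward_eliminate(
    ffit: FactorialFit, alpha: float = 0.05
) -> tuple[FactorialFit, list[EliminationStep]]:
    """Remove nonsignificant interactions to reach the final model.

    At each step the highest-order removable interactions are tested by
    partial F against the nested model; the one with the largest p > alpha
    is dropped and the model refit. Main effects are never dropped, and
    marginality is preserved (an interaction is only removable once no
    higher-order interaction contains it).
    """
    log: list[EliminationStep] = []
    current = ffit
    while True:
        removable = _removable(current.terms)
        if not removable:
            break
        max_order = max(len(t.split(":")) for t in removable)
        candidates = [t for t in removable if len(t.split(":")) == max_order]
        rows = [_term_f_test(current, t) for t in candidates]
        rows.sort(key=lambda r: -r.p)
        worst = rows[0]
        if worst.p > alpha:
            log.append(
                EliminationStep(worst.term, worst.F, worst.df1, worst.df2, worst.p, True)
            )
            new_terms = [t for t in current.terms if t != worst.term]
            if current.V is None:
                current = fit_factorial(current.table, new_terms, estimator="OLS")
            else:
                current = _refit_pgls(current, new_terms)
        else:
            # highest-order interactions all significant: record and stop at
            # this order (lower orders are protected by marginality)
            for row in rows:
                log.append(
                    EliminationStep(row.term, row.F, row.df1, row.df2, row.p, False)
                )
            break
    return current, log


def _refit_pgls(ffit: FactorialFit, terms: list[str]) -> FactorialFit:
    y, X, names, dinfo = _design(ffit.table, terms)
    fit = phylogls.gls_fit(
        X, y, ffit.V, names, ffit.structure,
        alpha_estimated=bool(ffit.structure and ffit.structure.kind == "OU"),
        drop_aliased=True,
    )
    return FactorialFit(
        "PGLS", terms, fit, dinfo, ffit.table, ffit.V, ffit.structure, list(ffit.notes)
    )


def sequential_partial_r2(ffit: FactorialFit) -> list[AnovaRow]:
    """Sequential (Type-I) ANOVA with each term's share of the total SS.

    Terms enter in the model's stated order; each row's partial R^2 is its
    sequential SS over the total (null-model) SS, so the rows sum exactly to
    the model R^2. Available for OLS only — a sequential SS decomposition of
    a PGLS fit has no agreed-upon definition here.
    """
    if ffit.estimator != "OLS":
        raise ValueError("sequential partial R^2 is only supported for OLS fits")
    table, V = ffit.table, ffit.V
    sst = _null_rss(table, V)
    full = ffit.fit
    rows: list[AnovaRow] = []
    prev_rss = sst
    prev_df = full.n - 1
    for i, term in enumerate(ffit.terms):
        fit_i = _fit_terms(table, ffit.terms[: i + 1], V)
        ss = prev_rss - fit_i.rss_whitened
        df1 = prev_df - fit_i.df_resid
        F = (ss / df1) / (full.rss_whitened / full.df_resid)
        p = float(stats.f.sf(F, df1, full.df_resid))
        rows.append(
            AnovaRow(term, float(ss), df1, full.df_resid, float(F), p, float(ss / sst))
        )
        prev_rss, prev_df = fit_i.rss_whitened, fit_i.df_resid
    return rows


def predict_standardized(
    ffit: FactorialFit,
    orders: list[str] | None = None,
    t_opt_values: tuple[float, ...] = (25.0, 35.0),
    mass_mg: float = 1.0,
    confidence: float = 0.95,
    min_n: int = 10,
) -> pd.DataFrame:
    """Predict ln development time for a standardized insect of ``mass_mg``.

    Defaults reproduce the study's visualization: a 1 mg insect (ln mass 0,
    so all mass terms vanish) at T_opt 25 and 35 C, for orders with at least
    ``min_n`` species. Returns mean prediction, delta-rule SE, and CI.
    """
    if orders is None:
        counts = ffit.table["order"].value_counts()
        orders = sorted(counts[counts >= min_n].index)
    known = set(ffit.table["order"])
    skipped = [o for o in orders if o not in known]
    orders = [o for o in orders if o in known]
    new = pd.DataFrame(
        [
            {"ln_mass": np.log(mass_mg), "t_opt": t, "order": o}
            for o in orders
            for t in t_opt_values
        ]
    )
    (X_new,) = build_design_matrices([ffit.design_info], new, return_type="dataframe")
    # keep only columns the fit retained (aliased columns may have dropped)
    X_new = np.asarray(X_new[ffit.fit.names])
    beta, cov = ffit.fit.coefficients, ffit.fit.coef_cov
    pred = X_new @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X_new, cov, X_new))
    tq = stats.t.ppf(0.5 + confidence / 2, df=ffit.fit.df_resid)
    out = new.copy()
    out["ln_tdev_pred"] = pred
    out["se"] = se
    out["ci_low"] = pred - tq * se
    out["ci_high"] = pred + tq * se
    out.attrs["skipped_orders"] = skipped
    return out


def binned_sma(
    table: pd.DataFrame,
    bin_edges: tuple[float, ...] = (28.0, 30.0, 33.0),
    robust: bool = False,
    confidence: float = 0.95,
    min_n: int = 3,
) -> dict[str, RegressionFit | None]:
    """SMA fits of ln T_dev on ln mass within T_opt bins.

    Bins are lower-closed: with the default edges they are (-inf, 28),
    [28, 30), [30, 33), [33, inf). Bins with fewer than ``min_n`` species
    are reported as None rather than fitted.
    """
    edges = sorted(bin_edges)
    labels = [f"<{edges[0]:g}"]
    labels += [f"[{a:g},{b:g})" for a, b in zip(edges[:-1], edges[1:])]
    labels += [f">={edges[-1]:g}"]
    idx = np.digitize(table["t_opt"].to_numpy(), edges, right=False)
    out: dict[str, RegressionFit | None] = {}
    for k, label in enumerate(labels):
        sub = table[idx == k]
        if len(sub) < min_n:
            out[label] = None
            continue
        out[label] = sma_fit(
            sub["ln_mass"], sub["ln_tdev"], robust=robust, confidence=confidence
        )
    return out


def covariate_independence_check(
    table: pd.DataFrame, include_order: bool = True
) -> AnovaRow:
    """Test whether T_opt covaries with ln mass (it should not, for the
    mass x T_opt interaction to be interpretable).

    Regresses T_opt on ln mass (plus order, absorbing clade-level T_opt
    differences) and reports the partial F for the mass term.
    """
    terms = ["ln_mass", "order"] if include_order and table["order"].nunique() > 1 else ["ln_mass"]
    full = _fit_terms(table, terms, None, response="t_opt")
    reduced = _fit_terms(table, [t for t in terms if t != "ln_mass"], None, response="t_opt")
    df1 = reduced.df_resid - full.df_resid
    df2 = full.df_resid
    ss = reduced.rss_whitened - full.rss_whitened
    F = (ss / df1) / (full.rss_whitened / df2)
    return AnovaRow("ln_mass", float(ss), df1, df2, float(F), float(stats.f.sf(F, df1, df2)))


def subset_min_species(table: pd.DataFrame, min_n: int = 10) -> pd.DataFrame:
    """Keep only species whose order has at least ``min_n`` species."""
    counts = table["order"].value_counts()
    keep = counts[counts >= min_n].index
    out = table[table["order"].isin(keep)].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"no order has >= {min_n} species")
    return out
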