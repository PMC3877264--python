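"""Phylogenetic generalized least squares with evolutionary-model selection.

Species are non-independent: residual covariance is induced by the phylogeny
under a model of trait evolution. Four candidate structures are compared —
{Brownian motion, Ornstein-Uhlenbeck} crossed with branch lengths {all equal
to one, Grafen's transformation} — and the winner is the lowest AIC.

* BM covariance: V[i, j] = shared root-path length to the MRCA of tips i, j.
* OU correlation (Martins-Hansen form): C[i, j] = exp(-alpha * d_ij) with
  d_ij the patristic distance; the diagonal is exactly 1. This is a valid
  correlation matrix on non-ultrametric trees (the unit-branch convention
  produces one), which is why the correlation form is used rather than the
  nonstationary OU covariance.
* alpha is optimized by restricted maximum likelihood (bounded search on
  ln alpha).

Estimation whitens through the Cholesky factor of V (never an explicit
inverse); the AIC is computed from the ML log-likelihood with the parameter
count including sigma^2 and, when estimated, alpha, so model comparisons
should be read by rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "CorrelationStructure",
    "GLSFit",
    "unit_branches",
    "grafen_transform",
    "tip_labels",
    "bm_covariance",
    "patristic_matrix",
    "ou_correlation",
    "structure_matrix",
    "gls_fit",
    "reml_loglik",
    "optimize_alpha_reml",
    "fit_candidates",
    "select_structure",
    "pgls_r2",
    "design_with_intercept",
]


@dataclass(frozen=True)
class CorrelationStructure:
    """One candidate evolutionary model: BM or OU(alpha) on transformed branches."""

    kind: str  # "BM" | "OU"
    transform: str  # "unit_branches" | "grafen"
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("BM", "OU"):
            raise ValueError(f"kind must be BM or OU, got {self.kind!r}")
        if self.transform not in ("unit_branches", "grafen", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.kind == "OU" and self.alpha is not None and not (self.alpha > 0):
            raise ValueError(f"OU alpha must be > 0, got {self.alpha}")

    def label(self) -> str:
        a = f", alpha={self.alpha:.4g}" if self.alpha is not None else ""
        return f"{self.kind}({self.transform}{a})"


@dataclass
class GLSFit:
    """A fitted GLS model with ML/REML likelihoods and AIC.

    ``sigma2`` is the REML (unbiased) residual variance on the whitened
    scale; ``coef_cov`` uses it. ``aic`` is ``-2*loglik_ml + 2k`` with
    k = #coefficients + 1 (sigma^2) + 1 if alpha was estimated.
    """

    names: list[str]
    coefficients: np.ndarray
    coef_cov: np.ndarray
    sigma2: float
    loglik_ml: float
    loglik_reml: float
    aic: float
    structure: CorrelationStructure | None
    n: int
    df_resid: int
    rss_whitened: float
    tss_whitened: float
    dropped_names: list[str] = field(default_factory=list)
    alpha_estimated: bool = False
    alpha_bound_warning: bool = False
    r2_lr: float | None = None
    data_key: tuple = field(default_factory=tuple)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        se = np.sqrt(np.diag(self.coef_cov))
        tq = stats.t.ppf(0.5 + level / 2, df=self.df_resid)
        return np.column_stack(
            [self.coefficients - tq * se, self.coefficients + tq * se]
        )

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])


# ---------------------------------------------------------------------------
# Branch-length transforms
# ---------------------------------------------------------------------------


def unit_branches(tree: dendropy.Tree) -> dendropy.Tree:
    """Clone the tree with every branch length set to 1 (the study convention
    when comparable branch lengths are unavailable)."""
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.head_node is out.seed_node:
            edge.length = None
        else:
            edge.length = 1.0
    return out


def grafen_transform(tree: dendropy.Tree, rho: float = 1.0) -> dendropy.Tree:
    """Grafen's branch lengths: node height ((#descendant tips - 1)/(N - 1))^rho.

    Tips sit at height 0 and the root at height 1; each branch is the parent
    height minus the child height, so all branches are nonnegative and every
    root-to-tip path has length exactly 1.
    """
    if tree.seed_node is None:
        raise ValueError("tree must be rooted")
    out = tree.clone(depth=1)
    n_tips = len(out.leaf_nodes())
    if n_tips < 2:
        raise ValueError("Grafen transform needs >= 2 tips")
    heights: dict = {}
    for node in out.postorder_node_iter():
        k = len(node.leaf_nodes()) if not node.is_leaf() else 1
        heights[node] = ((k - 1) / (n_tips - 1)) ** rho
    for node in out.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = heights[node.parent_node] - heights[node]
    return out


def _apply_transform(tree: dendropy.Tree, transform: str) -> dendropy.Tree:
    if transform == "unit_branches":
        return unit_branches(tree)
    if transform == "grafen":
        return grafen_transform(tree)
    if transform == "none":
        return tree
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# Covariance / correlation construction (polytomies handled natively)
# ---------------------------------------------------------------------------


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _leaf_index(tree: dendropy.Tree, labels: list[str] | None) -> dict[str, int]:
    present = tip_labels(tree)
    if labels is None:
        labels = present
    missing = set(labels) - set(present)
    if missing:
        raise KeyError(f"labels not in tree: {sorted(missing)}")
    return {lab: i for i, lab in enumerate(labels)}


def bm_covariance(
    tree: dendropy.Tree, labels: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance: shared root-path length to the MRCA.

    ``V[i, i]`` is the root-to-tip distance. Branch lengths must be present
    and nonnegative (apply a transform first if the input tree lacks them).
    """
    index = _leaf_index(tree, labels)
    labels_out = sorted(index, key=index.get)
    n = len(labels_out)
    V = np.zeros((n, n))
    depth: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        elen = node.edge.length
        if parent is None:
            depth[node] = 0.0
            continue
        if elen is None:
            raise ValueError(
                "tree has missing branch lengths; apply unit_branches or "
                "grafen_transform first"
            )
        if elen < 0:
            raise ValueError(f"negative branch length {elen}")
        depth[node] = depth[parent] + elen
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            idx = [index[lab]] if lab in index else []
            if idx:
                V[idx[0], idx[0]] = depth[node]
            tipsets[node] = idx
        else:
            groups = [tipsets[c] for c in node.child_nodes()]
            d = depth[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    if groups[a] and groups[b]:
                        ia = np.asarray(groups[a])
                        ib = np.asarray(groups[b])
                        V[np.ix_(ia, ib)] = d
                        V[np.ix_(ib, ia)] = d
            tipsets[node] = [i for g in groups for i in g]
    return V, labels_out


def patristic_matrix(
    tree: dendropy.Tree, labels: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Tip-to-tip path-length matrix, from the BM covariance identity
    d_ij = V_ii + V_jj - 2 V_ij."""
    V, labels_out = bm_covariance(tree, labels)
    diag = np.diag(V)
    D = diag[:, None] + diag[None, :] - 2 * V
    np.fill_diagonal(D, 0.0)
    return D, labels_out


def ou_correlation(
    tree: dendropy.Tree, alpha: float, labels: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Ornstein-Uhlenbeck correlation exp(-alpha * d_ij); diagonal exactly 1."""
    if not (alpha > 0):
        raise ValueError(f"alpha must be > 0, got {alpha}")
    D, labels_out = patristic_matrix(tree, labels)
    C = np.exp(-alpha * D)
    np.fill_diagonal(C, 1.0)
    return C, labels_out


def cov2corr(V: np.ndarray) -> np.ndarray:
    """Normalize a covariance matrix to a correlation matrix."""
    d = np.sqrt(np.diag(V))
    if np.any(d <= 0):
        raise ValueError("covariance has nonpositive diagonal")
    C = V / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def structure_matrix(
    tree: dendropy.Tree,
    structure: CorrelationStructure,
    labels: list[str] | None = None,
    corr_form: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Build the species covariance/correlation matrix for one candidate structure.

    ``corr_form=True`` normalizes the BM covariance to a correlation matrix.
    On non-ultrametric trees (the unit-branch convention makes tip depths
    unequal) this is what standard mixed-model GLS machinery fits — the
    structure carries correlation only, with a single sigma^2 — and it is the
    form used for candidate comparison. OU is a correlation already.
    """
    transformed = _apply_transform(tree, structure.transform)
    if structure.kind == "BM":
        V, labels_out = bm_covariance(transformed, labels)
        return (cov2corr(V) if corr_form else V), labels_out
    if structure.alpha is None:
        raise ValueError("OU structure requires alpha (optimize it first)")
    return ou_correlation(transformed, structure.alpha, labels)


# ---------------------------------------------------------------------------
# GLS estimation
# ---------------------------------------------------------------------------


def _chol_with_jitter(V: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-8 * float(np.mean(np.diag(V)))
        try:
            return linalg.cholesky(V + jitter * np.eye(V.shape[0]), lower=True)
        except linalg.LinAlgError as exc:
            eigmin = float(np.min(np.linalg.eigvalsh(V)))
            raise np.linalg.LinAlgError(
                f"V is not positive definite (min eigenvalue {eigmin:.3e}, "
                f"jitter {jitter:.1e} insufficient)"
            ) from exc


def design_with_intercept(x) -> tuple[np.ndarray, list[str]]:
    """[1, x] design for the bivariate allometric PGLS."""
    x = np.asarray(x, dtype=float)
    return np.column_stack([np.ones_like(x), x]), ["intercept", "slope"]


def _whiten(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    L = _chol_with_jitter(V)
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    return Xw, yw, logdet_V, L


def gls_fit(
    X: np.ndarray,
    y: np.ndarray,
    V: np.ndarray,
    names: list[str] | None = None,
    structure: CorrelationStructure | None = None,
    alpha_estimated: bool = False,
    drop_aliased: bool = False,
) -> GLSFit:
    """Generalized least squares by Cholesky whitening.

    beta-hat = (X' V^-1 X)^-1 X' V^-1 y, computed as OLS on the whitened
    system L^-1 X, L^-1 y with V = L L'. Both the ML log-likelihood
    (sigma^2 profiled) and the REML log-likelihood (residual contrast space)
    are returned; coefficient covariance uses the REML sigma^2.

    A rank-deficient design raises, listing the aliased columns — unless
    ``drop_aliased=True``, which removes them and records their names
    (the convention of standard linear-model tooling for factorial designs
    with sparse cells, e.g. single-species orders).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n or V.shape != (n, n):
        raise ValueError("X, y, V dimensions disagree")
    colnames = list(names) if names else [f"x{i}" for i in range(p)]
    Xw, yw, logdet_V, _ = _whiten(X, y, V)
    dropped_names: list[str] = []
    rank = np.linalg.matrix_rank(Xw)
    if rank < p:
        # identify aliased columns via pivoted QR
        _, R, piv = linalg.qr(Xw, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(Xw.shape) * np.finfo(float).eps * diag.max()
        bad = sorted(int(i) for i in piv[np.flatnonzero(diag < tol)])
        # pivoted-QR diag can understate rank loss; keep dropping until clean
        keep = [i for i in range(p) if i not in bad]
        while np.linalg.matrix_rank(Xw[:, keep]) < len(keep):
            _, R2, piv2 = linalg.qr(Xw[:, keep], mode="economic", pivoting=True)
            d2 = np.abs(np.diag(R2))
            worst = keep[int(piv2[int(np.argmin(d2))])]
            bad.append(worst)
            keep = [i for i in range(p) if i not in bad]
        if not drop_aliased:
            raise np.linalg.LinAlgError(
                "design is rank deficient; aliased columns: "
                f"{[colnames[i] for i in bad]}"
            )
        dropped_names = [colnames[i] for i in bad]
        colnames = [colnames[i] for i in keep]
        X = X[:, keep]
        Xw = Xw[:, keep]
        p = len(keep)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((yw - np.mean(yw)) ** 2))
    sigma2_ml = rss / n
    loglik_ml = -0.5 * (n * math.log(2 * math.pi * max(sigma2_ml, 1e-300)) + n + logdet_V)
    df = n - p
    sigma2_reml = rss / df if df > 0 else float("nan")
    XtX = Xw.T @ Xw
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    loglik_reml = -0.5 * (
        df * math.log(2 * math.pi * max(sigma2_reml, 1e-300))
        + df
        + logdet_V
        + logdet_XtX
    )
    coef_cov = sigma2_reml * np.linalg.inv(XtX)
    k = p + 1 + (1 if alpha_estimated else 0)
    aic = -2 * loglik_ml + 2 * k
    return GLSFit(
        names=colnames,
        coefficients=beta,
        coef_cov=coef_cov,
        sigma2=sigma2_reml,
        loglik_ml=loglik_ml,
        loglik_reml=loglik_reml,
        aic=aic,
        structure=structure,
        n=n,
        df_resid=df,
        rss_whitened=rss,
        tss_whitened=tss,
        dropped_names=dropped_names,
        alpha_estimated=alpha_estimated,
        data_key=(n, float(np.sum(y)), float(np.sum(y * y))),
    )


def reml_loglik(X: np.ndarray, y: np.ndarray, V: np.ndarray) -> float:
    """REML log-likelihood of (X, y) under covariance sigma^2 * V (sigma^2 profiled).

    Aliased design columns are dropped (they carry no information about the
    residual contrast space).
    """
    return gls_fit(X, y, V, drop_aliased=True).loglik_reml


def optimize_alpha_reml(
    tree: dendropy.Tree,
    X: np.ndarray,
    y: np.ndarray,
    bounds: tuple[float, float] = (1e-3, 1e3),
    transform: str = "unit_branches",
    labels: list[str] | None = None,
) -> tuple[float, float, bool]:
    """Maximize the REML log-likelihood over the OU constraint strength alpha.

    One-dimensional search on ln(alpha): a coarse grid scan locates the
    global basin (the REML surface can carry a second, spurious plateau at
    the independence limit alpha -> infinity), then a bounded optimizer
    refines within the bracketing grid cell. Returns
    ``(alpha, reml_loglik, bound_hit)``; a True ``bound_hit`` flags an
    optimum pinned at a bound (possible BM limit as alpha -> 0, or a
    star-tree / independence limit as alpha -> infinity).
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError(f"bounds must satisfy 0 < lo < hi, got {bounds}")
    transformed = _apply_transform(tree, transform)
    D, _ = patristic_matrix(transformed, labels)

    def neg_reml(log_alpha: float) -> float:
        C = np.exp(-math.exp(log_alpha) * D)
        np.fill_diagonal(C, 1.0)
        return -reml_loglik(X, y, C)

    grid = np.linspace(math.log(lo), math.log(hi), 40)
    values = np.array([neg_reml(g) for g in grid])
    best = int(np.argmin(values))
    blo = grid[max(best - 1, 0)]
    bhi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        neg_reml,
        bounds=(blo, bhi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    alpha = math.exp(res.x)
    # degeneracy warning: optimum pinned at a bound, or a surface so flat
    # that alpha is unidentifiable (e.g. a star tree, where the intercept
    # absorbs the equicorrelation and REML is constant in alpha)
    flat = float(values.max() - values.min()) < 1e-6 * max(1.0, abs(float(res.fun)))
    bound_hit = bool(
        flat or res.x - math.log(lo) < 1e-3 or math.log(hi) - res.x < 1e-3
    )
    return alpha, -res.fun, bound_hit


#: candidate order used for AIC ties: the study's four evolutionary models
CANDIDATE_STRUCTURES = [
    ("BM", "unit_branches"),
    ("OU", "unit_branches"),
    ("BM", "grafen"),
    ("OU", "grafen"),
]


def fit_candidates(
    tree: dendropy.Tree,
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    labels: list[str] | None = None,
    alpha_bounds: tuple[float, float] = (1e-3, 1e3),
    drop_aliased: bool = False,
) -> list[GLSFit]:
    """Fit all four candidate structures ({BM, OU} x {unit, Grafen}) to (X, y).

    OU alpha is REML-optimized per transform before the final fit.
    """
    fits = []
    for kind, transform in CANDIDATE_STRUCTURES:
        if kind == "BM":
            structure = CorrelationStructure("BM", transform)
            V, _ = structure_matrix(tree, structure, labels, corr_form=True)
            fits.append(
                gls_fit(X, y, V, names, structure, alpha_estimated=False,
                        drop_aliased=drop_aliased)
            )
        else:
            alpha, _, bound_hit = optimize_alpha_reml(
                tree, X, y, alpha_bounds, transform, labels
            )
            structure = CorrelationStructure("OU", transform, alpha=alpha)
            V, _ = structure_matrix(tree, structure, labels)
            fit = gls_fit(X, y, V, names, structure, alpha_estimated=True,
                          drop_aliased=drop_aliased)
            fit.alpha_bound_warning = bound_hit
            fits.append(fit)
    return fits


def select_structure(candidates: list[GLSFit]) -> GLSFit:
    """Choose the candidate with the lowest AIC; ties go to list order."""
    if not candidates:
        raise ValueError("no candidates")
    key = candidates[0].data_key
    for c in candidates[1:]:
        if c.data_key != key:
            raise ValueError("candidates were fit to differing data")
    best = min(candidates, key=lambda f: f.aic)
    return best


def pgls_r2(fit: GLSFit, null_fit: GLSFit) -> float:
    """Likelihood-ratio R^2 for PGLS: 1 - exp(-2 (lnL_full - lnL_null)/n).

    ``null_fit`` must be the intercept-only model under the same correlation
    structure and data.
    """
    if fit.data_key != null_fit.data_key:
        raise ValueError("full and null fits use different data")
    fs, ns = fit.structure, null_fit.structure
    if (fs is None) != (ns is None) or (
        fs is not None
        and (fs.kind != ns.kind or fs.transform != ns.transform)
    ):
        raise ValueError("full and null fits use different correlation structures")
    r2 = 1.0 - math.exp(-2.0 * (fit.loglik_ml - null_fit.loglik_ml) / fit.n)
    return float(np.clip(r2, 0.0, 1.0 - 1e-12))
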