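"""End-to-end orchestration: inputs -> analysis matrix -> all fitted models.

Thin glue over the stage modules, in the order the method runs: read and
validate the three inputs, summarize reaction norms, build consensus
masses, assemble the analysis matrix, then run the bivariate allometries
(OLS/SMA, standard and robust), the PGLS with evolutionary-model selection,
the factorial models with backward elimination, and the mass-error
resampling study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import allofit, inference, masscalc, massresample, phylogls, thermal
from .datamodel import (
    assemble_table,
    read_lengthmass_models,
    read_newick,
    read_species_table,
    reconcile_tree,
)

__all__ = ["StudyResults", "build_table", "run_study"]

QUARTER_POWER = 0.25  # the theoretically predicted exponent under test


@dataclass
class StudyResults:
    table: pd.DataFrame
    drop_report: list[str]
    ols: allofit.RegressionFit
    ols_robust: allofit.RegressionFit
    sma: allofit.RegressionFit
    sma_robust: allofit.RegressionFit
    sma_p_vs_quarter: float
    pgls_candidates: list[phylogls.GLSFit]
    pgls: phylogls.GLSFit
    pgls_r2: float
    ols_factorial_final: inference.FactorialFit
    ols_elimination: list[inference.EliminationStep]
    ols_anova: list[inference.AnovaRow]
    pgls_factorial_final: inference.FactorialFit
    pgls_elimination: list[inference.EliminationStep]
    predictions: pd.DataFrame
    binned_sma: dict
    covariate_check: inference.AnovaRow
    resampling: massresample.ResamplingResult | None
    notes: list[str] = field(default_factory=list)

    def fits_frame(self) -> pd.DataFrame:
        """Bivariate fits as the standard results CSV layout."""
        rows = []
        for fit in (self.ols, self.ols_robust, self.sma, self.sma_robust):
            rows.append(
                {
                    "method": fit.method,
                    "robust": fit.robust,
                    "n": fit.n,
                    "slope": fit.slope,
                    "ci_low": fit.slope_ci[0],
                    "ci_high": fit.slope_ci[1],
                    "intercept": fit.intercept,
                    "r2": fit.r2,
                }
            )
        return pd.DataFrame(rows)


def build_table(
    species_csv, models_csv, dialect: dict[str, str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Read the species and equation tables and assemble the analysis matrix."""
    records, bad_rows = read_species_table(species_csv, dialect)
    models = read_lengthmass_models(models_csv)
    summaries = thermal.summarize_species(records)
    masses = {
        rec.species_name: masscalc.ensemble_mass(rec.body_length_mm, rec.order, models)
        for rec in records
    }
    table, dropped = assemble_table(records, masses, summaries)
    return table, bad_rows + dropped


def run_study(
    species_csv,
    models_csv,
    newick,
    n_resample: int = 10_000,
    seed: int = 0,
    elim_alpha: float = 0.05,
    dialect: dict[str, str] | None = None,
) -> StudyResults:
    """Run the complete comparative analysis on the three inputs."""
    table, drop_report = build_table(species_csv, models_csv, dialect)
    tree = newick if isinstance(newick, dendropy.Tree) else read_newick(newick)
    mapping = reconcile_tree(tree, list(table["species"]))
    labels = [mapping[s] for s in table["species"]]

    x = table["ln_mass"].to_numpy()
    y = table["ln_tdev"].to_numpy()
    ols = allofit.ols_fit(x, y)
    ols_r = allofit.ols_fit(x, y, robust=True)
    sma = allofit.sma_fit(x, y)
    sma_r = allofit.sma_fit(x, y, robust=True)
    p_quarter = allofit.sma_slope_test(x, y, QUARTER_POWER)

    X, names = phylogls.design_with_intercept(x)
    candidates = phylogls.fit_candidates(tree, X, y, names, labels)
    best = phylogls.select_structure(candidates)
    X0 = np.ones((len(y), 1))
    V, _ = phylogls.structure_matrix(tree, best.structure, labels, corr_form=True)
    null_fit = phylogls.gls_fit(
        X0, y, V, ["intercept"], best.structure,
        alpha_estimated=best.structure.kind == "OU",
    )
    r2_lr = phylogls.pgls_r2(best, null_fit)

    ols_full = inference.fit_factorial(table, estimator="OLS")
    ols_final, ols_log = inference.backward_eliminate(ols_full, alpha=elim_alpha)
    anova = inference.sequential_partial_r2(ols_final)
    pgls_full = inference.fit_factorial(table, estimator="PGLS", tree=tree)
    pgls_final, pgls_log = inference.backward_eliminate(pgls_full, alpha=elim_alpha)
    predictions = inference.predict_standardized(ols_final)
    bins = inference.binned_sma(table)
    cov_check = inference.covariate_independence_check(table)
    resamp = (
        massresample.propagate_mass_error(table, n_reps=n_resample, seed=seed)
        if n_resample > 0
        else None
    )
    return StudyResults(
        table=table,
        drop_report=drop_report,
        ols=ols,
        ols_robust=ols_r,
        sma=sma,
        sma_robust=sma_r,
        sma_p_vs_quarter=p_quarter,
        pgls_candidates=candidates,
        pgls=best,
        pgls_r2=r2_lr,
        ols_factorial_final=ols_final,
        ols_elimination=ols_log,
        ols_anova=anova,
        pgls_factorial_final=pgls_final,
        pgls_elimination=pgls_log,
        predictions=predictions,
        binned_sma=bins,
        covariate_check=cov_check,
        resampling=resamp,
        notes=ols_full.notes + pgls_full.notes,
    )
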