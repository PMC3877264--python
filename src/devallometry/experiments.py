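"""Calibration and recovery experiments validating the estimation machinery.

Each experiment simulates data with known ground truth and measures how
reliably the corresponding estimator recovers it: evolutionary-structure
assignment by AIC, OU alpha recovery by REML, slope CI coverage, backward-
elimination calibration under null interactions, and slope attenuation
under mass measurement error. These are the package's quantitative
self-checks; the acceptance machinery and the test suite both call them.
"""

from __future__ import annotations

import numpy as np

from . import inference, massresample, phylogls, synthgen

__all__ = [
    "structure_recovery_experiment",
    "alpha_recovery_experiment",
    "slope_ci_coverage_experiment",
    "elimination_calibration_experiment",
    "attenuation_experiment",
]

#: generating OU constraint strengths for the structure-recovery experiment,
#: scaled inversely with tree depth so the prior correlation at typical
#: within-clade distances sits midway between independence and identity
#: (unit-branch trees are ~15 edges deep; Grafen trees have depth 1)
STRUCTURE_ALPHAS = {"unit_branches": 0.35, "grafen": 2.0}


def structure_recovery_experiment(
    n_tips: int = 200,
    n_reps: int = 100,
    seed: int = 0,
    n_clades: int = 12,
) -> dict[tuple[str, str], float]:
    """Fraction of replicates in which AIC selects the generating structure.

    Traits are simulated under each of {BM, OU} x {unit branches, Grafen}
    on one pure-birth tree, then all four candidates are fit and the lowest
    AIC wins. Returns ``{(kind, transform): correct_fraction}``.
    """
    rng = np.random.default_rng(seed)
    tree = synthgen.simulate_tree(n_tips, seed=int(rng.integers(2**31)), n_clades=n_clades)
    labels = phylogls.tip_labels(tree)
    x = rng.normal(size=n_tips)
    X, names = phylogls.design_with_intercept(x)
    chols = {}
    for kind, tf in phylogls.CANDIDATE_STRUCTURES:
        st = phylogls.CorrelationStructure(
            kind, tf, alpha=STRUCTURE_ALPHAS[tf] if kind == "OU" else None
        )
        V, _ = phylogls.structure_matrix(tree, st, labels, corr_form=True)
        chols[(kind, tf)] = np.linalg.cholesky(V + 1e-10 * np.eye(n_tips))
    results: dict[tuple[str, str], float] = {}
    for key, L in chols.items():
        correct = 0
        for _ in range(n_reps):
            y = 1.0 + 0.5 * x + L @ rng.standard_normal(n_tips)
            best = phylogls.select_structure(
                phylogls.fit_candidates(tree, X, y, names, labels, alpha_bounds=(1e-2, 1e2))
            )
            correct += (best.structure.kind, best.structure.transform) == key
        results[key] = correct / n_reps
    return results


def alpha_recovery_experiment(
    true_alpha: float = 1.0,
    n_tips: int = 200,
    n_reps: int = 100,
    seed: int = 0,
    factor: float = 2.0,
) -> tuple[float, np.ndarray]:
    """Fraction of replicates recovering OU alpha within ``factor`` of truth.

    The tree has exponential (variable) branch lengths: close tip pairs are
    what identify alpha, and a unit-branch tree has none closer than two
    edges, leaving alpha only weakly identified there.
    """
    rng = np.random.default_rng(seed)
    tree = synthgen.simulate_tree(
        n_tips, seed=int(rng.integers(2**31)), n_clades=12, unit_branch_lengths=False
    )
    labels = phylogls.tip_labels(tree)
    D, _ = phylogls.patristic_matrix(tree, labels)
    C = np.exp(-true_alpha * D)
    np.fill_diagonal(C, 1.0)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(n_tips))
    x = rng.normal(size=n_tips)
    X, names = phylogls.design_with_intercept(x)
    estimates = np.empty(n_reps)
    for i in range(n_reps):
        y = 1.0 + 0.5 * x + L @ rng.standard_normal(n_tips)
        alpha, _, _ = phylogls.optimize_alpha_reml(tree, X, y, transform="none", labels=labels)
        estimates[i] = alpha
    within = float(
        np.mean((estimates >= true_alpha / factor) & (estimates <= true_alpha * factor))
    )
    return within, estimates


def slope_ci_coverage_experiment(
    true_slope: float = 0.25,
    n_species: int = 361,
    target_r2: float = 0.26,
    n_reps: int = 200,
    seed: int = 0,
    confidence: float = 0.95,
) -> float:
    """Coverage of the OLS slope CI under the study-scale bivariate model.

    ln mass is uniform over the study's ~6-order-of-magnitude range and the
    residual SD is set so the expected R^2 matches ``target_r2``; returns
    the fraction of replicates whose CI contains the true slope.
    """
    from .allofit import ols_fit

    config = synthgen.GeneratorConfig(true_exponent=true_slope)
    sd = synthgen.residual_sd_for_r2(config, target_r2)
    lo, hi = config.mass_range_log10
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_reps):
        x = rng.uniform(lo * np.log(10), hi * np.log(10), size=n_species)
        y = 1.0 + true_slope * x + rng.normal(0.0, sd, size=n_species)
        fit = ols_fit(x, y, confidence=confidence)
        covered += fit.slope_ci[0] <= true_slope <= fit.slope_ci[1]
    return covered / n_reps


def elimination_calibration_experiment(
    n_reps: int = 200,
    n_species: int = 120,
    n_orders: int = 4,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Drop rate of a truly-null three-way interaction under backward elimination.

    Data are generated with main effects and NO interactions; under the
    null, the partial F-test exceeds its critical value with probability
    alpha, so the three-way interaction should be dropped in ~(1 - alpha)
    of replicates.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    orders = [f"Order{k}" for k in range(n_orders)]
    dropped = 0
    for _ in range(n_reps):
        order = rng.choice(orders, size=n_species)
        x = rng.uniform(-5, 7, size=n_species)
        t = rng.normal(30, 3, size=n_species)
        offs = {o: rng.normal(0, 0.5) for o in orders}
        y = 2.0 + 0.25 * x - 0.05 * (t - 30) + np.array([offs[o] for o in order])
        y = y + rng.normal(0, 0.8, size=n_species)
        table = pd.DataFrame(
            {"species": [f"sp{i}" for i in range(n_species)],
             "order": order, "ln_mass": x, "t_opt": t, "ln_tdev": y}
        )
        ffit = inference.fit_factorial(table, estimator="OLS")
        _, log = inference.backward_eliminate(ffit, alpha=alpha)
        dropped += any(
            s.term == "ln_mass:t_opt:order" and s.dropped for s in log
        )
    return dropped / n_reps


def attenuation_experiment(
    spreads: tuple[float, ...] = (0.0, 0.3, 0.8),
    n_species: int = 200,
    n_reps: int = 300,
    true_slope: float = 0.25,
    seed: int = 0,
) -> list[float]:
    """Mean resampled OLS slope at increasing mass-error spread.

    ``spreads`` are mass SDs as a fraction of the mass mean. With a positive
    true slope, larger spread attenuates the mean slope toward zero
    (classical errors-in-variables), so the returned means should decrease.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    x = rng.uniform(-4, 6, size=n_species)
    y = 1.0 + true_slope * x + rng.normal(0, 0.8, size=n_species)
    mass = np.exp(x)
    means = []
    for spread in spreads:
        table = pd.DataFrame(
            {"species": [f"sp{i}" for i in range(n_species)],
             "ln_tdev": y, "mass_mean_mg": mass, "mass_sd_mg": spread * mass}
        )
        res = massresample.propagate_mass_error(table, n_reps=n_reps, seed=seed + 1)
        means.append(res.slope_mean)
    return means
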