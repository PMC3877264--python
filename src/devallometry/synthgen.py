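"""Synthetic study generator with known ground truth.

Emulates the three inputs of the comparative analysis — a clade-structured
phylogeny, a long-format species table of thermal reaction norms, and a
table of order-specific length-mass equations — from a generative model
whose parameters are recorded alongside, so every pipeline stage is
testable end to end.

The generative trait model, with T_opt effects centered on a reference
temperature t_ref so that ``true_exponent`` is the mass slope at t_ref:

    ln T_dev = a + b*ln m + c*(T_opt - t_ref) + d*ln m*(T_opt - t_ref)
               + u_order + eps

``eps`` is i.i.d. or phylogenetically correlated (BM or OU) noise;
``u_order`` are order-level intercept offsets. Defaults mirror the scale of
the compiled insect study: 361 species in 16 orders with skewed richness,
ln mass spanning ~6 orders of magnitude, T_opt centered near 30 C with one
hot-shifted order, reaction norms measured at 2-11 constant temperatures,
and 2-7 length-mass models per order.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import phylogls
from .datamodel import LengthMassModel, read_newick

__all__ = [
    "GeneratorConfig",
    "StudyData",
    "simulate_tree",
    "simulate_traits",
    "simulate_reaction_norms",
    "simulate_lengthmass_models",
    "generate_study",
    "residual_sd_for_r2",
    "ORDER_NAMES",
]

#: insect order names used for synthetic clade labels (domain-realistic)
ORDER_NAMES = [
    "Blattaria", "Coleoptera", "Collembola", "Dermaptera", "Diptera",
    "Ephemeroptera", "Hemiptera", "Hymenoptera", "Lepidoptera", "Neuroptera",
    "Odonata", "Orthoptera", "Phasmatodea", "Psocodea", "Siphonaptera",
    "Thysanoptera",
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults mirror the compiled-study scale."""

    n_species: int = 361
    n_orders: int = 16
    # trait model
    true_exponent: float = 0.25          # b: mass slope at t_ref (ln d per ln mg)
    topt_effect: float = -0.055          # c: per degree C
    interaction_effect: float = -0.022   # d: per (ln mg * degree C)
    intercept: float = 3.0               # a: ln days for 1 mg at t_ref
    t_ref: float = 30.0                  # reference T_opt for centering
    order_intercept_sd: float = 0.8      # clade-level offsets (ln days)
    residual_sd: float = 1.35            # eps scale (ln days)
    phylo_model: str = "BM"              # "none" | "BM" | "OU"
    phylo_alpha: float = 1.0             # OU constraint strength
    # masses and T_opt
    mass_range_log10: tuple[float, float] = (-2.5, 3.2)
    t_opt_center: float = 30.0
    t_opt_order_sd: float = 2.0
    t_opt_tip_sd: float = 1.5
    hot_order: bool = True               # shift one order's T_opt +5 C
    # reaction norms
    temps_per_species: tuple[int, int] = (2, 11)
    norm_curvature: float = 0.01         # quadratic gain per C^2 below optimum
    norm_asymmetry: float = 2.0          # upper-limb curvature multiplier
    norm_noise_cv: float = 0.05          # multiplicative measurement noise
    # length-mass models
    models_per_order: tuple[int, int] = (2, 7)
    lm_true_ln_a: float = math.log(0.03)
    lm_true_b: float = 2.7
    lm_intercept_spread: float = 0.25    # sd of ln-intercept across models
    lm_exponent_spread: float = 0.04     # sd of exponent across models
    n_general_models: int = 3
    n_orders_without_models: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_species >= self.n_orders >= 1):
            raise ValueError("need n_species >= n_orders >= 1")
        lo, hi = self.mass_range_log10
        if not lo < hi:
            raise ValueError("mass range low must be < high")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.phylo_model not in ("none", "BM", "OU"):
            raise ValueError(f"unknown phylo_model {self.phylo_model!r}")


def residual_sd_for_r2(config: GeneratorConfig, target_r2: float) -> float:
    """Residual SD making the expected bivariate mass-only R^2 equal target_r2.

    Uses the variance of the uniform ln-mass distribution and treats all
    non-mass structure as noise, so it is exact when the T_opt and order
    effects are switched off.
    """
    lo, hi = config.mass_range_log10
    var_lnm = ((hi - lo) * math.log(10)) ** 2 / 12
    signal = config.true_exponent**2 * var_lnm
    if not (0 < target_r2 < 1):
        raise ValueError("target_r2 must be in (0, 1)")
    return math.sqrt(signal * (1 - target_r2) / target_r2)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def _yule_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Random pure-birth topology over ``labels`` (no branch lengths)."""
    nodes = [lab for lab in labels]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def _allocate(n_species: int, n_orders: int, rng: np.random.Generator) -> np.ndarray:
    """Skewed species richness per order (every order gets >= 1 species)."""
    probs = rng.dirichlet(np.full(n_orders, 0.4))
    extra = rng.multinomial(n_species - n_orders, probs)
    return extra + 1


def simulate_tree(
    n_tips: int,
    seed: int = 0,
    n_clades: int = 1,
    clade_sizes: list[int] | None = None,
    labels: list[str] | None = None,
    unit_branch_lengths: bool = True,
) -> dendropy.Tree:
    """Simulate a pure-birth topology, optionally structured into clades.

    With ``n_clades > 1`` a backbone tree joins monophyletic clade subtrees,
    so clade membership (the synthetic "order") is phylogenetically aligned.
    ``unit_branch_lengths=True`` sets every branch to 1 (the study
    convention); otherwise branch lengths are exponential waiting times.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"sp{i:04d}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")
    if clade_sizes is None:
        clade_sizes = list(_allocate(n_tips, n_clades, rng)) if n_clades > 1 else [n_tips]
    if sum(clade_sizes) != n_tips:
        raise ValueError("clade sizes must sum to n_tips")
    subtrees = []
    pos = 0
    for size in clade_sizes:
        block = labels[pos : pos + size]
        pos += size
        subtrees.append(block[0] if size == 1 else _yule_newick(block, rng))
    newick = (subtrees[0] if len(subtrees) == 1 else _yule_newick(subtrees, rng)) + ";"
    tree = read_newick(newick)
    if unit_branch_lengths:
        for edge in tree.preorder_edge_iter():
            edge.length = None if edge.head_node is tree.seed_node else 1.0
    else:
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                edge.length = None
            else:
                edge.length = float(rng.exponential(1.0))
    return tree


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------


def _phylo_noise(
    tree: dendropy.Tree,
    labels: list[str],
    model: str,
    alpha: float,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(labels)
    z = rng.standard_normal(n)
    if model == "none" or sd == 0:
        return sd * z
    if model == "BM":
        V, _ = phylogls.bm_covariance(tree, labels)
        C = phylogls.cov2corr(V)
    else:
        D, _ = phylogls.patristic_matrix(tree, labels)
        C = np.exp(-alpha * D)
        np.fill_diagonal(C, 1.0)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
    return sd * (L @ z)


def simulate_traits(
    tree: dendropy.Tree,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw per-species (ln_mass, t_opt, ln_tdev) under the generative model.

    Species orders are taken from tip labels of the form ``Order_spNNN``.
    Returns the realized trait table (the ground truth the pipeline should
    recover) and the generative parameter record.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = phylogls.tip_labels(tree)
    orders = [lab.split("_sp")[0] if "_sp" in lab else "Unknown" for lab in labels]
    order_names = sorted(set(orders))
    n = len(labels)

    lo, hi = config.mass_range_log10
    ln_mass = rng.uniform(lo * math.log(10), hi * math.log(10), size=n)

    offsets = {o: rng.normal(0.0, config.t_opt_order_sd) for o in order_names}
    if config.hot_order and len(order_names) > 1:
        offsets[order_names[-1]] += 5.0
    t_opt = np.array(
        [config.t_opt_center + offsets[o] for o in orders]
    ) + rng.normal(0.0, config.t_opt_tip_sd, size=n)
    t_opt = np.round(t_opt * 2) / 2  # measured at half-degree constant temps

    u = {o: rng.normal(0.0, config.order_intercept_sd) for o in order_names}
    eps = _phylo_noise(
        tree, labels, config.phylo_model, config.phylo_alpha, config.residual_sd, rng
    )
    tc = t_opt - config.t_ref
    ln_tdev = (
        config.intercept
        + config.true_exponent * ln_mass
        + config.topt_effect * tc
        + config.interaction_effect * ln_mass * tc
        + np.array([u[o] for o in orders])
        + eps
    )
    table = pd.DataFrame(
        {
            "species": labels,
            "order": orders,
            "ln_mass": ln_mass,
            "ln_tdev": ln_tdev,
            "t_opt": t_opt,
        }
    )
    truth = {
        "intercept": config.intercept,
        "true_exponent": config.true_exponent,
        "topt_effect": config.topt_effect,
        "interaction_effect": config.interaction_effect,
        "t_ref": config.t_ref,
        "phylo_model": config.phylo_model,
        "phylo_alpha": config.phylo_alpha,
        "residual_sd": config.residual_sd,
        "order_offsets": u,
        "t_opt_order_offsets": offsets,
    }
    return table, truth


def simulate_reaction_norms(
    t_dev: float,
    t_opt: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Sample a left-skewed reaction norm with its minimum ``t_dev`` at ``t_opt``.

    Development time follows a piecewise quadratic in temperature — shallower
    below the optimum, steeper above (curvature ratio ``norm_asymmetry``) —
    measured at 2-11 constant temperatures spanning the optimum, with
    multiplicative lognormal noise of CV ``norm_noise_cv``.
    """
    if not (t_dev > 0):
        raise ValueError("t_dev must be > 0")
    lo, hi = config.temps_per_species
    n_temps = int(rng.integers(lo, hi + 1))
    step = float(rng.choice([2.5, 5.0]))
    # position the optimum within the measured grid
    j = int(rng.integers(0, n_temps))
    temps = t_opt + step * (np.arange(n_temps) - j)
    dt = temps - t_opt
    curv = np.where(dt <= 0, config.norm_curvature, config.norm_asymmetry * config.norm_curvature)
    days = t_dev * (1.0 + curv * dt**2)
    if config.norm_noise_cv > 0:
        days = days * np.exp(rng.normal(0.0, config.norm_noise_cv, size=n_temps))
    return list(zip(temps.tolist(), days.tolist()))


def simulate_lengthmass_models(
    config: GeneratorConfig,
    orders: list[str],
    true_mass_mg: dict[str, float],
    species_orders: dict[str, str],
    rng: np.random.Generator,
) -> tuple[list[LengthMassModel], dict[str, float]]:
    """Per-order power-law model ensembles and back-computed body lengths.

    Each order has a "true" model used to convert true masses to lengths;
    the published-model ensemble scatters around it (ln-intercept and
    exponent perturbations), so per-species mass estimates disagree the way
    independent literature equations do. The last ``n_orders_without_models``
    orders get no order-specific models and must fall back to the general
    all-insect models.
    """
    true_models: dict[str, tuple[float, float]] = {}
    models: list[LengthMassModel] = []
    no_specific = set(orders[len(orders) - config.n_orders_without_models :]) if config.n_orders_without_models else set()
    mlo, mhi = config.models_per_order
    for order in orders:
        ln_a = config.lm_true_ln_a + rng.normal(0.0, 0.3)
        b = config.lm_true_b + rng.normal(0.0, 0.15)
        true_models[order] = (ln_a, b)
        if order in no_specific:
            continue
        n_models = int(rng.integers(mlo, mhi + 1))
        for k in range(n_models):
            models.append(
                LengthMassModel(
                    scope=order,
                    ln_intercept=ln_a + rng.normal(0.0, config.lm_intercept_spread),
                    exponent=b + rng.normal(0.0, config.lm_exponent_spread),
                    source_id=f"{order}-{k}",
                )
            )
    for k in range(config.n_general_models):
        models.append(
            LengthMassModel(
                scope="general",
                ln_intercept=config.lm_true_ln_a + rng.normal(0.0, config.lm_intercept_spread),
                exponent=config.lm_true_b + rng.normal(0.0, config.lm_exponent_spread),
                source_id=f"general-{k}",
            )
        )
    lengths: dict[str, float] = {}
    for sp, mass in true_mass_mg.items():
        ln_a, b = true_models[species_orders[sp]]
        lengths[sp] = math.exp((math.log(mass) - ln_a) / b)
    return models, lengths


# ---------------------------------------------------------------------------
# Full study assembly
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    """A complete synthetic study: the three inputs plus the generative truth."""

    species_table: pd.DataFrame  # long format, one row per measurement
    models: list[LengthMassModel]
    tree: dendropy.Tree
    traits: pd.DataFrame  # realized per-species ground truth
    truth: dict

    def write_inputs(self, outdir) -> dict[str, str]:
        """Write species CSV, equations CSV, Newick tree, and the truth record."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "species": str(outdir / "species.csv"),
            "models": str(outdir / "lengthmass_models.csv"),
            "tree": str(outdir / "tree.nwk"),
            "truth": str(outdir / "truth.json"),
        }
        self.species_table.to_csv(paths["species"], index=False)
        pd.DataFrame(
            [
                {
                    "scope": m.scope,
                    "ln_intercept": m.ln_intercept,
                    "exponent": m.exponent,
                    "source_id": m.source_id,
                }
                for m in self.models
            ]
        ).to_csv(paths["models"], index=False)
        with open(paths["tree"], "w") as fh:
            fh.write(
                self.tree.as_string(
                    schema="newick", suppress_rooting=True, unquoted_underscores=True
                )
            )
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)
        return paths


def generate_study(config: GeneratorConfig | None = None) -> StudyData:
    """Generate the full synthetic study from one seeded configuration."""
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    if config.n_orders <= len(ORDER_NAMES):
        order_names = ORDER_NAMES[: config.n_orders]
    else:
        order_names = [f"Order{i:02d}" for i in range(config.n_orders)]
    counts = _allocate(config.n_species, config.n_orders, rng)
    labels = []
    species_orders: dict[str, str] = {}
    clade_sizes = []
    for order, count in zip(order_names, counts):
        clade_sizes.append(int(count))
        for j in range(int(count)):
            name = f"{order}_sp{j + 1:03d}"
            labels.append(name)
            species_orders[name] = order
    tree = simulate_tree(
        config.n_species,
        seed=int(rng.integers(2**31)),
        clade_sizes=clade_sizes,
        labels=labels,
        unit_branch_lengths=True,
    )
    traits, truth = simulate_traits(tree, config, rng)
    true_mass = {s: math.exp(m) for s, m in zip(traits["species"], traits["ln_mass"])}
    models, lengths = simulate_lengthmass_models(
        config, list(order_names), true_mass, species_orders, rng
    )
    rows = []
    for _, row in traits.iterrows():
        norm = simulate_reaction_norms(
            math.exp(row["ln_tdev"]), row["t_opt"], config, rng
        )
        for temp, days in norm:
            rows.append(
                {
                    "species": row["species"],
                    "order": row["order"],
                    "family": f"{row['order']}idae",
                    "length_mm": lengths[row["species"]],
                    "temperature_C": temp,
                    "development_days": days,
                    "source": "synthetic",
                }
            )
    species_table = pd.DataFrame(rows)
    truth = dict(truth)
    truth["config"] = asdict(config)
    return StudyData(
        species_table=species_table,
        models=models,
        tree=tree,
        traits=traits,
        truth=truth,
    )
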