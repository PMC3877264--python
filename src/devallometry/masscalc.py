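"""Length-to-dry-mass conversion via an ensemble of published power-law models.

Each taxonomic order has one or more literature equations of the form
``dry_mass_mg = a * length_mm ** b``. Rather than picking a "best" equation,
every applicable model is evaluated and the consensus estimate is the
arithmetic mean of the per-model masses; the spread (sample SD) feeds the
measurement-error resampling study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .datamodel import LengthMassModel, resolve_models

__all__ = ["MassEstimate", "apply_model", "ensemble_mass", "estimates_frame"]


@dataclass(frozen=True)
class MassEstimate:
    """Consensus dry-mass estimate across an ensemble of length-mass models."""

    mean_mg: float
    sd_mg: float
    n_models: int
    per_model_mg: tuple[float, ...] = field(default_factory=tuple)


def apply_model(length_mm: float, model: LengthMassModel) -> float:
    """Evaluate one power-law model: ``exp(ln_intercept) * length_mm ** exponent`` (mg)."""
    if not (length_mm > 0):
        raise ValueError(f"length_mm must be > 0, got {length_mm}")
    return math.exp(model.ln_intercept) * length_mm**model.exponent


def ensemble_mass(
    length_mm: float,
    order: str,
    models: list[LengthMassModel],
    log_scale: bool = False,
) -> MassEstimate:
    """Consensus dry mass for one species from all models applicable to its order.

    Order-specific models are preferred; orders without any fall back to the
    ``"general"`` all-insect models. Averaging is on the mg scale by default
    (the consensus is a mean of mass estimates, not of their logs);
    ``log_scale=True`` switches to a geometric mean for sensitivity analysis.
    The SD uses the n-1 denominator, treating the model estimates as draws
    from independent model populations; it is 0 for a single model.
    """
    resolved = resolve_models(order, models)
    estimates = [apply_model(length_mm, m) for m in resolved]
    n = len(estimates)
    if log_scale:
        mean = math.exp(sum(math.log(e) for e in estimates) / n)
    else:
        mean = sum(estimates) / n
    if n > 1:
        var = sum((e - mean) ** 2 for e in estimates) / (n - 1)
        sd = math.sqrt(var) if not log_scale else _sd_about(estimates, mean)
    else:
        sd = 0.0
    return MassEstimate(mean_mg=mean, sd_mg=sd, n_models=n, per_model_mg=tuple(estimates))


def _sd_about(estimates: list[float], center: float) -> float:
    n = len(estimates)
    return math.sqrt(sum((e - center) ** 2 for e in estimates) / (n - 1))


def estimates_frame(estimates: dict[str, MassEstimate]) -> pd.DataFrame:
    """Tabulate estimates as (species, mean_mg, sd_mg, n_models)."""
    return pd.DataFrame(
        [
            {"species": name, "mean_mg": e.mean_mg, "sd_mg": e.sd_mg, "n_models": e.n_models}
            for name, e in sorted(estimates.items())
        ]
    )
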