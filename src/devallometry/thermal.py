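"""Reaction-norm summarization: minimum development time and its temperature.

For each species the thermal reaction norm — development time measured at a
handful of constant temperatures — is reduced to the empirical minimum
development time (T_dev) and the temperature attaining it (T_opt). No curve
is fitted: the optimum is the measured filled point, so sparse norms cannot
shift T_opt through interpolation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datamodel import NormPoint, SpeciesRecord

__all__ = ["ReactionNormSummary", "extract_optimum", "merge_species_estimates", "summarize_species"]

#: QC flag raised when the minimum sits at the warmest measured temperature:
#: development may still have been speeding up, so T_opt could be censored.
QC_BOUNDARY = "t_opt_at_warm_boundary"


@dataclass(frozen=True)
class ReactionNormSummary:
    """Minimum development time, its temperature, and measurement coverage."""

    t_dev_days: float
    t_opt_C: float
    n_temperatures: int
    qc_flag: str = ""


def extract_optimum(norm: list[NormPoint] | list[tuple]) -> ReactionNormSummary:
    """Return the empirical minimum development time and the temperature attaining it.

    Ties in development time break toward the lowest tied temperature (a
    deterministic, conservative rule: it never claims a warmer optimum than
    the data force). Norms whose minimum lies at the warmest measured
    temperature are flagged — such optima may be censored because the norm
    was never sampled past its optimum.
    """
    if not norm:
        raise ValueError("empty reaction norm")
    points = [p if isinstance(p, NormPoint) else NormPoint(*p) for p in norm]
    for p in points:
        if not (p.development_days > 0):
            raise ValueError(f"nonpositive development time {p.development_days}")
    best = min(points, key=lambda p: (p.development_days, p.temperature_C))
    temps = sorted({p.temperature_C for p in points})
    flag = QC_BOUNDARY if len(temps) > 1 and best.temperature_C == temps[-1] else ""
    return ReactionNormSummary(
        t_dev_days=best.development_days,
        t_opt_C=best.temperature_C,
        n_temperatures=len(temps),
        qc_flag=flag,
    )


def merge_species_estimates(
    summaries: list[ReactionNormSummary],
) -> ReactionNormSummary:
    """Combine independent estimates for one species: keep the smallest minimum.

    When several studies provide a minimum development time for the same
    species, the smallest T_dev wins and its T_opt is carried along; ties
    break toward the lowest T_opt.
    """
    if not summaries:
        raise ValueError("no summaries to merge")
    return min(summaries, key=lambda s: (s.t_dev_days, s.t_opt_C))


def summarize_species(records: list[SpeciesRecord]) -> dict[str, ReactionNormSummary]:
    """Extract a reaction-norm summary per species.

    Measurements pooled from multiple sources are scanned together; because
    the reduction is a minimum, pooling first or summarizing per source and
    then merging give the same answer.
    """
    return {rec.species_name: extract_optimum(rec.reaction_norm) for rec in records}


def summaries_frame(summaries: dict[str, ReactionNormSummary]) -> pd.DataFrame:
    """Tabulate summaries as (species, t_dev_days, t_opt_C, n_temperatures, qc_flag)."""
    return pd.DataFrame(
        [
            {
                "species": name,
                "t_dev_days": s.t_dev_days,
                "t_opt_C": s.t_opt_C,
                "n_temperatures": s.n_temperatures,
                "qc_flag": s.qc_flag,
            }
            for name, s in sorted(summaries.items())
        ]
    )
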