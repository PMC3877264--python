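"""Domain types and readers for the three study inputs.

The analysis consumes (1) a long-format species table of thermal
reaction-norm measurements, (2) a table of order-specific length->mass
power-law equations, and (3) a phylogeny in Newick format whose tip labels
match the species names.  This module parses and validates all three and
assembles the aligned analysis matrix (one row per species: ln dry mass,
ln minimum development time, optimal temperature, order).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import dendropy
import pandas as pd

__all__ = [
    "NormPoint",
    "SpeciesRecord",
    "LengthMassModel",
    "DEFAULT_DIALECT",
    "read_species_table",
    "read_lengthmass_models",
    "resolve_models",
    "read_newick",
    "write_newick",
    "patristic_distance",
    "normalize_name",
    "reconcile_tree",
    "assemble_table",
    "validate_table",
    "TABLE_COLUMNS",
]


@dataclass(frozen=True)
class NormPoint:
    """One reaction-norm measurement: development time at a constant temperature."""

    temperature_C: float
    development_days: float
    source: str = ""


@dataclass
class SpeciesRecord:
    """One species' taxonomy, body length, and thermal reaction norm.

    ``body_length_mm`` is the midpoint when the source reported a range.
    ``reaction_norm`` may pool measurements from several sources; each point
    carries its source tag.
    """

    species_name: str
    order: str
    family: str
    body_length_mm: float
    reaction_norm: list[NormPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species_name:
            raise ValueError("species_name must be non-empty")
        if not (self.body_length_mm > 0):
            raise ValueError(
                f"{self.species_name}: body_length_mm must be > 0, "
                f"got {self.body_length_mm}"
            )
        for p in self.reaction_norm:
            if not math.isfinite(p.temperature_C):
                raise ValueError(f"{self.species_name}: non-finite temperature")
            if not (p.development_days > 0):
                raise ValueError(
                    f"{self.species_name}: development_days must be > 0, "
                    f"got {p.development_days}"
                )


@dataclass(frozen=True)
class LengthMassModel:
    """Power-law dry-mass model ``mass_mg = exp(ln_intercept) * length_mm ** exponent``.

    ``scope`` is a taxonomic order name, or ``"general"`` for all-insect
    models used as a fallback for orders without order-specific equations.
    """

    scope: str
    ln_intercept: float
    exponent: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.exponent) or not math.isfinite(self.ln_intercept):
            raise ValueError(f"model {self.source_id!r}: non-finite parameters")


#: canonical -> default CSV column names for the long-format species table
DEFAULT_DIALECT: dict[str, str] = {
    "species": "species",
    "order": "order",
    "family": "family",
    "length_mm": "length_mm",
    "temperature_C": "temperature_C",
    "development_days": "development_days",
    "source": "source",
}

_RANGE_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*[-–—]\s*([0-9.eE+-]+)\s*$")


def _parse_length(value) -> float:
    """Parse a body length given as a single number or a 'min-max' range.

    Ranges (hyphen or en/em dash) are reduced to their midpoint, matching the
    convention of storing the midpoint when sources report a range.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    text = str(value).strip()
    m = _RANGE_RE.match(text)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        return 0.5 * (lo + hi)
    return float(text)


def read_species_table(
    path, dialect: dict[str, str] | None = None
) -> tuple[list[SpeciesRecord], list[str]]:
    """Read a long-format species CSV into grouped :class:`SpeciesRecord` objects.

    Parameters
    ----------
    path
        CSV path or file-like object. One row per (species, temperature)
        measurement.
    dialect
        Mapping from canonical column names (keys of :data:`DEFAULT_DIALECT`)
        to the file's actual headers, so differently-labelled tables load
        without code changes. Omitted keys keep their defaults.

    Returns
    -------
    (records, bad_rows)
        Grouped records plus a report of rows with unparseable numerics;
        such rows are reported, never silently dropped.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.empty:
        raise ValueError("species table is empty")
    required = ["species", "order", "length_mm", "temperature_C", "development_days"]
    for key in required:
        if cols[key] not in df.columns:
            raise KeyError(
                f"species table missing required column {cols[key]!r} "
                f"(canonical {key!r}); present: {list(df.columns)}"
            )
    has_family = cols["family"] in df.columns
    has_source = cols["source"] in df.columns

    bad_rows: list[str] = []
    grouped: dict[str, SpeciesRecord] = {}
    for idx, row in df.iterrows():
        name = str(row[cols["species"]]).strip()
        try:
            length = _parse_length(row[cols["length_mm"]])
            temp = float(row[cols["temperature_C"]])
            days = float(row[cols["development_days"]])
        except (TypeError, ValueError) as exc:
            bad_rows.append(f"row {idx} ({name}): {exc}")
            continue
        source = str(row[cols["source"]]).strip() if has_source else ""
        point = NormPoint(temp, days, source)
        if name in grouped:
            grouped[name].reaction_norm.append(point)
        else:
            grouped[name] = SpeciesRecord(
                species_name=name,
                order=str(row[cols["order"]]).strip(),
                family=str(row[cols["family"]]).strip() if has_family else "",
                body_length_mm=length,
                reaction_norm=[point],
            )
    records = list(grouped.values())
    for rec in records:
        if not rec.reaction_norm:
            raise ValueError(f"{rec.species_name}: empty reaction norm")
    return records, bad_rows


def read_lengthmass_models(path) -> list[LengthMassModel]:
    """Read the length->mass equation table (scope, ln_intercept, exponent, source_id)."""
    df = pd.read_csv(path, skipinitialspace=True)
    if df.empty:
        raise ValueError("length-mass model table is empty")
    for col in ("scope", "ln_intercept", "exponent"):
        if col not in df.columns:
            raise KeyError(f"model table missing required column {col!r}")
    models = []
    for idx, row in df.iterrows():
        try:
            ln_a = float(row["ln_intercept"])
            b = float(row["exponent"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"model table row {idx}: non-numeric parameter ({exc})")
        models.append(
            LengthMassModel(
                scope=str(row["scope"]).strip(),
                ln_intercept=ln_a,
                exponent=b,
                source_id=str(row.get("source_id", idx)),
            )
        )
    return models


def resolve_models(order: str, models: list[LengthMassModel]) -> list[LengthMassModel]:
    """Return the models applicable to ``order``: order-specific if any, else general.

    Orders lacking both order-specific and general models raise, naming the
    order, so a missing equation never silently drops species.
    """
    specific = [m for m in models if m.scope == order]
    if specific:
        return specific
    general = [m for m in models if m.scope.lower() == "general"]
    if general:
        return general
    raise ValueError(f"no length-mass model resolvable for order {order!r}")


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed; polytomies and missing branch lengths allowed)
# ---------------------------------------------------------------------------


def read_newick(source) -> dendropy.Tree:
    """Parse a Newick tree from a string, path, or file-like object.

    Duplicate tip labels raise: species joins are by exact label, and a
    duplicated tip makes the join ambiguous.
    """
    kwargs = dict(schema="newick", preserve_underscores=True)
    try:
        if isinstance(source, str) and source.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=source, **kwargs)
        elif hasattr(source, "read"):
            tree = dendropy.Tree.get(file=source, **kwargs)
        else:
            tree = dendropy.Tree.get(path=str(source), **kwargs)
    except (ValueError, OSError):
        raise
    except Exception as exc:  # dendropy parse errors carry position info
        raise ValueError(f"Newick parse failed: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels in tree: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def patristic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the path between tips ``a`` and ``b``."""
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    if ta is None or tb is None:
        raise KeyError(f"tip not found: {a if ta is None else b}")
    return pdm.patristic_distance(ta, tb)


_WS_RE = re.compile(r"[\s_]+")


def normalize_name(name: str) -> str:
    """Normalize a species name for table<->tree matching.

    Whitespace runs and underscores collapse to a single underscore and the
    result is case-folded. Matching is exact after this; no fuzzy matching,
    because a silent mis-join is worse than a hard error.
    """
    return _WS_RE.sub("_", name.strip()).casefold()


def reconcile_tree(tree: dendropy.Tree, species_names: list[str]) -> dict[str, str]:
    """Match analysis species to tree tips by normalized exact name.

    Returns a mapping ``species_name -> tip label``. Any species without a
    tip, or tip without a species, fails loudly with both lists.
    """
    tip_by_norm: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        key = normalize_name(leaf.taxon.label)
        if key in tip_by_norm:
            raise ValueError(f"tree tips collide after normalization: {key!r}")
        tip_by_norm[key] = leaf.taxon.label
    mapping: dict[str, str] = {}
    missing = []
    for name in species_names:
        key = normalize_name(name)
        if key in tip_by_norm:
            mapping[name] = tip_by_norm[key]
        else:
            missing.append(name)
    extra = sorted(set(tip_by_norm.values()) - set(mapping.values()))
    if missing or extra:
        raise ValueError(
            "tree/table reconciliation failed: "
            f"species without tips: {sorted(missing)}; tips without species: {extra}"
        )
    return mapping


# ---------------------------------------------------------------------------
# Analysis matrix
# ---------------------------------------------------------------------------

#: columns of the assembled analysis matrix, one row per species
TABLE_COLUMNS = [
    "species",
    "order",
    "ln_mass",
    "ln_tdev",
    "t_opt",
    "mass_mean_mg",
    "mass_sd_mg",
    "n_models",
    "n_temperatures",
]


def assemble_table(
    records: list[SpeciesRecord],
    mass_estimates: dict,
    thermal_summaries: dict,
) -> tuple[pd.DataFrame, list[str]]:
    """Join per-species mass estimates and thermal summaries into the analysis matrix.

    Parameters
    ----------
    records
        Parsed species records (provides taxonomy).
    mass_estimates
        ``species_name -> MassEstimate`` (from :mod:`devallometry.masscalc`).
    thermal_summaries
        ``species_name -> ReactionNormSummary`` (from :mod:`devallometry.thermal`).

    Returns
    -------
    (table, drop_report)
        DataFrame with :data:`TABLE_COLUMNS`, sorted by species name
        (the documented, stable row order), plus a report naming every
        species dropped for a missing component.
    """
    rows = []
    dropped: list[str] = []
    for rec in records:
        mass = mass_estimates.get(rec.species_name)
        summ = thermal_summaries.get(rec.species_name)
        if mass is None or summ is None:
            which = "mass estimate" if mass is None else "thermal summary"
            dropped.append(f"{rec.species_name}: missing {which}")
            continue
        rows.append(
            {
                "species": rec.species_name,
                "order": rec.order,
                "ln_mass": math.log(mass.mean_mg),
                "ln_tdev": math.log(summ.t_dev_days),
                "t_opt": summ.t_opt_C,
                "mass_mean_mg": mass.mean_mg,
                "mass_sd_mg": mass.sd_mg,
                "n_models": mass.n_models,
                "n_temperatures": summ.n_temperatures,
            }
        )
    if not rows:
        raise ValueError("assemble_table produced an empty table")
    table = pd.DataFrame(rows).sort_values("species").reset_index(drop=True)
    validate_table(table)
    return table, dropped


def validate_table(table: pd.DataFrame) -> None:
    """Check analysis-matrix invariants: required columns present, no missing values."""
    for col in ("species", "order", "ln_mass", "ln_tdev", "t_opt"):
        if col not in table.columns:
            raise ValueError(f"analysis table missing column {col!r}")
        if table[col].isna().any():
            bad = table.loc[table[col].isna(), "species"].tolist()
            raise ValueError(f"missing {col} for species: {bad}")
    if table["species"].duplicated().any():
        dupes = table.loc[table["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species rows: {dupes}")
    if "mass_sd_mg" in table.columns and (table["mass_sd_mg"] < 0).any():
        raise ValueError("negative mass_sd_mg")
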