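"""Readers and writers for the package's Newick and TSV dialects.

TSV is the canonical tabular format (tab-separated, UTF-8, header row,
empty string = missing); CSV is accepted on input by sniffing the header
line.  Every table written by a pipeline run starts with a provenance
block of ``#``-prefixed comment lines (version, config hash, seed), which
the readers skip.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Mapping, Optional

import dendropy
import pandas as pd
import yaml

from . import __version__
from .inflation_clock import validate_ultrametric
from .records import (
    ClineRecord,
    InferenceMethod,
    LineagePair,
    MarkerGenome,
    SpeclockError,
    ValidationError,
)

__all__ = [
    "read_tree",
    "read_years",
    "read_clines",
    "read_pairs",
    "write_table",
    "read_table",
    "RunConfig",
]


def read_tree(path: str | Path, rtol: float = 1e-6) -> dendropy.Tree:
    """Parse and validate an ultrametric Newick timetree.

    A depth spread within a decade of the tolerance passes but triggers a
    near-tolerance warning.
    """
    path = Path(path)
    if not path.exists():
        raise SpeclockError(f"tree file not found: {path}")
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise SpeclockError(f"malformed Newick in {path}: {exc}") from exc
    try:
        validate_ultrametric(tree, rtol=rtol / 10.0)
    except ValidationError:
        validate_ultrametric(tree, rtol=rtol)  # raises if truly beyond rtol
        warnings.warn(f"{path}: tip depth spread near the ultrametricity tolerance")
    return tree


def _sniff_sep(path: Path) -> str:
    header = path.open(encoding="utf-8").readline()
    return "\t" if "\t" in header or "," not in header else ","


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SpeclockError(f"input file not found: {path}")
    return pd.read_csv(path, sep=_sniff_sep(path), comment="#", dtype=str,
                       keep_default_na=False)


def read_years(path: str | Path) -> dict[str, int]:
    """Read the species/description-year TSV.

    Duplicate species resolve to the earliest year with a warning;
    non-integer years or years before 1758 are row-level errors.
    """
    df = read_table(path)
    cols = {c.lower(): c for c in df.columns}
    if "species" not in cols or "year" not in cols:
        raise SpeclockError(f"{path}: expected columns 'species' and 'year'")
    if df.empty:
        raise SpeclockError(f"{path}: no records")
    years: dict[str, int] = {}
    for i, row in df.iterrows():
        sp = row[cols["species"]].strip()
        raw = row[cols["year"]].strip()
        try:
            y = int(raw)
        except ValueError:
            raise ValidationError(f"{path} row {i + 2}: non-integer year {raw!r}")
        if y < 1758:
            raise ValidationError(f"{path} row {i + 2}: year {y} predates 1758")
        if sp in years:
            warnings.warn(f"duplicate species {sp!r}: keeping earliest year")
            years[sp] = min(years[sp], y)
        else:
            years[sp] = y
    return years


def _opt_float(v: str) -> Optional[float]:
    return None if v == "" else float(v)


def read_clines(path: str | Path) -> list[ClineRecord]:
    """Read the cline-measurement table; validates every record."""
    df = read_table(path)
    required = {"pair_id", "transect_id", "width_km", "n_markers",
                "marker_genome", "inference_method", "p_min", "p_max"}
    missing = required - set(df.columns)
    if missing:
        raise SpeclockError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        rec = ClineRecord(
            record_id=row.get("record_id", "") or f"row{i + 2}",
            pair_id=row["pair_id"],
            transect_id=row["transect_id"],
            width_km=float(row["width_km"]),
            n_markers=int(row["n_markers"]),
            marker_genome=MarkerGenome(row["marker_genome"] or "mixed/unknown"),
            inference_method=InferenceMethod(row["inference_method"]),
            p_min=_opt_float(row["p_min"]),
            p_max=_opt_float(row["p_max"]),
            survey_label=row.get("survey_label", ""),
        )
        rec.validate()
        records.append(rec)
    return records


def read_pairs(path: str | Path) -> dict[str, LineagePair]:
    """Read the hybridizing-pair table, binning dispersal rates on the fly."""
    from .hz_database import assign_dispersal_category

    df = read_table(path)
    required = {"pair_id", "taxon_a", "taxon_b", "group", "divergence_time_ma"}
    missing = required - set(df.columns)
    if missing:
        raise SpeclockError(f"{path}: missing columns {sorted(missing)}")
    pairs: dict[str, LineagePair] = {}
    for _, row in df.iterrows():
        rate = _opt_float(row.get("dispersal_rate_km_gen", ""))
        pair = LineagePair(
            pair_id=row["pair_id"],
            taxon_a=row["taxon_a"],
            taxon_b=row["taxon_b"],
            group=row["group"],
            divergence_time_ma=_opt_float(row["divergence_time_ma"]),
            dispersal_category=row.get("dispersal_category")
            or assign_dispersal_category(rate),
        )
        pair.validate()
        pairs[pair.pair_id] = pair
    return pairs


def provenance_header(config: Optional[Mapping] = None, seed: Optional[int] = None) -> str:
    cfg_hash = hashlib.sha256(
        json.dumps(dict(config or {}), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    lines = [f"# speclock {__version__}", f"# config_hash {cfg_hash}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    return "\n".join(lines) + "\n"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
) -> None:
    """Write a TSV with the provenance comment block prepended."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(provenance_header(config, seed))
        df.to_csv(fh, sep="\t", index=False)


#: Recognized configuration keys and their defaults.
_CONFIG_DEFAULTS: dict[str, object] = {
    "diagnostic_rule": "and",
    "glm_time_scale": "log",
    "glm_interactions": False,
    "anova_type": "II",
    "ellipse_scale": "log",
    "ellipse_estimator": "mvt",
    "ellipse_level": 0.95,
    "refpoint_min_markers": 3,
    "pivot_width_km": 30.0,
    "interval_length": 10,
    "interval_start": 1758,
    "threshold_ma": 2.0,
    "unique_pairs": False,
    "seed": 0,
}


class RunConfig(dict):
    """Validated run configuration; unknown keys are rejected by name."""

    def __init__(self, **kwargs):
        unknown = set(kwargs) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise SpeclockError(f"unknown config key(s): {sorted(unknown)}")
        merged = dict(_CONFIG_DEFAULTS)
        merged.update(kwargs)
        super().__init__(merged)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise SpeclockError(f"{path}: config must be a key-value mapping")
        return cls(**data)
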