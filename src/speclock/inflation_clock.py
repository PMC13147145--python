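"""Detecting taxonomic inflation from timetrees and description years.

On an ultrametric timetree the patristic distance between two tips (the
branch-length sum along the path) equals twice their divergence time, so
each species' *nearest relative* — the tip at minimum patristic distance —
gives its time-to-speciation estimate.  Slicing the tree by species
description year (pruning to the species described up to each decadal
cutoff) tracks how the age distribution of recognized species pairs
changed over taxonomic history; the proportion of pairs below a
reference divergence (e.g., 2.6 Ma in amphibians) and its recent increase
quantify potential taxonomic inflation.

"Species pairs" are counted per species: every species contributes one
record with its nearest relative, so mutual nearest neighbours yield two
records and n_pairs = n_species.  A ``unique_pairs`` mode collapsing
mutual pairs is available but non-default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .records import SpeclockError, ValidationError

__all__ = [
    "PairRecord",
    "ThresholdReport",
    "validate_ultrametric",
    "patristic_distances",
    "nearest_relative_pairs",
    "prune_to_year",
    "interval_series",
    "threshold_report",
    "inflation_increase",
    "compare_group_ages",
]

#: Start of zoological nomenclature; description years cannot predate it.
LINNEAN_START = 1758

ULTRAMETRIC_RTOL = 1e-6


@dataclass(frozen=True)
class PairRecord:
    species: str
    partner: str
    patristic_ma: float
    divergence_ma: float


@dataclass(frozen=True)
class ThresholdReport:
    threshold_ma: float
    count_below: int
    n_pairs: int
    proportion: float


def _leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    return {lf.taxon.label: lf.root_distance for lf in tree.leaf_node_iter()}


def validate_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> None:
    """Check equal root-to-tip depths (relative tolerance) and unique labels."""
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise ValidationError("tree must have >= 2 tips")
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"duplicate tip labels: {dup}")
    depths = _leaf_depths(tree)
    dmax, dmin = max(depths.values()), min(depths.values())
    if dmax > 0 and (dmax - dmin) > rtol * dmax:
        offenders = sorted(depths.items(), key=lambda kv: kv[1])
        raise ValidationError(
            "tree is not ultrametric: tip depths range from "
            f"{offenders[0][0]}={offenders[0][1]:.6g} to "
            f"{offenders[-1][0]}={offenders[-1][1]:.6g}"
        )


def patristic_distances(tree: dendropy.Tree, validate: bool = True) -> pd.DataFrame:
    """Symmetric patristic distance matrix over tips (labels sorted)."""
    if validate:
        validate_ultrametric(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            m[i, j] = m[j, i] = d
    return pd.DataFrame(m, index=labels, columns=labels)


def nearest_relative_pairs(
    tree_or_matrix: dendropy.Tree | pd.DataFrame,
    unique_pairs: bool = False,
    validate: bool = True,
) -> list[PairRecord]:
    """Each tip's nearest relative by patristic distance.

    Ties (exact or within 1e-9 relative) are broken alphabetically by
    partner label.  Divergence time is half the patristic distance.  With
    ``unique_pairs=True``, mutual nearest-neighbour duplicates are
    collapsed to a single record (species ordered alphabetically).
    """
    if isinstance(tree_or_matrix, pd.DataFrame):
        dm = tree_or_matrix
    else:
        dm = patristic_distances(tree_or_matrix, validate=validate)
    labels = list(dm.index)
    if len(labels) < 2:
        raise SpeclockError("nearest_relative_pairs requires >= 2 tips")
    vals = dm.to_numpy()
    records: list[PairRecord] = []
    for i, sp in enumerate(labels):
        row = vals[i].copy()
        row[i] = np.inf
        dmin = row.min()
        tol = 1e-9 * max(dmin, 1.0)
        partners = [labels[j] for j in np.flatnonzero(row <= dmin + tol)]
        partner = min(partners)
        d = float(dm.at[sp, partner])
        records.append(PairRecord(sp, partner, d, d / 2.0))
    if unique_pairs:
        seen: set[frozenset[str]] = set()
        deduped = []
        for rec in records:
            key = frozenset((rec.species, rec.partner))
            if key in seen:
                continue
            seen.add(key)
            deduped.append(rec)
        records = deduped
    return records


def prune_to_year(
    tree: dendropy.Tree,
    years: Mapping[str, int],
    cutoff_year: int,
    validate: bool = True,
) -> Optional[dendropy.Tree]:
    """Restrict the tree to species described by ``cutoff_year``.

    Path lengths among surviving tips are preserved exactly (unary nodes
    suppressed, merged branch lengths summed).  Species present in the
    year list but absent from the tree are skipped with a warning; tips
    without a description year are always excluded.  Fewer than two
    survivors returns ``None`` (empty-interval marker).
    """
    if validate:
        validate_ultrametric(tree)
    tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(set(years) - tip_labels)
    if missing:
        warnings.warn(
            f"{len(missing)} species in the year list absent from the tree "
            f"(e.g., {missing[:3]}); skipped"
        )
    keep = sorted(l for l in tip_labels if l in years and years[l] <= cutoff_year)
    if len(keep) < 2:
        return None
    pruned = tree.extract_tree_with_taxa_labels(keep)
    # the extracted tree shares the source namespace; detach so the source
    # tree and later prunes are unaffected
    pruned.migrate_taxon_namespace(dendropy.TaxonNamespace())
    return pruned


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write standard Newick.

    Branch lengths carry 10 significant digits so that root-to-tip depth
    sums survive a write/read round trip within the ultrametricity
    tolerance; fewer digits would make freshly written trees fail their
    own validation.
    """
    Path(path).write_text(
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        )
    )


def interval_series(
    tree: dendropy.Tree,
    years: Mapping[str, int],
    interval_length: int = 10,
    start: int = LINNEAN_START,
    out_dir: Optional[str | Path] = None,
    unique_pairs: bool = False,
) -> pd.DataFrame:
    """Per-cutoff summaries of nearest-relative patristic distances.

    Cutoffs run from ``start`` in steps of ``interval_length`` up to (and
    including) the last described year.  For each cutoff the tree is
    pruned, nearest-relative pairs are recomputed, and a summary row
    (cutoff_year, n_species, n_pairs, mean/min/max patristic distance) is
    emitted; empty intervals yield NaN statistics.  With ``out_dir`` set,
    each non-empty cutoff additionally writes ``tree_<year>.nwk`` and
    ``pairs_<year>.tsv``, and the summary is written as ``summary.tsv``.
    """
    if interval_length < 1:
        raise SpeclockError("interval_length must be >= 1 year")
    validate_ultrametric(tree)
    tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    usable = {sp: y for sp, y in years.items() if sp in tip_labels}
    if not usable:
        raise SpeclockError("no species in the year list occur in the tree")
    last = max(usable.values())
    cutoffs = list(range(start, last + interval_length, interval_length))
    if cutoffs[-1] < last:
        cutoffs.append(cutoffs[-1] + interval_length)

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rows = []
    for cutoff in cutoffs:
        pruned = prune_to_year(tree, usable, cutoff, validate=False)
        if pruned is None:
            rows.append(
                dict(cutoff_year=cutoff, n_species=sum(y <= cutoff for y in usable.values()),
                     n_pairs=0, mean_patristic_ma=math.nan,
                     min_patristic_ma=math.nan, max_patristic_ma=math.nan)
            )
            continue
        pairs = nearest_relative_pairs(pruned, unique_pairs=unique_pairs, validate=False)
        dists = [p.patristic_ma for p in pairs]
        rows.append(
            dict(
                cutoff_year=cutoff,
                n_species=len(pruned.taxon_namespace),
                n_pairs=len(pairs),
                mean_patristic_ma=float(np.mean(dists)),
                min_patristic_ma=float(np.min(dists)),
                max_patristic_ma=float(np.max(dists)),
            )
        )
        if out is not None:
            write_newick(pruned, out / f"tree_{cutoff}.nwk")
            pd.DataFrame([p.__dict__ for p in pairs]).to_csv(
                out / f"pairs_{cutoff}.tsv", sep="\t", index=False
            )
    summary = pd.DataFrame(rows)
    if out is not None:
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return summary


def threshold_report(
    pairs: Sequence[PairRecord], threshold_ma: float, on: str = "divergence"
) -> ThresholdReport:
    """Count and proportion of pairs strictly below a reference age.

    ``on="divergence"`` (default) thresholds the divergence time
    (patristic / 2); ``on="patristic"`` thresholds the full path length.
    """
    if not pairs:
        raise SpeclockError("threshold_report requires >= 1 pair record")
    if not threshold_ma > 0:
        raise SpeclockError("threshold must be positive")
    key = (lambda p: p.divergence_ma) if on == "divergence" else (lambda p: p.patristic_ma)
    count = sum(key(p) < threshold_ma for p in pairs)
    return ThresholdReport(
        threshold_ma=threshold_ma,
        count_below=count,
        n_pairs=len(pairs),
        proportion=count / len(pairs),
    )


def inflation_increase(
    sp: int, sp_young: int, sp_recent: int, sp_young_recent: int
) -> Optional[float]:
    """Relative increase (%) of the young-pair proportion among recent
    descriptions over the overall young-pair proportion.

    100 * ((sp_young_recent / sp_recent) / (sp_young / sp) - 1), rounded
    to 2 decimals.  Returns ``None`` (undefined-increase marker) when no
    young pairs exist overall.
    """
    if sp <= 0 or sp_recent <= 0:
        raise SpeclockError("SP and SP_recent must be positive")
    if not (0 <= sp_young <= sp and 0 <= sp_young_recent <= sp_recent <= sp):
        raise SpeclockError(
            f"inconsistent counts: SP={sp}, SP_young={sp_young}, "
            f"SP_recent={sp_recent}, SP_young_recent={sp_young_recent}"
        )
    if sp_young == 0:
        return None
    return round(100.0 * ((sp_young_recent / sp_recent) / (sp_young / sp) - 1.0), 2)


def _letter_display(groups: list[str], not_different: set[frozenset[str]]) -> dict[str, str]:
    # greedy compact letter display: groups share a letter iff every pair in
    # the letter-class is non-significant
    classes: list[set[str]] = []
    for g in groups:
        placed = False
        for cls in classes:
            if all(frozenset((g, h)) in not_different for h in cls):
                cls.add(g)
                placed = True
        if not placed:
            classes.append({g})
    letters = {g: "" for g in groups}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", classes):
        for g in cls:
            letters[g] += letter
    return letters


def compare_group_ages(
    ages_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise Welch t-tests of mean divergence times.

    Returns one row per group pair with the Welch statistic, raw and
    Bonferroni-adjusted p (multiplied by the number of comparisons, capped
    at 1), and a ``letters`` column mapping each group to its
    significance-grouping letters (groups sharing a letter do not differ
    at ``alpha``).
    """
    groups = sorted(g for g, v in ages_by_group.items() if len(v) >= 2)
    if len(groups) < 2:
        raise SpeclockError("compare_group_ages requires >= 2 groups with n >= 2")
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    m = len(pairs)
    rows = []
    not_different: set[frozenset[str]] = set()
    for a, b in pairs:
        xa = np.asarray(ages_by_group[a], dtype=float)
        xb = np.asarray(ages_by_group[b], dtype=float)
        flagged = xa.std(ddof=1) == 0 or xb.std(ddof=1) == 0
        if flagged and np.array_equal(xa, xb):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
        p_adj = min(1.0, float(p) * m)
        if p_adj > alpha:
            not_different.add(frozenset((a, b)))
        rows.append(
            dict(group_a=a, group_b=b, t=float(t), p_raw=float(p),
                 p_bonferroni=p_adj, zero_variance=bool(flagged))
        )
    letters = _letter_display(groups, not_different)
    df = pd.DataFrame(rows)
    df.attrs["letters"] = letters
    return df
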