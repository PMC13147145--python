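"""Synthetic trees, description years and cline tables.

The generator reproduces the statistical structure the pipeline assumes
about real data, so every stage is testable without external downloads:

* pure-birth (Yule) ultrametric trees with exponential waiting times;
* species description years biased so that lineages highly divergent from
  their nearest relative tend to be described earlier — the pattern by
  which morphologically distinct species enter the catalogue first;
* a hybrid-zone cline table in which the representative width follows
  log10 w = a + b * log10 T + group offset + gaussian noise, replicated
  over transects, markers and inference methods with multiplicative
  noise, and with a controllable fraction of non-diagnostic markers.

All randomness flows through a single seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.special import expit, logit

from .records import (
    ClineRecord,
    InferenceMethod,
    LineagePair,
    MarkerGenome,
)

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "assign_description_years",
    "simulate_cline_study",
]


@dataclass
class SimulationConfig:
    """Knobs of the cline-study generator.

    Defaults follow the structure of the compiled hybrid-zone literature:
    divergence times spanning ~0.05–20 Ma on a log scale, a negative
    log-log slope of width on time, group offsets of a fraction of a
    decade, ~30% of markers non-diagnostic before filtering, and group
    frequencies proportional to the published per-group pair counts.
    """

    seed: int = 0
    n_pairs: int = 200
    intercept_a: float = 2.0  # log10 km at T = 1 Ma
    slope_b: float = -0.5
    noise_sd: float = 0.2  # sd of the pair-level log10-width noise
    record_noise_sd: float = 0.1  # multiplicative (log10) noise per record
    time_range_ma: tuple[float, float] = (0.05, 20.0)
    group_probs: dict = field(
        default_factory=lambda: {
            "Lissamphibia": 0.30,
            "Aves": 0.26,
            "Squamata": 0.17,
            "Mammalia": 0.11,
            "Hexapoda": 0.12,
            "Other": 0.04,
        }
    )
    group_effects: dict = field(
        default_factory=lambda: {
            "Lissamphibia": 0.0,
            "Aves": 0.3,
            "Squamata": -0.1,
            "Mammalia": 0.1,
            "Hexapoda": -0.2,
            "Other": 0.0,
        }
    )
    dispersal_probs: dict = field(
        default_factory=lambda: {"A": 0.1, "B": 0.25, "C": 0.3, "D": 0.2, "E": 0.1, "F": 0.05}
    )
    dispersal_effects: dict = field(
        default_factory=lambda: {"A": -0.4, "B": -0.2, "C": 0.0, "D": 0.2, "E": 0.4, "F": 0.6}
    )
    nondiagnostic_fraction: float = 0.3
    max_transects: int = 3


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int | np.random.Generator = 0
) -> dendropy.Tree:
    """Ultrametric pure-birth tree with ``n_tips`` extant tips.

    Standard forward simulation: starting from the root split (two
    lineages), waiting times between speciations are exponential with
    rate (number of lineages) * ``birth_rate``; the lineage that splits is
    uniform.  After the (n-1)-th split a final exponential stretch with
    rate n * birth_rate runs to the present.  Tips are labelled T1..Tn in
    birth order.  Deterministic under a fixed seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth_rate > 0:
        raise ValueError("birth_rate must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tree = dendropy.Tree()
    root = tree.seed_node
    # active lineages as (node, birth_time)
    t = 0.0
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active = [(c1, 0.0), (c2, 0.0)]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (len(active) * birth_rate))
        idx = rng.integers(len(active))
        node, born = active.pop(int(idx))
        node.edge.length = t - born
        k1, k2 = dendropy.Node(), dendropy.Node()
        node.add_child(k1)
        node.add_child(k2)
        active.extend([(k1, t), (k2, t)])
    t += rng.exponential(1.0 / (len(active) * birth_rate))
    tns = tree.taxon_namespace
    for i, (node, born) in enumerate(active, start=1):
        node.edge.length = t - born
        node.taxon = tns.new_taxon(label=f"T{i}")
    root.edge.length = None
    return tree


def assign_description_years(
    tree: dendropy.Tree,
    year_range: tuple[int, int] = (1758, 2010),
    bias_strength: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, int]:
    """Description years biased toward early description of divergent species.

    For each tip, the position of its year within ``year_range`` is a
    logistic perturbation of a uniform draw: f = expit(logit(u) - c * z)
    where z is the standardized log nearest-relative divergence and c the
    bias strength, so highly divergent (distinct) species tend to receive
    early years.  ``bias_strength = 0`` gives uniform years.
    """
    from .inflation_clock import nearest_relative_pairs

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = nearest_relative_pairs(tree)
    logd = np.log([p.divergence_ma for p in pairs])
    z = (logd - logd.mean()) / (logd.std() or 1.0)
    u = rng.uniform(1e-12, 1 - 1e-12, size=len(pairs))
    f = expit(logit(u) - bias_strength * z)
    lo, hi = year_range
    years = np.floor(lo + f * (hi - lo + 1)).astype(int).clip(lo, hi)
    return {p.species: int(y) for p, y in zip(pairs, years)}


def _draw_p(rng: np.random.Generator, nondiag: bool) -> tuple[float, float]:
    if nondiag:  # violates both tails: p_min > 0.2 and p_max < 0.8
        return float(rng.uniform(0.21, 0.5)), float(rng.uniform(0.5, 0.79))
    return float(rng.uniform(0.0, 0.15)), float(rng.uniform(0.85, 1.0))


def simulate_cline_study(
    config: SimulationConfig,
) -> tuple[list[ClineRecord], dict[str, LineagePair]]:
    """Generate a cline table and pair table with the assumed structure.

    Each pair gets a true representative width from the log-linear model
    plus pair-level noise; each of its 1..max_transects transects carries
    single (mitochondrial and nuclear), median and average records whose
    widths add multiplicative record-level noise.  A
    ``nondiagnostic_fraction`` of single/average records receive tail
    frequencies violating the diagnosticity rule.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.group_probs)
    gp = np.array([cfg.group_probs[g] for g in groups], dtype=float)
    gp /= gp.sum()
    cats = list(cfg.dispersal_probs)
    dp = np.array([cfg.dispersal_probs[c] for c in cats], dtype=float)
    dp /= dp.sum()

    records: list[ClineRecord] = []
    pairs: dict[str, LineagePair] = {}
    rid = 0

    def emit(pair_id, transect, width, n_markers, genome, method, nondiag_draw):
        nonlocal rid
        rid += 1
        w = width * 10 ** rng.normal(0.0, cfg.record_noise_sd)
        nondiag = nondiag_draw and rng.uniform() < cfg.nondiagnostic_fraction
        p_min, p_max = _draw_p(rng, nondiag)
        records.append(
            ClineRecord(
                record_id=f"r{rid:05d}",
                pair_id=pair_id,
                transect_id=transect,
                width_km=float(w),
                n_markers=int(n_markers),
                marker_genome=genome,
                inference_method=method,
                p_min=p_min,
                p_max=p_max,
            )
        )

    lo, hi = cfg.time_range_ma
    for i in range(cfg.n_pairs):
        pair_id = f"p{i:04d}"
        t_ma = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        group = groups[rng.choice(len(groups), p=gp)]
        disp = cats[rng.choice(len(cats), p=dp)]
        log10_w = (
            cfg.intercept_a
            + cfg.slope_b * math.log10(t_ma)
            + cfg.group_effects.get(group, 0.0)
            + cfg.dispersal_effects.get(disp, 0.0)
            + rng.normal(0.0, cfg.noise_sd)
        )
        width = 10.0 ** log10_w
        pairs[pair_id] = LineagePair(
            pair_id=pair_id,
            taxon_a=f"{pair_id}_a",
            taxon_b=f"{pair_id}_b",
            group=group,
            divergence_time_ma=t_ma,
            dispersal_category=disp,
        )
        n_transects = int(rng.integers(1, cfg.max_transects + 1))
        for tr in range(n_transects):
            transect = f"{pair_id}_t{tr}"
            # single-marker clines (mix of mitochondrial and nuclear)
            for _ in range(int(rng.integers(1, 4))):
                genome = (
                    MarkerGenome.MITOCHONDRIAL
                    if rng.uniform() < 0.5
                    else MarkerGenome.NUCLEAR
                )
                emit(pair_id, transect, width, 1, genome, InferenceMethod.SINGLE, True)
            # a median over single-marker clines
            if rng.uniform() < 0.6:
                nm = int(rng.integers(2, 200))
                emit(pair_id, transect, width, nm, MarkerGenome.NUCLEAR,
                     InferenceMethod.MEDIAN, False)
            # an average (genomic ancestry) cline
            if rng.uniform() < 0.8:
                nm = int(10 ** rng.uniform(math.log10(2), math.log10(2000)))
                emit(pair_id, transect, width, max(2, nm), MarkerGenome.NUCLEAR,
                     InferenceMethod.AVERAGE, True)
    return records, pairs
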