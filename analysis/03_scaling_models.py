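#!/usr/bin/env python
"""Correlations, selection coefficients and gamma-GLM model selection.

On dataset B (one average width per pair): log-log Pearson correlations
overall and per group, tension-zone selection coefficients, the 8-model
gamma-GLM candidate set scored by AICc weights, and likelihood-ratio
tests of the best model's terms.  Writes correlations.tsv, selection.tsv,
models.tsv and anova.tsv under results/scaling/.
"""

from pathlib import Path

import pandas as pd

from speclock.io import read_table, write_table
from speclock.records import AnalysisRow, DISPERSAL_CATEGORIES
from speclock.scaling_models import (
    akaike_weights,
    anova_lr,
    enumerate_candidates,
    fit_gamma_glm,
    pearson_log,
    selection_coefficient,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_rows(name: str) -> list[AnalysisRow]:
    df = read_table(ROOT / "hzdb" / name)
    return [
        AnalysisRow(r.pair_id, str(r.category_id), float(r.width_km),
                    float(r.divergence_time_ma), r.group, r.dispersal_category,
                    int(r.n_markers_max))
        for r in df.itertuples()
    ]


def main() -> None:
    rows = load_rows("dataset_B.tsv")
    out = ROOT / "scaling"

    scopes = {"all": rows}
    for r in rows:
        scopes.setdefault(r.group, []).append(r)
    corr = []
    for scope, rs in scopes.items():
        if len(rs) < 3:
            continue
        c = pearson_log([r.width_km for r in rs], [r.divergence_time_ma for r in rs], scope)
        corr.append(dict(scope=scope, n=c.n, r=round(c.r, 3), p=c.p_value))
    write_table(pd.DataFrame(corr), out / "correlations.tsv")
    overall = next(c for c in corr if c["scope"] == "all")
    print(f"overall log-log correlation: r = {overall['r']} "
          f"(n = {overall['n']}, p = {overall['p']:.2g})")

    sel = [
        selection_coefficient(r.width_km, r.dispersal_category, r.pair_id)
        for r in rows if r.dispersal_category in DISPERSAL_CATEGORIES
    ]
    write_table(
        pd.DataFrame([s.__dict__ for s in sel]), out / "selection.tsv"
    )
    print(f"selection coefficients for {len(sel)} pairs "
          f"(median s = {pd.Series([s.s for s in sel]).median():.3g})")

    fits = akaike_weights([fit_gamma_glm(t, rows) for t in enumerate_candidates()])
    models = pd.DataFrame(
        [
            dict(formula=" + ".join(f.terms) or "1", k=f.k, n=f.n,
                 loglik=f.loglik, aicc=f.aicc, weight=f.akaike_weight)
            for f in fits
        ]
    )
    write_table(models, out / "models.tsv")
    best = fits[0]
    print(f"best gamma-GLM: width ~ {' + '.join(best.terms) or '1'} "
          f"(AICc weight {best.akaike_weight:.3f})")

    if best.terms:
        tab = anova_lr(best, rows)
        write_table(tab, out / "anova.tsv")
        print("likelihood-ratio tests of the best model:")
        print(tab.to_string(index=False))


if __name__ == "__main__":
    main()
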