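#!/usr/bin/env python
"""Stage 6: the correlation battery.

Runs the full fixture analysis (divergence on synthetic per-gene ortholog
pairs, topology, contribution) and tests every topology metric against
estimated omega and PI with Spearman and Kendall rank correlations, plus the
degree/neighborhood-connectivity and degree/betweenness Pearson pairs.
"""
from pathlib import Path

from odornet import PipelineConfig, pearson_r2, run_full_analysis

SEED = 20120928 % 100000
OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

report = run_full_analysis(PipelineConfig(seed=SEED, n_reps=1000))
report.correlations.to_csv(OUT / "correlations.tsv", sep="\t", index=False)

key = report.correlations.query(
    "y == 'omega' and method == 'spearman' and x in ('degree', 'betweenness_raw')")
for row in key.itertuples(index=False):
    print(f"omega vs {row.x}: spearman rs = {row.estimate:+.3f}, "
          f"P = {row.p_value:.3f} (n = {row.n})")

per_node = report.per_node
for a, b in (("degree", "neighborhood_connectivity"),
             ("degree", "betweenness_raw")):
    r, r2 = pearson_r2(per_node[a], per_node[b])
    print(f"{a} vs {b}: r = {r:+.3f}, R^2 = {r2:.3f}")
print(f"correlation battery written to {OUT / 'correlations.tsv'}")
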