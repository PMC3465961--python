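#!/usr/bin/env python
"""Stage 5: phenotypic contribution from the published chemotaxis table.

Computes the per-gene phenotype index (PI: sum of squared neuron-normalized
C.I. deficits) for the 11 assayed mutants and the weighted phenotype index
(WPI) of each group under three groupings: pathway position, degree
terciles, and betweenness terciles.
"""
from pathlib import Path

import pandas as pd

from odornet import bin_nodes, phenotype_index, weighted_phenotype_index
from odornet.fixtures import (chemotaxis_records, load_odor_network,
                              load_pathway_categories, wildtype_references)
from odornet.network import all_node_topologies

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

records = chemotaxis_records()
refs = wildtype_references(records)
by_gene = {}
for rec in records:
    if rec.gene != "wildtype" and rec.assay == "odortaxis":
        by_gene.setdefault(rec.gene, []).append(rec)
scores = {g: phenotype_index(rs, refs) for g, rs in by_gene.items()}

pi_table = pd.DataFrame(
    [{"gene": g, "PI": s.pi, "weight": s.weight,
      "neurons_assayed": len(s.neurons_assayed)} for g, s in sorted(scores.items())])
pi_table.to_csv(OUT / "phenotype_index.tsv", sep="\t", index=False)
print(f"PI computed for {len(scores)} mutants; "
      f"largest: {pi_table.loc[pi_table['PI'].idxmax(), 'gene']} "
      f"(PI = {pi_table['PI'].max():.3f})")

G = load_odor_network()
topo = all_node_topologies(G)
groupings = {
    "pathway_position": bin_nodes({g: 0.0 for g in G.nodes}, "pathway_position",
                                  categories=load_pathway_categories()),
    "degree_terciles": bin_nodes({g: float(d) for g, d in G.degree()},
                                 "quantiles_of_metric", k=3),
    "betweenness_terciles": bin_nodes(
        {g: topo[g].betweenness_raw for g in G.nodes},
        "quantiles_of_metric", k=3),
}
rows = []
for scheme, labels in groupings.items():
    for label in sorted(set(labels.values())):
        members = [g for g, lab in labels.items() if lab == label]
        member_scores = [scores[g] for g in members if g in scores]
        if not member_scores:
            continue
        wpi = weighted_phenotype_index(member_scores, group=label).wpi
        rows.append({"scheme": scheme, "group": label,
                     "n_scored": len(member_scores), "WPI": wpi})
wpi_table = pd.DataFrame(rows)
wpi_table.to_csv(OUT / "wpi.tsv", sep="\t", index=False)
print(wpi_table.to_string(index=False))
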