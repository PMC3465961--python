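# odornet

Topology, molecular evolution and phenotypic contribution in the nematode
odor-signaling network.

`odornet` re-implements, as a tested and reusable pipeline, an analysis of
how connectivity shapes selective constraint and behavioral contribution in
the composite *Caenorhabditis elegans* volatile-odor signaling network: 16
genes spanning the AWA/AWB/AWC sensory pathways (Gα subunits, receptor
guanylyl cyclases, the TAX-2/TAX-4 cGMP-gated channel, PKG, calcineurin,
arrestin, RGS, and the Go/Gq/DAG synaptic actuators), treated as a simple
undirected interaction graph.

The pipeline links four layers per gene:

* **Divergence** — synonymous (dS) and nonsynonymous (dN) substitution
  rates between orthologous coding sequences, via an own implementation of
  the Yang–Nielsen (2000) approximate method (F3x4 codon frequencies, κ
  from degenerate site classes, ω-weighted path counting iterated to
  convergence) with the Nei–Gojobori (1986) counting method as a second
  estimator; ω = dN/dS < 1 indicates purifying selection.
* **Diversity** — nucleotide diversity π and its 100-bp / 20-bp-step
  sliding-window profile along a coding alignment.
* **Topology** — the Cytoscape-style metric set on the undirected network:
  degree k, clustering coefficient C_n = 2e_n / (k_n(k_n−1)), betweenness
  C_b(n) = Σ_{s≠n≠t} σ_st(n)/σ_st, plus closeness, eccentricity, radiality,
  stress, neighborhood connectivity and topological coefficient.
* **Contribution** — chemotaxis-derived phenotype indices: per-neuron
  deficit C.I.diff = C.I.wt − C.I.mut, per-gene
  PI = Σ_neuron (C.I.diff / C.I.wt)², the long-term-adaptation variant
  (share of the wildtype adaptation response lost in the mutant), and the
  group-level WPI = Σ(PI_i·w_i)/Σ(w_i) with odor-count weights.

Rank correlations (Spearman, Kendall τ-b; exact permutation p-values for
n ≤ 8) relate the layers, and a randomization test places the network-mean
ω inside an empirical null built from 50,000 random 16-gene sets drawn with
replacement from a genome-wide ortholog pool — optionally constrained so
each set contains exactly 6 Gα-family genes, controlling for the network's
Gα enrichment.

A synthetic-data module generates every input (codon ortholog pairs evolved
under a Goldman–Yang-style codon model with known true ω, heavy-tailed
ortholog pools with a tagged Gα-like subset, random graphs), and the
package ships a curated fixture: the 16-gene network (reconstructed to
match the published summary statistics exactly — 16 edges, diameter 5,
characteristic path length 2.825; see `src/odornet/data/README.md`), the
full published chemotaxis table, and the pathway-position categories.

## Worked example

```python
from odornet import (SimulationConfig, simulate_codon_pair, estimate_yn00,
                     make_odor_fixture, network_summary, node_topology)

# recover a known omega from a simulated ortholog pair
pair = simulate_codon_pair(SimulationConfig(
    length_codons=500, kappa=2.0, omega_true=0.2, branch_length=0.3, seed=1))
est = estimate_yn00(pair)
print(f"dN={est.dN:.4f} dS={est.dS:.4f} omega={est.omega:.3f}")
# dN=0.0465 dS=0.2698 omega=0.172

G, records, categories = make_odor_fixture()
s = network_summary(G)
print(s.n_nodes, s.n_edges, s.diameter, s.characteristic_path_length)
# 16 16 5 2.825
print(node_topology(G, "odr-3").degree, node_topology(G, "egl-4").degree)
# 6 5
```

The estimated ω of 0.172 recovers the simulation's true value 0.2 to within
the single-pair sampling noise (the estimator-recovery tests average 100
such pairs); the fixture reproduces the published network summary exactly,
with odr-3 and egl-4 as the two hubs.

The full analysis is organized as numbered drivers under `analysis/`
(fixture assembly, divergence, diversity scans, topology, contribution,
correlations, randomization), each writing its tables under `results/`.
The same computations are available from the command line:

```sh
odornet network --out topo.tsv
odornet contribution --out pi.tsv
odornet randomize --reps 50000 --set-size 16 --constrain Galpha=6 \
    --seed 1 --out null.json
odornet all --seed 1 --out report/
```

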