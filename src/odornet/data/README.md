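# Curated odor-network fixture

## odor_network.sif

A curated reconstruction of the composite *C. elegans* volatile-odor
signaling network over the 16 genes of the study (AWA/AWB/AWC pathways
collapsed onto one undirected graph). The published figure of this network
is a schematic with no machine-readable edge list, so the edges here were
selected from pathway-plausible interactions (Gα subunits coupling to the
receptor guanylyl cyclases, cGMP gating of the TAX-2/TAX-4 channel, PKG and
calcineurin regulation, RGS/arrestin modulation of Gα, and the
Go/Gq/DAG-kinase synaptic actuator module) under the constraint that the
graph reproduce the published summary statistics exactly:

* 16 nodes, 16 edges (mean number of neighbors = 2)
* network diameter 5
* characteristic path length 2.825 (total pairwise distance 339 over the
  120 unordered node pairs)
* the two most highly connected nodes are odr-3 (degree 6) and egl-4
  (degree 5), matching the published identification of the hubs

No residual deviation from the printed summary statistics remains. The
individual edges are a curated stand-in, not the authors' original adjacency
list; node-level metrics other than the constrained ones may differ from the
original network.

The gene *egl-4* is also known as *pkg-1*; the fixture uses *egl-4*
throughout.

## chemotaxis.tsv

Every chemotaxis value printed in the source study: wildtype odortaxis
chemotaxis indices per neuron (0.9 AWA; -0.95 AWB; 0.85 AWC), wildtype
long-term-adaptation (LTA) C.I. differences (0.5 AWA; 0.65 AWC), and the
per-mutant C.I. differences for the 11 mutants with published assays.
Mutant C.I. values themselves are not printed, so `ci_mut` is left empty;
`ci_diff` carries the printed wildtype-minus-mutant difference. Genes
without a published assay (gpa-3, gpa-5, gpa-13, arr-1, tax-6) are absent
rather than zero-filled. The per-mutant odor counts used as WPI weights were
not published; `n_odors` defaults to the number of neurons with a recorded
assay for the gene and can be replaced by the user.

## pathway_categories.tsv

The three pathway-position categories: class 1 regulators (6 genes),
class 2 regulators (6 genes), actuators (4 genes).
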