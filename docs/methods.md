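# Methods

## The analysis

`odornet` studies a 16-gene composite network of volatile-odor signaling in
*C. elegans* (the AWA/AWB/AWC pathways collapsed onto one simple undirected
graph) and asks how a gene's position in that network relates to (i) its
rate of protein evolution against a distant nematode ortholog, (ii) its
within-alignment nucleotide diversity, and (iii) its behavioral
contribution as measured by chemotaxis assays. Four computational layers
feed a correlation battery and a randomization test; each layer is an
independently tested module.

## Divergence estimation

Both estimators operate on a gap-free, in-frame pair of aligned coding
sequences (gap columns are stripped codon-wise for divergence inputs so
the frame survives, and nucleotide-wise for diversity scans, where the
statistic is per-site).

**NG86 (Nei–Gojobori 1986).** Synonymous site counts assign each codon
position the fraction of its possible changes that are synonymous;
mutations creating stop codons are excluded and the denominator reduced, so
each codon contributes exactly 3 sites split between S and N. Differences
between codons are averaged with equal weights over all minimal
substitution paths (orders of the differing positions); paths through stop
codons are excluded, unless every order is blocked, in which case all
orders are counted. Proportions are corrected for multiple hits with the
Jukes–Cantor formula; a proportion ≥ 3/4 is reported as a flagged saturated
estimate.

**YN00 (Yang–Nielsen 2000 approximate method).** Codon frequencies come
from the F3x4 model estimated from the two sequences pooled (an
equal-frequency mode is available); the transition/transversion ratio κ is
estimated by applying the K80 correction separately to fourfold-degenerate
and nondegenerate codon positions (sites counted only where both codons
agree on the degeneracy class) and combining the two estimates weighted by
site counts, with κ = 1 as the uninformative fallback and a cap of 99 when
no transversions are observed. Site counts weight each single-nucleotide
mutation by κ (transitions) and the target-codon frequency, taking the
synonymous share of total mutational flux scaled to 3 sites per codon.
Differences are counted with path weights κ^(transitions)·ω^(nonsynonymous
steps) (ω floored at 1e-6 so fully nonsynonymous pairs remain countable),
and dS/dN are corrected with the K80 formula applied to the synonymous and
nonsynonymous transition/transversion proportions separately. ω = dN/dS is
iterated from ω = 1 to a tolerance of 1e-6 with a cap of 100 iterations
(non-convergence is flagged). This follows the published algorithm's
structure rather than any particular implementation line-for-line;
agreement with an independent implementation of the same method is asserted
in the test suite.

ω is undefined (NaN, flagged) when dS = 0 or saturated; undefined entries
are excluded from network means with a logged count. The recovery target
the estimators are held to: for ≥ 500 codons, divergence ≤ 0.5
substitutions/codon, the mean estimate over 100 replicates is within 15% of
a true ω in {0.1, 0.2, 1.0}.

## The codon-pair simulator

Ground truth for the estimators comes from a Goldman–Yang-style codon
model: 61 sense codons (universal code), single-nucleotide changes only,
rate to codon j proportional to π_j, multiplied by κ for transitions and ω
for nonsynonymous changes, scaled to one expected substitution per codon
per unit branch length. The ancestor is drawn from the equilibrium
frequencies (equal by default) and the descendant from exp(Qt). Defaults —
κ = 2, 500-codon genes, branch length 0.3–0.6 substitutions per codon —
represent a divergent but alignable nematode ortholog pair. The simulator
excludes stop codons by construction; ω = 0 provably never changes the
protein. It does not model indels, codon-usage bias (unless frequencies are
supplied), rate variation among sites, or selection heterogeneity along the
gene, so estimator recovery on these simulations bounds only
model-matched accuracy, not real-data robustness.

## Nucleotide diversity

π is the mean proportion of differing sites over all unordered sequence
pairs; with the default two-sequence interspecies alignment this is the
raw per-site difference proportion (no multiple-hit correction, matching
the convention of window-scan software). Windows are 100 bp advanced by
20 bp, starting at position 1; trailing partial windows are dropped so all
windows are comparable. Sites with non-ACGT characters are excluded from
both numerator and denominator of the affected pair.

## Topology metrics

All-pairs BFS provides distances and counts of distinct shortest paths
σ_st. Betweenness is the literal defining sum Σ σ_st(n)/σ_st over unordered
pairs with s ≠ n ≠ t (σ_st(n) = σ_sn·σ_nt when n lies on a shortest path),
stress the corresponding unweighted count; both are verified against
exhaustive simple-path enumeration on every connected graph with ≤ 6 nodes.
Clustering, closeness (reciprocal mean distance to reachable nodes),
eccentricity, radiality ((Δ+1−mean distance)/Δ with Δ the component
diameter), neighborhood connectivity (mean neighbor degree) and topological
coefficient follow the Cytoscape NetworkAnalyzer definitions. Raw and
normalized betweenness are both reported; correlations use raw values by
default. Disconnected graphs are handled per component; the characteristic
path length averages over connected pairs only.

## The curated fixture

The published network figure has no machine-readable edge list, so the
fixture's 16 edges were curated from pathway-plausible interactions under
the hard constraints of the published summary statistics and hub identity,
which they reproduce exactly (16 edges, diameter 5, characteristic path
length 2.825, hubs odr-3 and egl-4); `src/odornet/data/README.md` records
the construction. The chemotaxis table carries every published value
verbatim; mutant chemotaxis indices themselves were not published, so only
the differences are stored, and genes without a published assay are absent
rather than zero-filled. Per-mutant odor counts (the WPI weights) were not
published either; the default weight is the number of neurons assayed for
the gene, replaceable by user-supplied weights.

## Contribution metrics

PI is implemented exactly as the printed sum of squared neuron-normalized
deficits (no square root); a Euclidean-norm variant is available behind a
flag because the printed form is not decidable from the single worked
example. Missing neuron assays contribute zero, with a per-gene
completeness flag. The group-level WPI formula is printed in a
typographically garbled form; it is read as the weight-normalized mean
Σ(PI·w)/Σ(w), the only interpretation consistent with "weighted" and the
stated meaning of w. The LTA index is the share of the wildtype adaptation
response lost in the mutant.

## Correlations and the randomization null

Spearman (mid-rank) and Kendall τ-b estimates come from scipy; for n ≤ 8
the p-value is an exact two-sided enumeration over all n! orderings
(vectorized via the permutation-invariance of rank variances and of τ-b's
tie corrections), otherwise the standard large-sample approximations. The
study's n = 16 sits in the approximation regime; exactness at small n
exists to make the tests airtight.

The randomization null draws 16-gene sets with replacement (a gene may
repeat within a set — the literal reading of the published procedure; a
without-replacement-within-set option exists) from an ortholog pool. The
synthetic pool emulates the genome-wide 1:1 ortholog set: 5,666 entries, ω
i.i.d. gamma with mean 0.14 and shape 0.8 (right-skewed, zero-heavy, as
genome-wide dN/dS distributions are), with 1% of entries tagged as a
Gα-like family drawn from a lower-ω law (mean 0.05) so that constraining 6
of 16 draws to the tagged family shifts the null mean downward, mirroring
the published direction (0.106 < 0.14). The one-sided empirical p for
"observed mean below the null" uses the add-one rule and is never zero.
Nothing ties the synthetic pool to real ortholog identities; the
randomization results demonstrate the machinery, not genome biology.

## Pipeline and problem sizes

The fixture-mode pipeline assigns each gene a true ω from a
degree-dependent purifying-selection profile, ω_g = 0.027·exp(−k_g/2),
chosen to place the network mean near 0.012 with hubs most constrained —
i.e., the synthetic condition encodes the association the pipeline is built
to detect, and the correlation battery demonstrably recovers it (Spearman
rs ≈ −0.7 for ω against degree at the default seed). Default per-gene
simulations use 600 codons at 0.6 substitutions/codon — divergent enough to
be interesting, shallow enough that the K80-style corrections remain
defined. Acceptance-level checks run the randomization at 5,000 replicates
(Monte-Carlo standard errors are quoted accordingly); the analysis drivers
use the full 50,000.

## Known limitations

* The YN00 implementation is the approximate counting method; no
  maximum-likelihood (codeml-style) estimator is provided.
* Saturated distances (correction argument ≤ 0) are reported as flagged
  infinities rather than the very large finite values some tools print.
* The curated edge list is constrained only by the published summary
  statistics; individual edges are plausible, not authoritative, so
  node-level metrics beyond the constrained ones are fixture properties.
* π has no multiple-hit correction and no additional diversity statistics
  (θ_W, Tajima's D) are computed.
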