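"""Phenotypic-contribution metrics derived from chemotaxis assays.

A gene's behavioral contribution is scored from published chemotaxis indices
(C.I., in [-1, 1]): the deficit of a mutant in each odor-sensing neuron pair
(AWA, AWB, AWC) is the wildtype-minus-mutant difference C.I.diff, the
phenotype index (PI) sums the squared neuron-normalized deficits, and the
weighted phenotype index (WPI) aggregates PIs over a group of genes with
odor-count weights.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

NEURONS = ("AWA", "AWB", "AWC")
ASSAYS = ("odortaxis", "LTA")


@dataclass(frozen=True)
class ChemotaxisRecord:
    """One gene x neuron x assay measurement."""
    gene: str
    neuron: str
    assay: str = "odortaxis"
    ci_wt: float | None = None
    ci_mut: float | None = None
    ci_diff: float | None = None
    n_odors: int | None = None

    def __post_init__(self):
        if self.neuron not in NEURONS:
            raise ValueError(f"unknown neuron {self.neuron!r}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        for name, value in (("ci_wt", self.ci_wt), ("ci_mut", self.ci_mut)):
            if value is not None and abs(value) > 1:
                raise ValueError(f"{name}={value} outside [-1, 1]")
        if (self.ci_wt is not None and self.ci_mut is not None
                and self.ci_diff is not None
                and abs((self.ci_wt - self.ci_mut) - self.ci_diff) > 1e-9):
            raise ValueError("ci_diff inconsistent with ci_wt - ci_mut")

    def resolved_diff(self) -> float | None:
        if self.ci_diff is not None:
            return self.ci_diff
        if self.ci_wt is not None and self.ci_mut is not None:
            return self.ci_wt - self.ci_mut
        return None


@dataclass(frozen=True)
class ContributionScore:
    gene: str
    pi: float
    weight: float = 1.0
    group: str | None = None
    neurons_assayed: frozenset[str] = field(default_factory=frozenset)

    @property
    def complete(self) -> bool:
        """True when all three neurons were assayed."""
        return self.neurons_assayed == frozenset(NEURONS)


@dataclass(frozen=True)
class GroupContribution:
    group: str
    wpi: float
    n_members: int


def ci_diff(ci_wt: float, ci_mut: float) -> float:
    """Behavioral deficit of a mutant: wildtype C.I. minus mutant C.I."""
    for name, value in (("ci_wt", ci_wt), ("ci_mut", ci_mut)):
        if abs(value) > 1:
            raise ValueError(f"{name}={value} outside [-1, 1]")
    return ci_wt - ci_mut


def phenotype_index(records: list[ChemotaxisRecord],
                    wildtype_refs: dict[str, float],
                    root_form: bool = False) -> ContributionScore:
    """Phenotype index of one gene: sum over assayed neurons of
    (C.I.diff / C.I.wt)^2; neurons without a record contribute 0.

    root_form=True returns the Euclidean-norm variant (square root of the
    sum); the squared-sum form is the default.
    """
    if not records:
        raise ValueError("no chemotaxis records given")
    genes = {r.gene for r in records}
    if len(genes) != 1:
        raise ValueError(f"records span multiple genes: {sorted(genes)}")
    (gene,) = genes
    total = 0.0
    assayed = set()
    weight = 0
    for rec in records:
        diff = rec.resolved_diff()
        if diff is None:
            continue
        ref = wildtype_refs.get(rec.neuron)
        if ref is None or ref == 0:
            raise ValueError(
                f"zero/missing wildtype reference for neuron {rec.neuron}")
        total += (diff / ref) ** 2
        assayed.add(rec.neuron)
        if rec.n_odors is not None:
            weight = max(weight, rec.n_odors)
    if not assayed:
        raise ValueError(f"no usable C.I.diff values for {gene}")
    if weight == 0:
        weight = len(assayed)  # default weight: neurons with a recorded assay
    pi = float(np.sqrt(total)) if root_form else total
    return ContributionScore(gene=gene, pi=pi, weight=float(weight),
                             neurons_assayed=frozenset(assayed))


def lta_phenotype_index(ci_diff_wt_lta: float, ci_diff_mut_lta: float) -> float:
    """Contribution of a gene to long-term adaptation (LTA).

    ci_diff_wt_lta is the wildtype adaptation response (drop in C.I. after
    prolonged odor exposure); ci_diff_mut_lta is the residual response in
    the mutant. The index is the share of the wildtype response lost in the
    mutant: (wt - mut) / wt. A fully LTA-defective mutant (no residual
    response) scores 1; a mutant with wildtype-level adaptation scores 0.
    """
    if ci_diff_wt_lta == 0:
        raise ValueError("wildtype LTA response is zero; index undefined")
    return (ci_diff_wt_lta - ci_diff_mut_lta) / ci_diff_wt_lta


def weighted_phenotype_index(scores: list[ContributionScore],
                             group: str | None = None) -> GroupContribution:
    """Weight-normalized mean PI of a group: sum(PI_i * w_i) / sum(w_i)."""
    if not scores:
        raise ValueError("empty group")
    weights = np.array([s.weight for s in scores], dtype=float)
    if (weights < 0).any():
        raise ValueError("negative weights")
    if weights.sum() == 0:
        raise ValueError("all-zero weights")
    pis = np.array([s.pi for s in scores], dtype=float)
    label = group if group is not None else (scores[0].group or "group")
    return GroupContribution(group=label,
                             wpi=float((pis * weights).sum() / weights.sum()),
                             n_members=len(scores))


def bin_nodes(values: dict[str, float], scheme: str = "quantiles_of_metric",
              k: int = 3, categories: dict[str, str] | None = None
              ) -> dict[str, str]:
    """Assign each gene a group label.

    scheme="pathway_position" uses the supplied category map;
    scheme="quantiles_of_metric" assigns k ordered bins by metric value with
    ties broken by gene-id order (logged).
    """
    if not values:
        raise ValueError("empty value map")
    if scheme == "pathway_position":
        if categories is None:
            raise ValueError("pathway_position binning needs a category map")
        missing = set(values) - set(categories)
        if missing:
            raise ValueError(f"genes without a category: {sorted(missing)}")
        return {g: categories[g] for g in values}
    if scheme == "quantiles_of_metric":
        if k > len(values):
            raise ValueError(f"k={k} exceeds number of genes {len(values)}")
        ordered = sorted(values, key=lambda g: (values[g], g))
        if len({values[g] for g in values}) < len(values):
            logger.warning("ties in metric values broken by gene-id order")
        out = {}
        n = len(ordered)
        for rank, gene in enumerate(ordered):
            out[gene] = f"bin{min(rank * k // n, k - 1) + 1}"
        return out
    raise ValueError(f"unknown binning scheme {scheme!r}")
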