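"""Sense-codon machinery shared by the codon simulator and the divergence estimators.

The universal genetic code (61 sense codons, 3 stops) comes from Biopython's
codon table. Everything downstream — synonymous-site fractions, minimal
substitution paths between codons, transition/transversion classification —
is precomputed here once at import.
"""
from __future__ import annotations

import itertools
from typing import NamedTuple

from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_STANDARD = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD.forward_table))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID = dict(_STANDARD.forward_table)

N_SENSE = len(SENSE_CODONS)
assert N_SENSE == 61


def is_transition(a: str, b: str) -> bool:
    """True if the nucleotide change a<->b is a transition (purine<->purine
    or pyrimidine<->pyrimidine)."""
    return (a in PURINES) == (b in PURINES) and a != b


def is_synonymous(c1: str, c2: str) -> bool:
    return AMINO_ACID[c1] == AMINO_ACID[c2]


def codon_neighbors(codon: str) -> list[tuple[str, int]]:
    """Sense codons one nucleotide change away, with the changed position."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            other = codon[:pos] + nt + codon[pos + 1:]
            if other not in STOP_CODONS:
                out.append((other, pos))
    return out


def _syn_site_count(codon: str) -> float:
    """Synonymous sites of one codon (Nei-Gojobori counting).

    Each position contributes the fraction of its possible changes that are
    synonymous; changes to stop codons are excluded and the denominator
    reduced, so the three positions always sum to 3 sites total.
    """
    s = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            other = codon[:pos] + nt + codon[pos + 1:]
            if other in STOP_CODONS:
                continue
            n_valid += 1
            if is_synonymous(codon, other):
                n_syn += 1
        if n_valid:
            s += n_syn / n_valid
    return s


SYN_SITES = {c: _syn_site_count(c) for c in SENSE_CODONS}


class PathSteps(NamedTuple):
    """Per-path step counts between two codons along one minimal substitution
    order: synonymous/nonsynonymous split by transition/transversion."""
    syn_ts: int
    syn_tv: int
    non_ts: int
    non_tv: int

    @property
    def syn(self) -> int:
        return self.syn_ts + self.syn_tv

    @property
    def non(self) -> int:
        return self.non_ts + self.non_tv


def _enumerate_paths(c1: str, c2: str) -> tuple[list[PathSteps], bool]:
    """All minimal substitution paths c1 -> c2 (one order of the differing
    positions per path). Returns (paths, any_excluded): paths through stop
    codons are excluded; if every order passes through a stop, all orders are
    kept instead so the pair still contributes difference counts.
    """
    diff = [p for p in range(3) if c1[p] != c2[p]]
    all_paths: list[tuple[PathSteps, bool]] = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = [0, 0, 0, 0]
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            ts = is_transition(cur[pos], c2[pos])
            syn = is_synonymous(cur, nxt)
            idx = (0 if syn else 2) + (0 if ts else 1)
            steps[idx] += 1
            cur = nxt
        if not blocked:
            all_paths.append((PathSteps(*steps), False))
    if all_paths:
        return [p for p, _ in all_paths], False
    # every order blocked by a stop: fall back to unblocked counting,
    # classifying each step against c1's frame ignoring stop intermediates
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = [0, 0, 0, 0]
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            ts = is_transition(cur[pos], c2[pos])
            syn = nxt not in STOP_CODONS and cur not in STOP_CODONS and is_synonymous(cur, nxt)
            idx = (0 if syn else 2) + (0 if ts else 1)
            steps[idx] += 1
            cur = nxt
        paths.append(PathSteps(*steps))
    return paths, True


# minimal-path step data for every ordered pair of distinct sense codons
PAIR_PATHS: dict[tuple[str, str], list[PathSteps]] = {}
for _a, _b in itertools.product(SENSE_CODONS, repeat=2):
    if _a != _b:
        PAIR_PATHS[(_a, _b)], _ = _enumerate_paths(_a, _b)


def split_codons(seq: str) -> list[str]:
    """Split an in-frame nucleotide string into codons.

    Raises ValueError on length not divisible by 3 or internal stop codons.
    """
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon {i + 1}")
        if c not in CODON_INDEX:
            raise ValueError(f"non-ACGT codon {c!r} at codon {i + 1}")
    return codons
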