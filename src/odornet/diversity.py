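"""Nucleotide diversity (pi) and its sliding-window profile.

pi is the average proportion of differing sites over all unordered pairs of
aligned sequences. The window scan follows the classic coding-region
convention: fixed-width windows advanced by a fixed step, trailing partial
windows dropped. Sites where either sequence of a pair carries a non-ACGT
character are excluded from both the numerator and denominator of that pair.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class DiversityProfile:
    """Sliding-window pi values (1-based inclusive window coordinates)."""
    windows: tuple[tuple[int, int, float], ...]
    global_pi: float

    def midpoints(self) -> list[float]:
        return [(s + e) / 2 for s, e, _ in self.windows]


def _pair_pi(a: str, b: str) -> float:
    comparable = diffs = 0
    for x, y in zip(a, b):
        if x in _VALID and y in _VALID:
            comparable += 1
            if x != y:
                diffs += 1
    if comparable == 0:
        return float("nan")
    return diffs / comparable


def pairwise_pi(sequences: list[str]) -> float:
    """Average pairwise proportion of differing sites."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
    if lengths == {0}:
        raise ValueError("empty sequences")
    seqs = [s.upper().replace("U", "T") for s in sequences]
    values = [_pair_pi(a, b) for a, b in itertools.combinations(seqs, 2)]
    values = [v for v in values if not np.isnan(v)]
    if not values:
        return float("nan")
    return float(np.mean(values))


def sliding_window_pi(sequences: list[str], window: int = 100,
                      step: int = 20) -> DiversityProfile:
    """Window scan of pi: windows start at 1, 1+step, 1+2*step, ...; only
    full windows (end <= alignment length) are emitted."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("unequal sequence lengths")
    if length < window:
        raise ValueError(f"alignment length {length} shorter than window {window}")
    windows = []
    start = 1
    while start + window - 1 <= length:
        end = start + window - 1
        sliced = [s[start - 1:end] for s in sequences]
        windows.append((start, end, pairwise_pi(sliced)))
        start += step
    return DiversityProfile(windows=tuple(windows),
                            global_pi=pairwise_pi(sequences))


def profile_table(profile: DiversityProfile):
    """DataFrame view (start, end, midpoint, pi) for export/plotting."""
    import pandas as pd
    return pd.DataFrame(
        [(s, e, (s + e) / 2, pi) for s, e, pi in profile.windows],
        columns=["start", "end", "midpoint", "pi"])
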