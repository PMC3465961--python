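"""Synthetic inputs for every pipeline stage.

* codon ortholog pairs evolved under a Goldman–Yang-style codon model with a
  chosen true omega (the ground truth the divergence estimators must recover)
* ortholog pools with a heavy-tailed omega distribution and a tagged
  Galpha-like subset (the substrate of the randomization null)
* random undirected graphs (test substrates for the topology metrics)

Every operation takes an explicit integer seed; there is no global random
state.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.linalg import expm

from .codons import (CODON_INDEX, N_SENSE, SENSE_CODONS, is_synonymous,
                     is_transition)
from .io import CodonSequencePair


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one codon-pair simulation.

    branch_length is the expected number of substitutions per codon
    separating the two sequences (the sum over both lineages; the model is
    reversible so only the total matters).
    """
    length_codons: int
    kappa: float = 2.0
    omega_true: float = 0.2
    branch_length: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.length_codons < 1:
            raise ValueError("length_codons must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega_true < 0:
            raise ValueError("omega_true must be >= 0")
        if self.branch_length < 0:
            raise ValueError("branch_length must be >= 0")


def codon_rate_matrix(kappa: float, omega: float,
                      freqs: np.ndarray | None = None) -> np.ndarray:
    """Goldman–Yang instantaneous rate matrix over the 61 sense codons.

    Single-nucleotide changes only; rate to codon j proportional to pi_j,
    times kappa for transitions and omega for nonsynonymous changes. Scaled
    so the expected substitution rate is one per codon per unit time.
    """
    if freqs is None:
        freqs = np.full(N_SENSE, 1.0 / N_SENSE)
    Q = np.zeros((N_SENSE, N_SENSE))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            rate = freqs[j]
            if is_transition(ci[p], cj[p]):
                rate *= kappa
            if not is_synonymous(ci, cj):
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
    mean_rate = -(freqs * np.diag(Q)).sum()
    if mean_rate > 0:
        Q /= mean_rate
    return Q


def simulate_codon_pair(config: SimulationConfig,
                        freqs: np.ndarray | None = None) -> CodonSequencePair:
    """Evolve a descendant from a random ancestor under the codon model.

    Returns a pair of sequences of length 3 * length_codons with the
    descendant drawn from the transition matrix expm(Q * branch_length).
    Deterministic given config.seed.
    """
    rng = np.random.default_rng(config.seed)
    if freqs is None:
        freqs = np.full(N_SENSE, 1.0 / N_SENSE)
    ancestor = rng.choice(N_SENSE, size=config.length_codons, p=freqs)
    if config.branch_length == 0:
        descendant = ancestor.copy()
    else:
        Q = codon_rate_matrix(config.kappa, config.omega_true, freqs)
        P = expm(Q * config.branch_length)
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=1, keepdims=True)
        cum = np.cumsum(P, axis=1)
        u = rng.random(config.length_codons)
        descendant = (u[:, None] > cum[ancestor]).sum(axis=1)
    seq_a = "".join(SENSE_CODONS[i] for i in ancestor)
    seq_b = "".join(SENSE_CODONS[i] for i in descendant)
    return CodonSequencePair("ancestor", "descendant", seq_a, seq_b)


# ---------------------------------------------------------------------------
# ortholog pools
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolEntry:
    pair_id: str
    omega: float
    tags: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class OrthologPool:
    """A collection of per-pair omega values with category tags, the
    substrate of the randomization null."""
    entries: tuple[PoolEntry, ...]

    def __post_init__(self):
        ids = [e.pair_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("pair_ids must be unique")
        for e in self.entries:
            if not np.isfinite(e.omega) or e.omega < 0:
                raise ValueError(f"invalid omega {e.omega} for {e.pair_id}")

    def __len__(self) -> int:
        return len(self.entries)

    def omegas(self, tag: str | None = None, without: bool = False) -> np.ndarray:
        """All omega values, or those with (without) a given tag."""
        if tag is None:
            sel = self.entries
        elif without:
            sel = [e for e in self.entries if tag not in e.tags]
        else:
            sel = [e for e in self.entries if tag in e.tags]
        return np.array([e.omega for e in sel], dtype=float)


def gamma_omega_law(mean: float = 0.14, shape: float = 0.8):
    """Default heavy-tailed omega distribution: gamma with the given mean.

    Shape < 1 gives the right-skewed, zero-heavy profile typical of genome-
    wide dN/dS between divergent nematodes.
    """
    scale = mean / shape
    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.gamma(shape, scale, size=size)
    draw.mean = mean
    return draw


def _resolve_law(law):
    if law is None:
        return gamma_omega_law()
    if np.isscalar(law):
        value = float(law)
        def point(rng, size):
            return np.full(size, value)
        point.mean = value
        return point
    if hasattr(law, "rvs"):  # frozen scipy distribution
        return lambda rng, size: law.rvs(size=size, random_state=rng)
    return law  # callable (rng, size) -> array


def simulate_ortholog_pool(n_pairs: int, omega_law=None, tag_fraction: float = 0.0,
                           tag_label: str = "Galpha", seed: int = 0,
                           tagged_omega_law=None) -> OrthologPool:
    """Draw a pool of n_pairs omega values i.i.d. from omega_law.

    Exactly round(n_pairs * tag_fraction) entries carry tag_label; when
    tagged_omega_law is given, the tagged entries are drawn from it instead
    (e.g. a lower-omega law for a strongly conserved gene family).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0.0 <= tag_fraction <= 1.0:
        raise ValueError("tag_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    law = _resolve_law(omega_law)
    omegas = np.clip(np.asarray(law(rng, n_pairs), dtype=float), 0.0, None)
    n_tagged = round(n_pairs * tag_fraction)
    tagged_idx = rng.choice(n_pairs, size=n_tagged, replace=False)
    if tagged_omega_law is not None and n_tagged:
        tlaw = _resolve_law(tagged_omega_law)
        omegas[np.sort(tagged_idx)] = np.clip(
            np.asarray(tlaw(rng, n_tagged), dtype=float), 0.0, None)
    tagged = set(tagged_idx.tolist())
    entries = tuple(
        PoolEntry(pair_id=f"pair{i:05d}", omega=float(omegas[i]),
                  tags=frozenset({tag_label}) if i in tagged else frozenset())
        for i in range(n_pairs))
    return OrthologPool(entries)


# ---------------------------------------------------------------------------
# random graphs
# ---------------------------------------------------------------------------

def simulate_network(n_nodes: int, model: str = "erdos_renyi",
                     param: float = 0.2, seed: int = 0) -> nx.Graph:
    """Simple undirected random graph; deterministic given seed.

    model="erdos_renyi": param is the edge probability.
    model="tree_plus_chords": a uniform random labeled tree plus
    int(param) extra chord edges drawn uniformly from the non-edges.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if model == "erdos_renyi":
        return nx.gnp_random_graph(n_nodes, param, seed=seed)
    if model == "tree_plus_chords":
        G = nx.random_labeled_tree(n_nodes, seed=seed) if n_nodes > 1 else nx.empty_graph(1)
        rng = np.random.default_rng(seed)
        non_edges = sorted(nx.non_edges(G))
        k = min(int(param), len(non_edges))
        if k:
            chosen = rng.choice(len(non_edges), size=k, replace=False)
            G.add_edges_from(non_edges[i] for i in chosen)
        return G
    raise ValueError(f"unknown network model {model!r}")
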