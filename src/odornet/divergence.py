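"""Pairwise synonymous/nonsynonymous divergence estimation.

Two estimators over a gap-free in-frame codon pair:

* ``estimate_ng86`` — the Nei–Gojobori (1986) counting method: per-codon
  synonymous-site fractions, equal-weight averaging over all minimal
  substitution paths between differing codons, Jukes–Cantor correction.
* ``estimate_yn00`` — the Yang–Nielsen (2000) approximate method: F3x4 codon
  frequencies estimated from the pair, transition/transversion ratio (kappa)
  from fourfold-degenerate and nondegenerate sites, flux-weighted site
  counts, omega-weighted path counting iterated to convergence, and a
  K80-style multiple-hit correction applied separately to the synonymous and
  nonsynonymous transition/transversion proportions.

dN is nonsynonymous substitutions per nonsynonymous site, dS synonymous
substitutions per synonymous site; omega = dN/dS is undefined (NaN, flagged)
when dS = 0.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .codons import (AMINO_ACID, CODON_INDEX, NUCLEOTIDES, PAIR_PATHS,
                     SENSE_CODONS, STOP_CODONS, SYN_SITES, codon_neighbors,
                     is_synonymous, is_transition, split_codons)
from .io import CodonSequencePair

logger = logging.getLogger(__name__)

FLAG_UNDEFINED_OMEGA = "undefined_omega"
FLAG_SATURATED_DS = "saturated_dS"
FLAG_SATURATED_DN = "saturated_dN"
FLAG_NO_CONVERGENCE = "no_convergence"


@dataclass(frozen=True)
class DivergenceEstimate:
    """Per-pair divergence: rates, the ts/tv ratio, and the site/difference
    counts they were derived from."""
    pair_id: str
    method: str
    dN: float
    dS: float
    omega: float            # NaN when undefined (dS = 0) or saturated
    kappa_hat: float
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def omega_defined(self) -> bool:
        return math.isfinite(self.omega)


def _jukes_cantor(p: float) -> tuple[float, bool]:
    """JC69 multiple-hit correction of a proportion of differing sites.
    Returns (distance, saturated)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return math.inf, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def _k80_distance(P: float, Q: float) -> tuple[float, bool]:
    """K80 distance from transition (P) and transversion (Q) proportions."""
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return math.inf, True
    return -0.5 * math.log(a) - 0.25 * math.log(b), False


def estimate_ng86(pair: CodonSequencePair) -> DivergenceEstimate:
    """Nei–Gojobori (1986) counting estimate of dN, dS and omega."""
    codons_a = split_codons(pair.seq_a)
    codons_b = split_codons(pair.seq_b)
    n = len(codons_a)

    S = 0.5 * (sum(SYN_SITES[c] for c in codons_a) + sum(SYN_SITES[c] for c in codons_b))
    N = 3.0 * n - S

    Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if ca == cb:
            continue
        paths = PAIR_PATHS[(ca, cb)]
        Sd += sum(p.syn for p in paths) / len(paths)
        Nd += sum(p.non for p in paths) / len(paths)

    flags = set()
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, sat_s = _jukes_cantor(pS)
    dN, sat_n = _jukes_cantor(pN)
    if sat_s:
        flags.add(FLAG_SATURATED_DS)
    if sat_n:
        flags.add(FLAG_SATURATED_DN)

    if dS == 0.0 or sat_s or sat_n:
        omega = 0.0 if (dN == 0.0 and dS > 0.0) else math.nan
        if math.isnan(omega):
            flags.add(FLAG_UNDEFINED_OMEGA)
    else:
        omega = dN / dS

    return DivergenceEstimate(
        pair_id=f"{pair.id_a}|{pair.id_b}", method="NG86",
        dN=dN, dS=dS, omega=omega, kappa_hat=math.nan,
        S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, flags=frozenset(flags))


# ---------------------------------------------------------------------------
# YN00
# ---------------------------------------------------------------------------

def _degeneracy(codon: str, pos: int) -> int:
    """0 if no change at pos is synonymous, 4 if all (non-stop) changes are,
    2 otherwise."""
    n_syn = n_valid = 0
    for nt in NUCLEOTIDES:
        if nt == codon[pos]:
            continue
        other = codon[:pos] + nt + codon[pos + 1:]
        if other in STOP_CODONS:
            continue
        n_valid += 1
        if is_synonymous(codon, other):
            n_syn += 1
    if n_syn == 0:
        return 0
    if n_valid and n_syn == n_valid == 3:
        return 4
    return 2


def _estimate_kappa(codons_a: list[str], codons_b: list[str]) -> float:
    """kappa from fourfold-degenerate and nondegenerate site classes via K80,
    combined by a site-count-weighted average. Falls back to 1.0 when neither
    class is informative."""
    stats = {0: [0, 0, 0], 4: [0, 0, 0]}  # class -> [n_sites, ts, tv]
    for ca, cb in zip(codons_a, codons_b):
        for pos in range(3):
            da, db = _degeneracy(ca, pos), _degeneracy(cb, pos)
            if da != db or da not in stats:
                continue
            rec = stats[da]
            rec[0] += 1
            if ca[pos] != cb[pos]:
                if is_transition(ca[pos], cb[pos]):
                    rec[1] += 1
                else:
                    rec[2] += 1
    kappas, weights = [], []
    for rec in stats.values():
        L, ts, tv = rec
        if L == 0 or (ts == 0 and tv == 0):
            continue
        P, Q = ts / L, tv / L
        a = 1.0 - 2.0 * P - Q
        b = 1.0 - 2.0 * Q
        if a <= 0.0 or b <= 0.0:
            continue
        alpha_t = -0.5 * math.log(a) + 0.25 * math.log(b)
        beta_t = -0.25 * math.log(b)
        if beta_t <= 0.0:
            kappa = 99.0  # no transversions observed: cap
        else:
            kappa = max(alpha_t / beta_t, 1e-6)
        kappas.append(kappa)
        weights.append(L)
    if not kappas:
        return 1.0
    return float(np.average(kappas, weights=weights))


def _f3x4_frequencies(codons_a: list[str], codons_b: list[str]) -> np.ndarray:
    """F3x4 codon frequencies: position-specific nucleotide frequencies from
    both sequences pooled, renormalized over the 61 sense codons."""
    pos_counts = np.full((3, 4), 0.0)
    nt_index = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    for codon in codons_a + codons_b:
        for pos in range(3):
            pos_counts[pos, nt_index[codon[pos]]] += 1
    pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    pi = np.array([pos_freq[0, nt_index[c[0]]] * pos_freq[1, nt_index[c[1]]]
                   * pos_freq[2, nt_index[c[2]]] for c in SENSE_CODONS])
    total = pi.sum()
    if total <= 0:
        return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    return pi / total


def _count_sites_yn(codon_usage: Counter, pi: np.ndarray, kappa: float,
                    n_codons: int) -> tuple[float, float]:
    """Flux-weighted site counts: mutation u->v (one nucleotide apart) gets
    weight kappa^[ts] * pi_v; the synonymous share of total flux, scaled to
    3 sites per codon."""
    syn_flux = tot_flux = 0.0
    total_usage = sum(codon_usage.values())
    for codon, cnt in codon_usage.items():
        f_u = cnt / total_usage
        for other, pos in codon_neighbors(codon):
            w = f_u * pi[CODON_INDEX[other]]
            if is_transition(codon[pos], other[pos]):
                w *= kappa
            tot_flux += w
            if is_synonymous(codon, other):
                syn_flux += w
    if tot_flux <= 0:
        rho = 0.25
    else:
        rho = syn_flux / tot_flux
    S = 3.0 * n_codons * rho
    return S, 3.0 * n_codons - S


def _count_diffs_weighted(codons_a, codons_b, kappa: float, omega: float
                          ) -> tuple[float, float, float, float]:
    """Expected (syn_ts, syn_tv, non_ts, non_tv) difference counts, weighting
    each minimal path by kappa^(ts steps) * omega^(nonsyn steps)."""
    w_omega = max(omega, 1e-6)  # keep paths with nonsyn steps countable
    totals = np.zeros(4)
    for ca, cb in zip(codons_a, codons_b):
        if ca == cb:
            continue
        paths = PAIR_PATHS[(ca, cb)]
        weights = np.array([kappa ** (p.syn_ts + p.non_ts) * w_omega ** p.non
                            for p in paths])
        weights /= weights.sum()
        steps = np.array([[p.syn_ts, p.syn_tv, p.non_ts, p.non_tv] for p in paths])
        totals += weights @ steps
    return tuple(totals)


def estimate_yn00(pair: CodonSequencePair, codon_freq: str = "F3x4",
                  tol: float = 1e-6, max_iter: int = 100) -> DivergenceEstimate:
    """Yang–Nielsen (2000) approximate estimate of dN, dS and omega.

    codon_freq: "F3x4" (frequencies from the pair, the default) or "equal".
    """
    codons_a = split_codons(pair.seq_a)
    codons_b = split_codons(pair.seq_b)
    n = len(codons_a)

    if codon_freq == "F3x4":
        pi = _f3x4_frequencies(codons_a, codons_b)
    elif codon_freq == "equal":
        pi = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    else:
        raise ValueError(f"unknown codon frequency model {codon_freq!r}")

    kappa = _estimate_kappa(codons_a, codons_b)
    usage = Counter(codons_a) + Counter(codons_b)
    S, N = _count_sites_yn(usage, pi, kappa, n)

    flags: set[str] = set()
    omega = 1.0
    dN = dS = 0.0
    converged = False
    for _ in range(max_iter):
        s_ts, s_tv, n_ts, n_tv = _count_diffs_weighted(codons_a, codons_b, kappa, omega)
        dS, sat_s = _k80_distance(s_ts / S, s_tv / S) if S > 0 else (0.0, False)
        dN, sat_n = _k80_distance(n_ts / N, n_tv / N) if N > 0 else (0.0, False)
        if sat_s:
            flags.add(FLAG_SATURATED_DS)
        if sat_n:
            flags.add(FLAG_SATURATED_DN)
        if dS == 0.0 or not math.isfinite(dS) or not math.isfinite(dN):
            new_omega = math.nan
        else:
            new_omega = dN / dS
        if math.isnan(new_omega):
            omega = new_omega
            converged = True  # nothing further to iterate on
            break
        if abs(new_omega - omega) < tol:
            omega = new_omega
            converged = True
            break
        omega = new_omega
    if not converged:
        flags.add(FLAG_NO_CONVERGENCE)
    if math.isnan(omega):
        if dN == 0.0 and dS > 0.0 and math.isfinite(dS):
            omega = 0.0
        else:
            flags.add(FLAG_UNDEFINED_OMEGA)

    s_ts, s_tv, n_ts, n_tv = _count_diffs_weighted(
        codons_a, codons_b, kappa, omega if math.isfinite(omega) else 1.0)
    return DivergenceEstimate(
        pair_id=f"{pair.id_a}|{pair.id_b}", method="YN00",
        dN=dN, dS=dS, omega=omega, kappa_hat=kappa,
        S_sites=S, N_sites=N, Sd=s_ts + s_tv, Nd=n_ts + n_tv,
        flags=frozenset(flags))


def network_mean_omega(estimates) -> float:
    """Arithmetic mean of per-pair omega values.

    Accepts DivergenceEstimate objects or bare floats. Undefined (NaN)
    entries are excluded with a logged count; all-undefined input raises.
    """
    values = []
    n_undefined = 0
    for e in estimates:
        omega = e.omega if isinstance(e, DivergenceEstimate) else float(e)
        if math.isfinite(omega):
            values.append(omega)
        else:
            n_undefined += 1
    if not values:
        raise ValueError("no defined omega values to average")
    if n_undefined:
        logger.warning("%d undefined omega value(s) excluded from the mean", n_undefined)
    return float(np.mean(values))
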