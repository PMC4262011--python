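"""Neutrality statistics computed per delimited species.

Statistics are computed on sampled sequences, i.e. haplotypes expanded by
their multiplicities, after complete deletion of alignment columns holding
a gap, ``N`` or any other non-ACGT character.  Sites with more than two
alleles count as one segregating site contributing ``alleles - 1``
mutations.  Undefined statistics propagate as ``nan`` sentinels.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import InsufficientDataError
from .io_core import HaplotypeAlignment

_ACGT = np.frombuffer(b"ACGT", dtype="S1")


def _expand(aln) -> list[str]:
    if isinstance(aln, HaplotypeAlignment):
        return aln.expanded_sequences()
    return [s.upper() for s in aln]


def _clean_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Sequence matrix restricted to columns that are ACGT in every row."""
    mat = np.array([np.frombuffer(s.encode(), dtype="S1") for s in seqs])
    keep = np.isin(mat, _ACGT).all(axis=0)
    return mat[:, keep]


# ---------------------------------------------------------------------------
# site summaries
# ---------------------------------------------------------------------------

@dataclass
class SiteSummaries:
    """Inputs shared by all five neutrality tests."""

    n: int          # sample size (sequences)
    S: int          # segregating sites
    k_bar: float    # mean pairwise difference count (sites, not per-site)
    theta_W: float  # Watterson estimator on the differences scale
    eta: int        # mutation count (alleles - 1 summed over sites)
    eta_s: int      # singleton mutations
    K: int          # distinct sequences
    singleton_load: np.ndarray  # per-sequence singleton mutation counts U_i


def site_summaries(aln) -> SiteSummaries:
    """Single pass over the (expanded) alignment.

    ``eta_s`` counts mutations carried by exactly one sequence; at a site
    where every allele is unique one allele is treated as ancestral so the
    singleton count never exceeds the mutation count.
    """
    seqs = _expand(aln)
    n = len(seqs)
    if n < 2:
        raise InsufficientDataError("site summaries need >= 2 sequences")
    if len({len(s) for s in seqs}) > 1:
        raise InsufficientDataError("sequences differ in length")
    mat = _clean_matrix(seqs)
    S = 0
    eta = 0
    eta_s = 0
    total_diff_pairs = 0
    U = np.zeros(n, dtype=int)
    n_pairs = n * (n - 1) // 2
    for col in mat.T:
        alleles, counts = np.unique(col, return_counts=True)
        a = len(alleles)
        if a < 2:
            continue
        S += 1
        eta += a - 1
        total_diff_pairs += n_pairs - int(
            (counts * (counts - 1) // 2).sum()
        )
        single_mask = counts == 1
        n_single = int(single_mask.sum())
        budget = min(n_single, a - 1)
        eta_s += budget
        if budget:
            # deterministic choice of which singleton allele is "ancestral"
            # when all alleles are unique: drop the lexicographically first
            singles = alleles[single_mask]
            if n_single > budget:
                singles = np.sort(singles)[n_single - budget:]
            for allele in singles:
                U[int(np.nonzero(col == allele)[0][0])] += 1
    k_bar = total_diff_pairs / n_pairs
    a1 = _harmonic(n - 1)
    theta_W = S / a1
    K = len({row.tobytes() for row in mat}) if mat.shape[1] else 1
    return SiteSummaries(
        n=n,
        S=S,
        k_bar=float(k_bar),
        theta_W=float(theta_W),
        eta=int(eta),
        eta_s=int(eta_s),
        K=int(K),
        singleton_load=U,
    )


def _harmonic(m: int, power: float = 1.0) -> float:
    return float(np.sum(1.0 / np.arange(1, m + 1) ** power))


# ---------------------------------------------------------------------------
# the five statistics
# ---------------------------------------------------------------------------

def tajimas_d(ss: SiteSummaries) -> float:
    """Tajima's D with the canonical variance constants."""
    n, S = ss.n, ss.S
    if S == 0 or n < 4:
        return float("nan")
    a1 = _harmonic(n - 1)
    a2 = _harmonic(n - 1, 2.0)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((ss.k_bar - S / a1) / math.sqrt(var))


def fu_li(ss: SiteSummaries) -> tuple[float, float]:
    """Fu & Li's D* and F* (no-outgroup variants, corrected constants)."""
    n = ss.n
    eta, eta_s = ss.eta, ss.eta_s
    if ss.S == 0 or n < 4:
        return float("nan"), float("nan")
    an = _harmonic(n - 1)
    bn = _harmonic(n - 1, 2.0)
    an1 = an + 1.0 / n
    cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2.0) / (n - 1.0) ** 2
        + (2.0 / (n - 1.0))
        * (1.5 - (2.0 * an1 - 3.0) / (n - 2.0) - 1.0 / n)
    )
    # D*
    v_d = (
        (n / (n - 1.0)) ** 2 * bn
        + an**2 * dn
        - 2.0 * (n * an * (an + 1.0)) / (n - 1.0) ** 2
    ) / (an**2 + bn)
    u_d = (n / (n - 1.0)) * (an - n / (n - 1.0)) - v_d
    d_star = ((n / (n - 1.0)) * eta - an * eta_s) / math.sqrt(
        u_d * eta + v_d * eta**2
    )
    # F*
    v_f = (
        dn
        + 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
        - (2.0 / (n - 1.0)) * (4.0 * bn - 6.0 + 8.0 / n)
    ) / (an**2 + bn)
    u_f = (
        (
            n / (n - 1.0)
            + (n + 1.0) / (3.0 * (n - 1.0))
            - 4.0 / (n * (n - 1.0))
            + 2.0 * (n + 1.0) / (n - 1.0) ** 2
            * (an1 - 2.0 * n / (n + 1.0))
        )
        / an
        - v_f
    )
    f_star = (ss.k_bar - ((n - 1.0) / n) * eta_s) / math.sqrt(
        u_f * eta + v_f * eta**2
    )
    return float(d_star), float(f_star)


def _log_stirling_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |S(n, k)|,
    k = 0..n, built by the additive recurrence in log space."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |S(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |S(m,k)| = (m-1)|S(m-1,k)| + |S(m-1,k-1)|
        with np.errstate(invalid="ignore"):
            grown = row + (math.log(m - 1) if m > 1 else -np.inf)
        new[1:] = np.logaddexp(grown[1:], row[:-1])
        new[0] = grown[0]
        row = new
    return row


def fu_fs(ss: SiteSummaries) -> float:
    """Fu's Fs from the Ewens sampling distribution of haplotype counts.

    ``S' = P(K >= K_obs | theta = k_bar)`` is evaluated exactly in log
    space; ``Fs = ln(S'/(1 - S'))`` is formed as a difference of
    log-partial-sums so neither tail cancels catastrophically.
    """
    n, K = ss.n, ss.K
    theta = ss.k_bar
    if theta <= 0:
        return float("nan")
    log_stir = _log_stirling_row(n)[1:]  # k = 1..n
    ks = np.arange(1, n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    log_pk = log_stir + ks * math.log(theta) - log_rising
    if K <= 1:
        # theta > 0 forces K >= 2; kept as an explicit sentinel regardless
        return float("inf")
    upper = logsumexp(log_pk[K - 1:])
    lower = logsumexp(log_pk[: K - 1])
    return float(upper - lower)


def r2_stat(ss: SiteSummaries) -> float:
    """Ramos-Onsins & Rozas R2 from per-sequence singleton loads."""
    n, S = ss.n, ss.S
    if S == 0:
        return float("nan")
    u = ss.singleton_load.astype(float)
    return float(math.sqrt(np.mean((u - ss.k_bar / 2.0) ** 2)) / S)


# ---------------------------------------------------------------------------
# one-stop wrapper
# ---------------------------------------------------------------------------

@dataclass
class NeutralityStats:
    n: int
    S: int
    k_bar: float
    theta_W: float
    eta: int
    eta_s: int
    K: int
    D: float
    D_star: float
    F_star: float
    Fs: float
    R2: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def neutrality_stats(aln) -> NeutralityStats:
    """All five statistics for one (expanded) alignment."""
    ss = site_summaries(aln)
    d_star, f_star = fu_li(ss)
    return NeutralityStats(
        n=ss.n,
        S=ss.S,
        k_bar=ss.k_bar,
        theta_W=ss.theta_W,
        eta=ss.eta,
        eta_s=ss.eta_s,
        K=ss.K,
        D=tajimas_d(ss),
        D_star=d_star,
        F_star=f_star,
        Fs=fu_fs(ss),
        R2=r2_stat(ss),
    )


__all__ = [
    "SiteSummaries",
    "NeutralityStats",
    "site_summaries",
    "tajimas_d",
    "fu_li",
    "fu_fs",
    "r2_stat",
    "neutrality_stats",
]
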