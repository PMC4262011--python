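import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from discretus import popgen as pg
from discretus.errors import InsufficientDataError
from discretus.io_core import SequenceRecord, collapse_haplotypes


# ---------------------------------------------------------------------------
# naive reference implementation (plain loops, exact integer Stirling)
# ---------------------------------------------------------------------------

def naive_clean(seqs):
    cols = []
    for j in range(len(seqs[0])):
        column = [s[j] for s in seqs]
        if all(c in "ACGT" for c in column):
            cols.append(column)
    return cols


def naive_summaries(seqs):
    n = len(seqs)
    cols = naive_clean(seqs)
    S = eta = eta_s = 0
    U = [0] * n
    diff_total = 0
    for column in cols:
        alleles = sorted(set(column))
        if len(alleles) > 1:
            S += 1
            eta += len(alleles) - 1
            singles = [a for a in alleles if column.count(a) == 1]
            budget = min(len(singles), len(alleles) - 1)
            eta_s += budget
            for a in sorted(singles)[len(singles) - budget:]:
                U[column.index(a)] += 1
    for i, j in combinations(range(n), 2):
        diff_total += sum(
            1 for column in cols if column[i] != column[j]
        )
    pairs = n * (n - 1) // 2
    k_bar = diff_total / pairs
    a1 = sum(1.0 / i for i in range(1, n))
    rows = ["".join(col[i] for col in cols) for i in range(n)]
    return {
        "n": n,
        "S": S,
        "k_bar": k_bar,
        "theta_W": S / a1,
        "eta": eta,
        "eta_s": eta_s,
        "K": len(set(rows)),
        "U": U,
    }


def naive_tajima(s):
    n, S = s["n"], s["S"]
    if S == 0 or n < 4:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (s["k_bar"] - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def naive_fu_li(s):
    n, eta, eta_s = s["n"], s["eta"], s["eta_s"]
    if s["S"] == 0 or n < 4:
        return float("nan"), float("nan")
    an = sum(1.0 / i for i in range(1, n))
    bn = sum(1.0 / i**2 for i in range(1, n))
    an1 = an + 1.0 / n
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1) ** 2 + 2 / (n - 1) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n
    )
    vd = (
        (n / (n - 1)) ** 2 * bn
        + an**2 * dn
        - 2 * (n * an * (an + 1)) / (n - 1) ** 2
    ) / (an**2 + bn)
    ud = n / (n - 1) * (an - n / (n - 1)) - vd
    dstar = (n / (n - 1) * eta - an * eta_s) / math.sqrt(
        ud * eta + vd * eta**2
    )
    vf = (
        dn
        + 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        - 2 / (n - 1) * (4 * bn - 6 + 8.0 / n)
    ) / (an**2 + bn)
    uf = (
        n / (n - 1)
        + (n + 1) / (3 * (n - 1))
        - 4.0 / (n * (n - 1))
        + 2 * (n + 1) / (n - 1) ** 2 * (an1 - 2 * n / (n + 1))
    ) / an - vf
    fstar = (s["k_bar"] - (n - 1) / n * eta_s) / math.sqrt(
        uf * eta + vf * eta**2
    )
    return dstar, fstar


def exact_stirling(n):
    """Unsigned Stirling numbers of the first kind via exact integers."""
    row = [1]  # |S(0,0)|
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            new[k] = (m - 1) * (row[k] if k < len(row) else 0) + row[k - 1]
        row = new
    return row  # |S(n, k)| for k = 0..n


def naive_fs(s):
    theta = s["k_bar"]
    if theta <= 0:
        return float("nan")
    n, K = s["n"], s["K"]
    stir = exact_stirling(n)
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    probs = [stir[k] * theta**k / rising for k in range(1, n + 1)]
    s_prime = sum(probs[K - 1:])
    return math.log(s_prime / (1.0 - s_prime))


def naive_r2(s):
    if s["S"] == 0:
        return float("nan")
    n = s["n"]
    total = sum((u - s["k_bar"] / 2.0) ** 2 for u in s["U"])
    return math.sqrt(total / n) / s["S"]


def random_alignment(rng, n=None, sites=None):
    n = n or int(rng.integers(4, 9))
    sites = sites or int(rng.integers(5, 31))
    # mixture of conserved and variable columns to get realistic S
    base = rng.choice(list("ACGT"), size=sites)
    seqs = []
    for _ in range(n):
        s = base.copy()
        mask = rng.random(sites) < 0.25
        s[mask] = rng.choice(list("ACGT"), size=int(mask.sum()))
        seqs.append("".join(s))
    return seqs


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestSiteSummaries:
    def test_identical_sequences(self):
        ss = pg.site_summaries(["ACGT"] * 4)
        assert (ss.S, ss.k_bar, ss.K) == (0, 0.0, 1)

    def test_two_sequences_one_diff(self):
        ss = pg.site_summaries(["AAAA", "AAAT"])
        assert ss.S == 1
        assert ss.k_bar == 1.0
        assert ss.theta_W == 1.0  # a1 = 1

    def test_complete_deletion(self):
        ss = pg.site_summaries(["AC-T", "ACGT", "TCGT"])
        # column 3 dropped entirely; column 1 segregating
        assert ss.S == 1

    def test_insufficient(self):
        with pytest.raises(InsufficientDataError):
            pg.site_summaries(["ACGT"])

    def test_matches_naive_scan(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            seqs = random_alignment(rng)
            ss = pg.site_summaries(seqs)
            ref = naive_summaries(seqs)
            assert ss.n == ref["n"]
            assert ss.S == ref["S"]
            assert ss.k_bar == pytest.approx(ref["k_bar"], abs=1e-12)
            assert ss.theta_W == pytest.approx(ref["theta_W"], abs=1e-12)
            assert ss.eta == ref["eta"]
            assert ss.eta_s == ref["eta_s"]
            assert ss.K == ref["K"]
            assert list(ss.singleton_load) == ref["U"]

    def test_multiplicity_expansion_keeps_s(self):
        recs = [
            SequenceRecord("a", "ACGTACGT"),
            SequenceRecord("b", "ACGTACGT"),
            SequenceRecord("c", "ACGAACGT"),
        ]
        hap = collapse_haplotypes(recs)
        s_raw = pg.site_summaries([r.seq for r in recs]).S
        s_hap = pg.site_summaries([r.seq for r in hap.records]).S
        s_exp = pg.site_summaries(hap).S
        assert s_raw == s_hap == s_exp

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=6, max_size=6),
            min_size=2,
            max_size=10,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_summaries_property(self, seqs):
        ss = pg.site_summaries(seqs)
        assert 0 <= ss.eta_s <= ss.eta
        assert ss.S <= ss.eta
        assert ss.k_bar <= ss.S + 1e-12


class TestFiveStatistics:
    def test_all_match_naive_on_random_alignments(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            seqs = random_alignment(rng)
            ss = pg.site_summaries(seqs)
            ref = naive_summaries(seqs)
            assert pg.tajimas_d(ss) == pytest.approx(
                naive_tajima(ref), abs=1e-10, nan_ok=True
            )
            d_star, f_star = pg.fu_li(ss)
            nd, nf = naive_fu_li(ref)
            assert d_star == pytest.approx(nd, abs=1e-10, nan_ok=True)
            assert f_star == pytest.approx(nf, abs=1e-10, nan_ok=True)
            assert pg.fu_fs(ss) == pytest.approx(
                naive_fs(ref), abs=1e-8, nan_ok=True
            )
            assert pg.r2_stat(ss) == pytest.approx(
                naive_r2(ref), abs=1e-10, nan_ok=True
            )

    def test_tajima_zero_numerator(self):
        # n = 2: k_bar always equals theta_W (a1 = 1), but D needs n >= 4;
        # construct a 4-sequence case with k_bar == S / a1
        # S = 2, a1 = 1+1/2+1/3 = 11/6 -> need k_bar = 12/11: not integer-
        # valued; instead verify D == 0 by direct construction of summaries
        ss = pg.SiteSummaries(
            n=6, S=3, k_bar=3 / sum(1 / i for i in range(1, 6)),
            theta_W=3 / sum(1 / i for i in range(1, 6)), eta=3, eta_s=1,
            K=4, singleton_load=np.zeros(6, dtype=int),
        )
        assert pg.tajimas_d(ss) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_when_monomorphic(self):
        ss = pg.site_summaries(["ACGT"] * 5)
        assert math.isnan(pg.tajimas_d(ss))
        assert all(math.isnan(v) for v in pg.fu_li(ss))
        assert math.isnan(pg.fu_fs(ss))
        assert math.isnan(pg.r2_stat(ss))

    def test_r2_two_sequences(self):
        ss = pg.site_summaries(["AAAA", "AAAT"])
        assert pg.r2_stat(ss) == pytest.approx(0.5)

    def test_fs_closed_form_n2(self):
        ss = pg.site_summaries(["AAAA", "AATT"])
        theta = ss.k_bar
        s_prime = theta / (1.0 + theta)
        assert pg.fu_fs(ss) == pytest.approx(
            math.log(s_prime / (1 - s_prime)), rel=1e-10
        )

    def test_dstar_zero_numerator_construction(self):
        n = 5
        an = sum(1.0 / i for i in range(1, n))
        # numerator n/(n-1)*eta - an*eta_s = 0 when eta_s/eta = n/((n-1)*an)
        eta = 25
        eta_s = n * eta / ((n - 1) * an)
        ss = pg.SiteSummaries(
            n=n, S=eta, k_bar=2.0, theta_W=eta / an, eta=eta,
            eta_s=eta_s, K=3, singleton_load=np.zeros(n, dtype=int),
        )
        d_star, _ = pg.fu_li(ss)
        assert d_star == pytest.approx(0.0, abs=1e-12)


class TestNeutralSims:
    """Directional Monte-Carlo checks on coalescent simulations."""

    @staticmethod
    def simulate_alignments(
        n_reps, initial_size=1000, growth_rate=0.0, rate=6e-7, seed=1
    ):
        import msprime

        alignments = []
        demog = msprime.Demography()
        demog.add_population(
            initial_size=initial_size, growth_rate=growth_rate
        )
        for rep in range(n_reps):
            ts = msprime.sim_ancestry(
                samples=5,
                demography=demog,
                ploidy=2,
                sequence_length=800,
                random_seed=seed + rep,
            )
            mts = msprime.sim_mutations(
                ts,
                rate=rate,
                random_seed=seed + 10_000 + rep,
                model=msprime.JC69(),
            )
            alignments.append(
                list(mts.alignments(reference_sequence="A" * 800))
            )
        return alignments

    def test_neutral_means_small(self):
        stats = [
            pg.neutrality_stats(a)
            for a in self.simulate_alignments(150, seed=5)
        ]
        d = [s.D for s in stats if not math.isnan(s.D)]
        ds = [s.D_star for s in stats if not math.isnan(s.D_star)]
        fs = [s.F_star for s in stats if not math.isnan(s.F_star)]
        assert -0.25 < float(np.mean(d)) < 0.15
        assert -0.3 < float(np.mean(ds)) < 0.2
        assert -0.3 < float(np.mean(fs)) < 0.2

    def test_growth_pushes_statistics_negative_and_r2_down(self):
        neutral = [
            pg.neutrality_stats(a)
            for a in self.simulate_alignments(80, rate=1.2e-6, seed=21)
        ]
        # recent expansion: large present-day size, star-like genealogies
        grown = [
            pg.neutrality_stats(a)
            for a in self.simulate_alignments(
                80,
                initial_size=20_000,
                growth_rate=0.005,
                rate=1.2e-6,
                seed=41,
            )
        ]

        def mean(stats, attr):
            vals = [
                getattr(s, attr)
                for s in stats
                if not math.isnan(getattr(s, attr))
            ]
            return float(np.mean(vals))

        for attr in ("D", "D_star", "F_star", "R2"):
            assert mean(grown, attr) < mean(neutral, attr)
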