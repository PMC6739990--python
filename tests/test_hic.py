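"""Hi-C balancing, decay modelling, significance and flexible FDR.

Each numerical routine is checked against an independent oracle: Sinkhorn
iteration run to convergence for ICE, exact rational tail sums for the
binomial p-values, a direct step-up computation for Benjamini-Hochberg,
and a hand-written pool-adjacent-violators pass for the monotone decay.
"""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from enchain import hic
from enchain.elements import GeneRecord, GenomicInterval
from enchain.hic import (
    calibrate_flexible_fdr,
    contact_significance,
    fit_distance_decay,
    ice_balance,
    select_low_expressed_promoters,
)
from tests.conftest import make_promoter


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def binom_upper_tail_exact(k: int, n: int, p: Fraction) -> Fraction:
    """Exact P(X >= k) for X ~ Binomial(n, p) by rational tail summation."""
    from math import comb

    if k <= 0:
        return Fraction(1)
    return sum(
        comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def bh_stepup(pvals):
    """Direct Benjamini-Hochberg step-up adjustment."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, pvals[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def pav_decreasing(y, w):
    """Weighted pool-adjacent-violators for a non-increasing fit."""
    blocks = [[yi, wi, 1] for yi, wi in zip(y, w)]  # value, weight, n points
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] < blocks[i + 1][0] - 1e-15:
            y1, w1, n1 = blocks[i]
            y2, w2, n2 = blocks[i + 1]
            blocks[i] = [(y1 * w1 + y2 * w2) / (w1 + w2), w1 + w2, n1 + n2]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    expanded = []
    for val, _, n in blocks:
        expanded.extend([val] * n)
    return np.array(expanded)


def sinkhorn_balance(mat, iters=5000):
    """Dense symmetric Sinkhorn-style iteration as an ICE oracle."""
    m = mat.astype(float).copy()
    mask = m.sum(axis=1) > 0
    for _ in range(iters):
        marg = m.sum(axis=1)
        s = np.ones_like(marg)
        s[mask] = marg[mask] / marg[mask].mean()
        m = m / np.outer(s, s)
    return m


def contacts_frame(entries):
    """entries: list of (chrom, bin_i, bin_j, count)."""
    return pd.DataFrame(entries, columns=["chrom", "bin_i", "bin_j", "count"])


# ---------------------------------------------------------------------------
# ICE
# ---------------------------------------------------------------------------

class TestIceBalance:
    def test_single_pair_already_balanced(self):
        contacts = contacts_frame([("chr1", 0, 5000, 4)])
        balanced, biases = ice_balance(contacts)
        assert balanced["balanced"].iloc[0] == pytest.approx(4.0)
        assert all(b == pytest.approx(1.0) for b in biases.values())

    def test_triangle_marginals_equalised(self):
        # smallest support admitting equal marginals (a path graph does not:
        # the middle bin's marginal is the sum of both edges)
        contacts = contacts_frame(
            [("chr1", 0, 5000, 2), ("chr1", 5000, 10000, 6), ("chr1", 0, 10000, 3)]
        )
        balanced, _ = ice_balance(contacts, max_iter=2000, tol=1e-12)
        w = dict(zip(zip(balanced.bin_i, balanced.bin_j), balanced.balanced))
        marg = np.array([
            w[(0, 5000)] + w[(0, 10000)],
            w[(0, 5000)] + w[(5000, 10000)],
            w[(5000, 10000)] + w[(0, 10000)],
        ])
        assert marg.std() / marg.mean() < 1e-9

    def test_degenerate_path_support_stays_finite(self):
        # equal marginals are infeasible on a path; the iteration must not
        # diverge and balanced totals stay on the raw scale
        contacts = contacts_frame([("chr1", 0, 5000, 2), ("chr1", 5000, 10000, 2)])
        balanced, biases = ice_balance(contacts, max_iter=500)
        assert np.isfinite(balanced["balanced"]).all()
        assert balanced["balanced"].sum() == pytest.approx(4.0)
        assert all(np.isfinite(list(biases.values())))

    def test_matches_sinkhorn_oracle(self):
        rng = np.random.default_rng(0)
        n = 12
        dense = rng.poisson(20.0, size=(n, n))
        dense = np.triu(dense, 1)
        sym = dense + dense.T
        oracle = sinkhorn_balance(sym)
        entries = [
            ("chr1", i * 5000, j * 5000, int(dense[i, j]))
            for i in range(n) for j in range(i + 1, n) if dense[i, j] > 0
        ]
        balanced, _ = ice_balance(contacts_frame(entries), max_iter=5000, tol=1e-12)
        # compare up to the raw-total rescaling our implementation applies
        got = np.zeros((n, n))
        for r in balanced.itertuples(index=False):
            got[r.bin_i // 5000, r.bin_j // 5000] = r.balanced
        got += got.T
        scale = oracle.sum() / got.sum()
        np.testing.assert_allclose(got * scale, oracle, rtol=1e-6, atol=1e-9)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty matrix"):
            ice_balance(contacts_frame([("chr1", 0, 5000, 0)]))

    def test_scaling_counts_leaves_biases_unchanged(self):
        rng = np.random.default_rng(1)
        entries = [
            ("chr1", i * 5000, j * 5000, int(rng.integers(1, 30)))
            for i in range(8) for j in range(i + 1, 8)
        ]
        _, b1 = ice_balance(contacts_frame(entries))
        scaled = contacts_frame([(c, i, j, 3 * v) for c, i, j, v in entries])
        _, b2 = ice_balance(scaled)
        for key in b1:
            assert b1[key] == pytest.approx(b2[key], rel=1e-9)

    def test_planted_biases_recovered(self):
        rng = np.random.default_rng(2)
        n = 150
        b = np.exp(0.4 * rng.standard_normal(n))
        lam = 40.0 * np.outer(b, b)
        raw = np.triu(rng.poisson(lam), 1)
        entries = [
            ("chr1", i * 5000, j * 5000, int(raw[i, j]))
            for i in range(n) for j in range(i + 1, n) if raw[i, j] > 0
        ]
        _, biases = ice_balance(contacts_frame(entries), max_iter=500, tol=1e-10)
        est = np.array([biases[("chr1", i * 5000)] for i in range(n)])
        corr = np.corrcoef(np.log(est), np.log(b))[0, 1]
        assert corr > 0.99


# ---------------------------------------------------------------------------
# decay model
# ---------------------------------------------------------------------------

def balanced_frame(rows):
    """rows: (chrom, bin_i, bin_j, balanced)"""
    df = pd.DataFrame(rows, columns=["chrom", "bin_i", "bin_j", "balanced"])
    df["count"] = df["balanced"]
    df["distance"] = df["bin_j"] - df["bin_i"]
    return df


class TestDistanceDecay:
    def test_single_distance_mean_over_total(self):
        df = balanced_frame([("chr1", 0, 5000, 2.0), ("chr1", 5000, 10000, 4.0)])
        model = fit_distance_decay(df, n_bins=1)
        assert model.total_contacts == pytest.approx(6.0)
        assert model.expected_prob[0] == pytest.approx(0.5)

    def test_monotone_input_unchanged(self):
        # two distances with probs (0.4, 0.2): already non-increasing
        df = balanced_frame([
            ("chr1", 0, 5000, 4.0), ("chr1", 0, 10000, 2.0),
        ])
        model = fit_distance_decay(df, n_bins=2)
        np.testing.assert_allclose(model.expected_prob, [4 / 6, 2 / 6])

    def test_violation_pooled_like_pav(self):
        # probs (1/3, 1/2) increasing -> pooled to equal weighted mean
        df = balanced_frame([
            ("chr1", 0, 5000, 2.0), ("chr1", 0, 10000, 3.0),
        ])
        model = fit_distance_decay(df, n_bins=2)
        oracle = pav_decreasing([2 / 5, 3 / 5], [1.0, 1.0])
        np.testing.assert_allclose(model.expected_prob, oracle)

    def test_matches_pav_oracle_on_random_profiles(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_dist = int(rng.integers(3, 15))
            # one pair per distance -> equal occupancy puts one distance per bin
            rows = [
                ("chr1", 0, (k + 1) * 5000, float(rng.uniform(0.5, 5.0)))
                for k in range(n_dist)
            ]
            df = balanced_frame(rows)
            model = fit_distance_decay(df, n_bins=n_dist)
            raw_probs = (df.sort_values("distance")["balanced"]
                         / df["balanced"].sum()).to_numpy()
            oracle = pav_decreasing(list(raw_probs), [1.0] * n_dist)
            np.testing.assert_allclose(model.expected_prob, oracle, rtol=1e-10)

    def test_distance_filter_and_error(self):
        df = balanced_frame([("chr1", 0, 5000, 1.0), ("chr1", 0, 3_000_000, 9.0)])
        model = fit_distance_decay(df)  # 3 Mb pair excluded
        assert model.total_contacts == pytest.approx(1.0)
        with pytest.raises(ValueError):
            fit_distance_decay(balanced_frame([("chr1", 0, 3_000_000, 9.0)]))

    def test_probability_mass_conserved(self):
        rng = np.random.default_rng(4)
        rows = [
            ("chr1", 0, k * 5000, float(rng.uniform(0.5, 8.0)))
            for k in range(1, 100) for _ in range(3)
        ]
        df = balanced_frame(rows)
        model = fit_distance_decay(df, n_bins=10)
        per_dist = df.groupby("distance")["balanced"].count()
        # pair counts per equal-occupancy bin via the stored edges
        edges = model.distance_bin_edges
        npairs = np.zeros(len(model.expected_prob))
        for d, n in per_dist.items():
            b = np.searchsorted(edges[1:], d, side="left")
            npairs[min(b, len(npairs) - 1)] += n
        assert float(model.expected_prob @ npairs) == pytest.approx(1.0, rel=1e-9)


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

class TestSignificance:
    def test_documented_binomial_example(self):
        # P(X >= 3) for Binomial(10, 0.1) = 0.0702 to 4 s.f.
        exact = binom_upper_tail_exact(3, 10, Fraction(1, 10))
        assert float(exact) == pytest.approx(0.0702, abs=5e-5)

    def test_pvalues_match_exact_tail_sums(self):
        model = hic.DecayModel(
            distance_bin_edges=np.array([5000.0, 10000.0]),
            expected_prob=np.array([0.1]),
            total_contacts=10.0,
        )
        rows = [("chr1", 0, 5000 + 5000 * i, float(k)) for i, k in enumerate([0, 1, 3, 7])]
        df = balanced_frame([r for r in rows if r[3] >= 0])
        df["distance"] = 5000  # single-bin model
        out = contact_significance(df, model)
        for k, p in zip([0, 1, 3, 7], out["p_value"]):
            exact = binom_upper_tail_exact(k, 10, Fraction(1, 10))
            assert p == pytest.approx(float(exact), abs=1e-10)

    def test_zero_count_p_is_one(self):
        exact = binom_upper_tail_exact(0, 10, Fraction(1, 10))
        assert float(exact) == 1.0

    def test_grid_against_rational_oracle(self):
        from scipy import stats as ss

        for n in (5, 20, 80):
            for p in (Fraction(1, 1000), Fraction(1, 10), Fraction(1, 2), Fraction(9, 10)):
                for k in range(0, n + 1, max(1, n // 7)):
                    got = float(ss.binom.sf(k - 1, n, float(p)))
                    exact = float(binom_upper_tail_exact(k, n, p))
                    assert got == pytest.approx(exact, abs=1e-10)

    def test_bh_documented_example(self):
        adj = bh_stepup(np.array([0.01, 0.02, 0.04]))
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])

    def test_bh_matches_stepup_oracle(self):
        rng = np.random.default_rng(5)
        model = hic.DecayModel(
            distance_bin_edges=np.array([5000.0, 10000.0]),
            expected_prob=np.array([0.05]),
            total_contacts=50.0,
        )
        ks = rng.integers(0, 12, size=40)
        df = balanced_frame(
            [("chr1", 0, 5000, float(k)) for k in ks]
        )
        out = contact_significance(df, model)
        oracle = bh_stepup(out["p_value"].to_numpy())
        np.testing.assert_allclose(out["q_value"].to_numpy(), oracle, rtol=1e-12)
        # q-values monotone non-decreasing in p rank
        srt = out.sort_values("p_value")
        assert (np.diff(srt["q_value"]) >= -1e-15).all()

    def test_out_of_range_contacts_excluded(self):
        model = hic.DecayModel(
            distance_bin_edges=np.array([5000.0, 10000.0]),
            expected_prob=np.array([0.1]),
            total_contacts=10.0,
        )
        df = balanced_frame([("chr1", 0, 5000, 2.0), ("chr1", 0, 50_000, 2.0)])
        out = contact_significance(df, model)
        assert len(out) == 1 and out["distance"].iloc[0] == 5000


# ---------------------------------------------------------------------------
# low-expressed promoter selection and flexible FDR
# ---------------------------------------------------------------------------

def k27me3(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestLowExpressedSelection:
    def make(self, rpkms, densities):
        genes, promoters, peaks = [], [], []
        for i, (rpkm, dens) in enumerate(zip(rpkms, densities)):
            tss = 100_000 * (i + 1)
            genes.append(GeneRecord(f"g{i}", "chr1", tss, "+", rpkm))
            promoters.append(make_promoter(f"P:g{i}", tss=tss, gene_id=f"g{i}"))
            if dens > 0:
                peaks.append(k27me3("chr1", tss - int(1000 * dens), tss))
        return genes, promoters, peaks

    def test_top_k_by_density(self):
        genes, promoters, peaks = self.make([0.5, 0.5, 0.5], [1.5, 0.5, 1.0])
        out = select_low_expressed_promoters(genes, promoters, peaks, k=2)
        assert out == ["P:g0", "P:g2"]

    def test_ties_break_by_gene_id(self):
        genes, promoters, peaks = self.make([0.5, 0.5, 0.5], [1.0, 1.0, 1.0])
        out = select_low_expressed_promoters(genes, promoters, peaks, k=2)
        assert out == ["P:g0", "P:g1"]

    def test_rpkm_one_excluded(self):
        genes, promoters, peaks = self.make([1.0, 0.99], [1.0, 1.0])
        out = select_low_expressed_promoters(genes, promoters, peaks, k=10)
        assert out == ["P:g1"]

    def test_no_low_expressed_rejected(self):
        genes, promoters, peaks = self.make([2.0, 3.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            select_low_expressed_promoters(genes, promoters, peaks)


class TestFlexibleFdr:
    def significance_frame(self, promoter_qs):
        """One contact per promoter bin with the given q-value."""
        rows = []
        for i, q in enumerate(promoter_qs):
            rows.append(
                {"chrom": "chr1", "bin_i": 100_000 * (i + 1), "bin_j": 900_000_0 + i * 5000,
                 "q_value": q}
            )
        return pd.DataFrame(rows)

    def bin_map(self, n):
        return {f"P{i}": {("chr1", 100_000 * (i + 1))} for i in range(n)}

    def test_documented_rule(self):
        # 10% of promoters flagged at 0.05, 4% at 0.01 -> choose 0.01
        qs = [0.03] * 4 + [0.008] * 2 + [1.0] * 44
        cal = calibrate_flexible_fdr(
            self.significance_frame(qs), [f"P{i}" for i in range(50)],
            self.bin_map(50), grid=[0.05, 0.01],
        )
        assert cal.chosen_threshold == 0.01

    def test_all_clean_chooses_largest(self):
        qs = [1.0] * 20
        cal = calibrate_flexible_fdr(
            self.significance_frame(qs), [f"P{i}" for i in range(20)],
            self.bin_map(20), grid=[0.05, 0.01, 0.001],
        )
        assert cal.chosen_threshold == 0.05

    def test_exact_five_percent_rejected(self):
        # exactly 1/20 = 5% flagged: strict inequality rejects the level
        qs = [0.04] + [1.0] * 19
        cal = calibrate_flexible_fdr(
            self.significance_frame(qs), [f"P{i}" for i in range(20)],
            self.bin_map(20), grid=[0.05, 0.01],
        )
        assert cal.chosen_threshold == 0.01

    def test_infeasible_reports_minimum(self):
        qs = [1e-15] * 10
        with pytest.raises(ValueError, match="minimum achievable"):
            calibrate_flexible_fdr(
                self.significance_frame(qs), [f"P{i}" for i in range(10)],
                self.bin_map(10), grid=[0.05, 0.01],
            )

    def test_fraction_flagged_monotone(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            qs = rng.uniform(0, 1, size=30)
            cal = None
            try:
                cal = calibrate_flexible_fdr(
                    self.significance_frame(qs), [f"P{i}" for i in range(30)],
                    self.bin_map(30), grid=[0.5, 0.2, 0.1, 0.05, 0.01, 0.001],
                )
            except ValueError:
                continue
            # grid decreasing => flagged fraction non-increasing
            assert (np.diff(cal.fraction_flagged) <= 1e-12).all()
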