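"""Chain metric suite: restricted betweenness (vs an exhaustive
shortest-path enumeration oracle), connectivity z-scores, CTCF motif
convergence, structural overlaps, Jaccard, persistence, and inter-chain
contacts with a shuffled control."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enchain.chains import EnhancerChain
from enchain.elements import GenomicInterval
from enchain.metrics import (
    TissueActivityVector,
    betweenness_scores,
    chain_distances,
    connectivity_counts,
    convergent_ctcf_fraction,
    inter_ec_contacts,
    rank_persistence,
    structural_overlap_fractions,
    tissue_jaccard,
)
from tests.conftest import make_enhancer, make_network, make_promoter
from tests.test_chains import random_graph_suite


def oracle_betweenness(g: nx.Graph, enhancers, promoters) -> dict:
    """Enumerate every shortest enhancer->promoter path explicitly."""
    bc = {e: 0.0 for e in enhancers}
    for s in enhancers:
        for t in promoters:
            if s == t or not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for v in enhancers:
                if v in (s, t):
                    continue
                bc[v] += sum(v in p for p in paths) / len(paths)
    return bc


class TestBetweenness:
    def test_matches_enumeration_oracle_on_500_graphs(self):
        for g, promoters in random_graph_suite(seed=46):
            net = make_network([("a", "b")], promoters)
            net.graph = g
            got = betweenness_scores(net)
            expected = oracle_betweenness(g, net.enhancers, net.promoters)
            assert set(got) == set(expected)
            for v in got:
                assert got[v] == pytest.approx(expected[v], abs=1e-12)

    def test_path_example(self):
        net = make_network([("P", "A"), ("A", "B"), ("B", "C")], {"P"})
        bc = betweenness_scores(net)
        assert bc == {"A": 2.0, "B": 1.0, "C": 0.0}

    def test_diamond_split_paths(self):
        net = make_network([("P", "A"), ("P", "B"), ("A", "C"), ("B", "C")], {"P"})
        bc = betweenness_scores(net)
        assert bc["A"] == pytest.approx(0.5) and bc["B"] == pytest.approx(0.5)
        assert bc["C"] == 0.0

    def test_single_enhancer_promoter_scores_zero(self):
        net = make_network([("P", "A")], {"P"})
        assert betweenness_scores(net) == {"A": 0.0}


class TestConnectivity:
    def test_neighbour_counts(self):
        net = make_network(
            [("P", "E"), ("E", "F"), ("E", "G")], {"P"}
        )
        records, _ = connectivity_counts([net], [])
        rec = {r.element_id: r for r in records}
        assert rec["E"].n_connected_promoters == 1
        assert rec["E"].n_connected_enhancers == 2

    def test_equal_degrees_give_zero_z(self):
        net = make_network([("P", "A"), ("P", "B")], {"P"})
        records, top = connectivity_counts([net], [])
        assert all(r.z_score == 0.0 for r in records)
        assert len(top) == 1  # degenerate argmax with < 20 enhancers

    def test_top_five_percent(self):
        nets = [
            make_network([(f"P{i}", f"E{i}")], {f"P{i}"}, network_id=f"n{i}")
            for i in range(100)
        ]
        # one high-degree enhancer
        nets[0] = make_network(
            [("P0", "E0")] + [("E0", f"X{j}") for j in range(5)], {"P0"},
            network_id="n0",
        )
        records, top = connectivity_counts(nets, [])
        assert len(top) == max(1, int(len(records) * 0.05))
        assert "E0" in top

    def test_chain_membership_counted(self):
        net = make_network([("P", "A"), ("A", "B")], {"P"})
        chain = EnhancerChain("c1", "P", ("A", "B"))
        records, _ = connectivity_counts([net], [chain])
        rec = {r.element_id: r for r in records}
        assert rec["A"].n_connected_chains == 1


class TestCtcfConvergence:
    def motifs(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )

    def pair(self, left_center, right_center, label="P-E1"):
        return (make_enhancer("L", left_center), make_enhancer("R", right_center), label)

    def test_convergent_tandem_divergent(self):
        motifs = self.motifs([
            ("chr1", 99_990, 100_010, "CTCF", 5.0, "+"),
            ("chr1", 199_990, 200_010, "CTCF", 5.0, "-"),
            ("chr1", 299_990, 300_010, "CTCF", 5.0, "+"),
            ("chr1", 399_990, 400_010, "CTCF", 5.0, "+"),
        ])
        result = convergent_ctcf_fraction(
            [self.pair(100_000, 200_000), self.pair(300_000, 400_000)], motifs
        )
        assert result["by_class"]["P-E1"]["n_pairs"] == 2
        assert result["by_class"]["P-E1"]["n_convergent"] == 1

    def test_motifless_pair_excluded_from_denominator(self):
        motifs = self.motifs([
            ("chr1", 99_990, 100_010, "CTCF", 5.0, "+"),
            ("chr1", 199_990, 200_010, "CTCF", 5.0, "-"),
        ])
        result = convergent_ctcf_fraction(
            [self.pair(100_000, 200_000), self.pair(300_000, 400_000)], motifs
        )
        assert result["fraction"] == pytest.approx(1.0)

    def test_highest_scoring_motif_wins(self):
        motifs = self.motifs([
            ("chr1", 99_990, 100_010, "CTCF", 2.0, "-"),
            ("chr1", 99_980, 100_000, "CTCF", 9.0, "+"),
            ("chr1", 199_990, 200_010, "CTCF", 5.0, "-"),
        ])
        result = convergent_ctcf_fraction([self.pair(100_000, 200_000)], motifs)
        assert result["fraction"] == pytest.approx(1.0)

    def test_invariant_to_pair_input_order(self):
        motifs = self.motifs([
            ("chr1", 99_990, 100_010, "CTCF", 5.0, "+"),
            ("chr1", 199_990, 200_010, "CTCF", 5.0, "-"),
        ])
        a = convergent_ctcf_fraction([self.pair(100_000, 200_000)], motifs)
        swapped = [(make_enhancer("R", 200_000), make_enhancer("L", 100_000), "P-E1")]
        b = convergent_ctcf_fraction(swapped, motifs)
        assert a["fraction"] == b["fraction"] == pytest.approx(1.0)


class TestStructuralOverlap:
    def setup(self):
        self.elements = {
            "P": make_promoter("P", tss=100_000),
            "E1": make_enhancer("E1", 300_000),
            "E2": make_enhancer("E2", 200_000),
        }
        self.chain = EnhancerChain("c", "P", ("E1", "E2"))
        self.ranks = {"E1": 1, "E2": 2}

    def test_loop_anchor_overlap(self):
        self.setup()
        loops = pd.DataFrame(
            [("chr1", 295_000, 305_000, "chr1", 95_000, 105_000)],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        out = structural_overlap_fractions(
            self.elements, [self.chain], [], self.ranks, loop_anchors=loops
        )
        assert out["loop_anchor_overlap"] == {"E1": 1.0, "E2": 0.0}

    def test_subtad_crossing(self):
        self.setup()
        subtads = [GenomicInterval("chr1", 0, 250_000),
                   GenomicInterval("chr1", 250_000, 500_000)]
        edges = [("P", "E1"), ("E1", "E2"), ("P", "E2")]
        out = structural_overlap_fractions(
            self.elements, [self.chain], edges, self.ranks, subtads=subtads
        )
        assert out["subtad_crossing"]["E1-P"] == 1.0   # 100k vs 300k cross
        assert out["subtad_crossing"]["E2-P"] == 0.0   # both left of 250k

    def test_tad_containment(self):
        self.setup()
        inside = [GenomicInterval("chr1", 0, 400_000)]
        out = structural_overlap_fractions(
            self.elements, [self.chain], [], self.ranks, tads=inside
        )
        assert out["tad_containment"] == 1.0
        crossing = [GenomicInterval("chr1", 0, 250_000),
                    GenomicInterval("chr1", 250_000, 400_000)]
        out = structural_overlap_fractions(
            self.elements, [self.chain], [], self.ranks, tads=crossing
        )
        assert out["tad_containment"] == 0.0


class TestJaccard:
    def vec(self, element_id, flags, panel_size=None):
        panel = tuple(f"A{i}" for i in range(len(flags)))
        return TissueActivityVector(element_id, panel, tuple(flags))

    def test_documented_values(self):
        ones = self.vec("p", [True] * 5)
        assert tissue_jaccard(ones, self.vec("e", [True] * 5)) == 1.0
        assert tissue_jaccard(
            self.vec("p", [True, True, False, False]),
            self.vec("e", [False, False, True, True]),
        ) == 0.0
        p = self.vec("p", [True] * 10 + [False] * 10)
        e = self.vec("e", [True, True] + [False] * 16 + [True, True])
        assert tissue_jaccard(p, e) == pytest.approx(2 / 12)

    def test_both_empty_is_zero(self):
        assert tissue_jaccard(self.vec("p", [False] * 4), self.vec("e", [False] * 4)) == 0.0

    def test_panel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tissue_jaccard(self.vec("p", [True] * 4), self.vec("e", [True] * 5))

    @settings(derandomize=True, max_examples=100)
    @given(a=st.lists(st.booleans(), min_size=1, max_size=20))
    def test_symmetric_bounded_and_identity(self, a):
        b = a[::-1]
        pa = self.vec("p", a)
        pb = self.vec("e", b + [False] * 0)
        if len(a) == len(b):
            j1 = tissue_jaccard(pa, self.vec("e", b))
            j2 = tissue_jaccard(self.vec("p", b), self.vec("e", a))
            assert j1 == j2 and 0.0 <= j1 <= 1.0
        j_same = tissue_jaccard(pa, self.vec("e", a))
        assert j_same == (1.0 if any(a) else 0.0)


class TestRankPersistence:
    def test_diagonal_and_absent_tallies(self):
        ranks = {
            "T1": {"A": 1, "B": 2, "C": 1},
            "T2": {"A": 1, "B": 1},
        }
        out = rank_persistence(ranks)
        counts = out["counts"]
        # ordered pairs (T1->T2) and (T2->T1)
        assert counts["E1"]["E1"] == 2   # A both ways
        assert counts["E1"]["absent"] == 1  # C in T1 -> absent in T2
        assert counts["E2"]["E1"] == 1   # B: E2 in T1 -> E1 in T2
        assert counts["E1"]["E2"] == 1   # B back: E1 in T2 -> E2 in T1

    def test_toy_fraction(self):
        ranks = {
            "T1": {"A": 1, "B": 1, "C": 1, "D": 1},
            "T2": {"A": 1, "B": 1, "C": 2, "D": 2},
        }
        out = rank_persistence(ranks)
        # T1->T2: A,B stay E1, C,D switch to E2; T2->T1: A,B stay E1
        # (C,D tally under origin E2) -> 4 of 6 E1 origins stay E1
        frac = out["fractions_excluding_absent"]["E1"]["E1"]
        assert frac == pytest.approx(4 / 6)

    def test_single_tissue_rejected(self):
        with pytest.raises(ValueError):
            rank_persistence({"T1": {"A": 1}})


class TestInterEcContacts:
    def network_with_two_chains(self, cross_edge):
        edges = [("P", "A"), ("A", "B"), ("P", "C"), ("C", "D")]
        if cross_edge:
            edges.append(("B", "D"))
        net = make_network(edges, {"P"})
        chains = [
            EnhancerChain("c1", "P", ("A", "B")),
            EnhancerChain("c2", "P", ("C", "D")),
        ]
        return net, chains

    def test_cross_edge_observed_fraction_one(self):
        net, chains = self.network_with_two_chains(cross_edge=True)
        out = inter_ec_contacts(net, chains, seed=1)
        assert out["observed_chain_pair_fraction"] == 1.0

    def test_no_cross_edges_zero(self):
        net, chains = self.network_with_two_chains(cross_edge=False)
        out = inter_ec_contacts(net, chains, seed=1)
        assert out["observed_chain_pair_fraction"] == 0.0
        assert out["observed_same_rank_fraction"] == 0.0

    def test_shuffle_reproducible(self):
        net, chains = self.network_with_two_chains(cross_edge=True)
        a = inter_ec_contacts(net, chains, seed=7)
        b = inter_ec_contacts(net, chains, seed=7)
        assert a == b

    def test_no_qualifying_pairs_returns_none(self, caplog):
        net = make_network([("P", "A"), ("A", "B")], {"P"})
        chains = [EnhancerChain("c1", "P", ("A", "B"))]
        with caplog.at_level("INFO"):
            assert inter_ec_contacts(net, chains, seed=1) is None

    def test_null_chains_observed_matches_control(self):
        # chains assigned at random -> observed fraction within the control's
        # binomial spread
        rng = np.random.default_rng(8)
        edges = [("P", f"E{i}") for i in range(6)]
        for i in range(6):
            for j in range(i + 1, 6):
                if rng.random() < 0.4:
                    edges.append((f"E{i}", f"E{j}"))
        net = make_network(edges, {"P"})
        obs, ctl = [], []
        for trial in range(40):
            ids = [f"E{i}" for i in rng.permutation(6)]
            chains = [
                EnhancerChain("c1", "P", (ids[0], ids[1])),
                EnhancerChain("c2", "P", (ids[2], ids[3])),
            ]
            out = inter_ec_contacts(net, chains, n_shuffles=5, seed=trial)
            if out is None:
                continue
            obs.append(out["observed_chain_pair_fraction"])
            ctl.append(out["control_chain_pair_fraction"])
        p_obs, p_ctl = np.mean(obs), np.mean(ctl)
        se = np.sqrt(p_ctl * (1 - p_ctl) / len(obs)) + 1e-9
        assert abs(p_obs - p_ctl) < 4 * se + 0.1


class TestChainDistances:
    def test_distance_table_and_medians(self):
        elements = {
            "P": make_promoter("P", tss=500_000),
            "E1": make_enhancer("E1", 596_000),
            "E2": make_enhancer("E2", 455_000),
        }
        chain = EnhancerChain("c", "P", ("E1", "E2"))
        table, summary = chain_distances([chain], elements)
        d = dict(zip(table["rank_class"], table["distance"]))
        assert d["E1"] == 96_000 and d["E2"] == 45_000
        signed = dict(zip(table["rank_class"], table["signed_distance"]))
        assert signed["E2"] == -45_000  # upstream side
        assert summary["median_by_class"]["E1"] == 96_000

    def test_degenerate_zero_distance(self):
        elements = {
            "P": make_promoter("P", tss=500_000),
            "E1": make_enhancer("E1", 500_000),
            "E2": make_enhancer("E2", 455_000),
        }
        chain = EnhancerChain("c", "P", ("E1", "E2"))
        table, _ = chain_distances([chain], elements)
        assert table.loc[table["rank_class"] == "E1", "distance"].iloc[0] == 0
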