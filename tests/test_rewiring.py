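"""Change counting, rate arithmetic, randomization, and null tests."""

import itertools

import numpy as np
import pytest

from prmnet.network import SpeciesNetwork
from prmnet.orthology import AlignedFamily, OrthologyMap
from prmnet.rewiring import (
    ChangeCount,
    conserved_global,
    conserved_local,
    count_protein_changes,
    estimate_rate_error,
    null_rate_test,
    randomize_network,
    rate,
    reverse_ortholog_sets,
)
from tests.conftest import make_site


def net_from(species, edges, domain_proteins=("D0", "D1")):
    return SpeciesNetwork(species, set(edges), {}, set(domain_proteins))


def identity_orth(proteins, species_list):
    return {p: {sp: {p} for sp in species_list} for p in proteins}


class TestConservedGlobal:
    def test_identical_networks_have_no_changes(self):
        edges = {("D0", "C00", f"T{i}") for i in range(10)}
        a, b = net_from("A", edges), net_from("B", edges)
        orth = identity_orth({"D0"} | {f"T{i}" for i in range(10)}, ["B"])
        cc = conserved_global(a, b, orth)
        assert (cc.conserved, cc.int_changes) == (10, 0)

    def test_empty_other_network(self):
        edges = {("D0", "C00", "T0"), ("D0", "C00", "T1")}
        a, b = net_from("A", edges), net_from("B", set())
        orth = identity_orth({"D0", "T0", "T1"}, ["B"])
        cc = conserved_global(a, b, orth)
        assert (cc.lost, cc.gained) == (2, 0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(17)
        proteins = [f"T{i}" for i in range(8)]
        # non-trivial orthology: each reference target has 1-2 orthologs
        orth = {"D0": {"B": {"D0b"}}}
        for i, p in enumerate(proteins):
            orth[p] = {"B": {f"{p}b"} | ({f"{p}b2"} if i % 3 == 0 else set())}
        ref_edges = {("D0", "C00", p) for p in rng.choice(proteins, size=5, replace=False)}
        other_pool = [o for p in proteins for o in orth[p]["B"]]
        other_edges = {
            ("D0b", "C00", o) for o in rng.choice(other_pool, size=6, replace=False)
        }
        a, b = net_from("A", ref_edges), net_from("B", other_edges)
        cc = conserved_global(a, b, orth)

        conserved = lost = 0
        for (d, c, t) in ref_edges:
            hit = any(
                (d2, c, t2) in other_edges
                for d2 in orth[d]["B"]
                for t2 in orth[t]["B"]
            )
            conserved += hit
            lost += not hit
        reverse = reverse_ortholog_sets(orth)
        gained = 0
        for (d2, c, t2) in other_edges:
            refs_d = reverse.get(("B", d2), set())
            refs_t = reverse.get(("B", t2), set())
            if refs_d and refs_t and not any(
                (d, c, t) in ref_edges for d in refs_d for t in refs_t
            ):
                gained += 1
        assert (cc.conserved, cc.lost, cc.gained) == (conserved, lost, gained)


def _local_fixture(shift: int):
    """Two species with one edge each; the other species' site is moved
    by `shift` residues."""
    L = 60
    seq = "A" * L
    fam = AlignedFamily("T0", "A", {"A": seq, "B": seq})
    ref_site = make_site(target="T0", class_id="C00", start=20, length=7)
    other_site = make_site(target="T0", class_id="C00", start=20 + shift, length=7, species="B")
    a = SpeciesNetwork("A", {("D0", "C00", "T0")}, {("D0", "C00", "T0"): [ref_site]}, {"D0"})
    b = SpeciesNetwork("B", {("D0", "C00", "T0")}, {("D0", "C00", "T0"): [other_site]}, {"D0"})
    omap = OrthologyMap("A", {"T0": {"B": ("T0", 0.5)}, "D0": {"B": ("D0", 0.5)}})
    return a, b, {"T0": fam}, omap


class TestConservedLocal:
    def test_identical_sites_conserved(self):
        a, b, fams, omap = _local_fixture(0)
        cc = conserved_local(a, b, fams, omap)
        assert (cc.conserved, cc.int_changes) == (1, 0)

    @pytest.mark.parametrize("shift,conserved", [(10, 1), (16, 1), (17, 0), (25, 0)])
    def test_window_boundary(self, shift, conserved):
        # window = site +-10 flank: starts 10..36 inclusive of other site
        a, b, fams, omap = _local_fixture(shift)
        cc = conserved_local(a, b, fams, omap)
        assert cc.conserved == conserved

    def test_missing_family_is_skipped(self):
        a, b, _, omap = _local_fixture(0)
        cc = conserved_local(a, b, {}, omap)
        assert cc.skipped >= 1 and cc.conserved == 0

    def test_matches_window_membership_oracle(self):
        rng = np.random.default_rng(23)
        L = 80
        fam = AlignedFamily("T0", "A", {"A": "A" * L, "B": "A" * L})
        for _ in range(20):
            rs = int(rng.integers(0, L - 7))
            os_ = int(rng.integers(0, L - 7))
            a, b, fams, omap = _local_fixture(0)
            a.sites[("D0", "C00", "T0")] = [make_site(target="T0", start=rs)]
            b.sites[("D0", "C00", "T0")] = [make_site(target="T0", start=os_, species="B")]
            cc = conserved_local(a, b, {"T0": fam}, omap)
            expected = max(0, rs - 10) <= os_ < min(L, rs + 7 + 10)
            assert cc.conserved == int(expected)


class TestProteinChange:
    def test_all_orthologs_present(self):
        net = net_from("A", {("D0", "C00", "T0"), ("D0", "C00", "T1")})
        orth = identity_orth({"D0", "T0", "T1"}, ["B"])
        cc = count_protein_changes(net, orth, "B")
        assert cc.int_changes == 0

    def test_lost_gene_counts_all_its_edges(self):
        net = net_from("A", {("D0", "C00", "T0"), ("D0", "C01", "T0"), ("D0", "C00", "T1")})
        orth = {"D0": {"B": {"D0"}}, "T1": {"B": {"T1"}}, "T0": {}}
        cc = count_protein_changes(net, orth, "B")
        assert (cc.lost, cc.conserved) == (2, 1)

    def test_matches_set_membership_oracle(self):
        rng = np.random.default_rng(31)
        targets = [f"T{i}" for i in range(12)]
        lost_genes = set(rng.choice(targets, size=3, replace=False))
        orth = identity_orth({"D0"} | (set(targets) - lost_genes), ["B"])
        edges = {("D0", "C00", t) for t in rng.choice(targets, size=8, replace=False)}
        cc = count_protein_changes(net_from("A", edges), orth, "B")
        expected_lost = sum(1 for _, _, t in edges if t in lost_genes)
        assert cc.lost == expected_lost


class TestRate:
    def test_zero_changes_zero_rate(self):
        assert rate(0, 5, 100, 10) == 0.0

    def test_linearity(self):
        base = rate(100, 10, 1000, 50)
        assert rate(200, 10, 1000, 50) == pytest.approx(2 * base)
        assert rate(100, 20, 1000, 50) == pytest.approx(base / 2)
        assert rate(100, 10, 1000, 100) == pytest.approx(base / 2)

    def test_invalid_denominators(self):
        for args in [(1, 0, 10, 10), (1, 5, 0, 10), (1, 5, 10, 0), (1, -5, 10, 10)]:
            with pytest.raises(ValueError):
                rate(*args)


class TestRateError:
    def test_no_errors_no_bound(self):
        assert estimate_rate_error(0, 0, 1000) == 0.0

    def test_arithmetic_and_linearity(self):
        assert estimate_rate_error(50, 41, 1_070_160) == pytest.approx(1.70e-4, rel=5e-3)
        assert estimate_rate_error(100, 82, 1_070_160) == pytest.approx(3.40e-4, rel=5e-3)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            estimate_rate_error(1, 1, 0)


class TestRandomize:
    def test_single_edge_unchanged(self):
        net = net_from("A", {("D0", "C00", "T0")})
        assert randomize_network(net, seed=1).edges == net.edges

    def test_degree_sequences_preserved(self):
        rng = np.random.default_rng(5)
        edges = {
            (f"D{i%3}", f"C0{i%3}", f"T{rng.integers(0, 15)}") for i in range(40)
        }
        net = net_from("A", edges)
        rand = randomize_network(net, seed=7)

        def degrees(es):
            out_deg, in_deg = {}, {}
            for d, c, t in es:
                out_deg[(d, c)] = out_deg.get((d, c), 0) + 1
                in_deg[t] = in_deg.get(t, 0) + 1
            return out_deg, in_deg

        assert degrees(rand.edges) == degrees(net.edges)
        assert len(rand.edges) == len(net.edges)

    def test_forced_configuration_cannot_move(self):
        # out-degrees (2,1), in-degrees (2,1): the only degree-preserving
        # edge set is the original one
        edges = {("D0", "C00", "T0"), ("D0", "C00", "T1"), ("D1", "C01", "T0")}
        net = net_from("A", edges)
        for seed in range(5):
            assert randomize_network(net, seed=seed).edges == edges

    def test_reachable_set_matches_enumeration(self):
        # perfect matching on 2x2: exactly two degree-preserving states
        edges = {("D0", "C00", "T0"), ("D1", "C01", "T1")}
        net = net_from("A", edges)
        seen = {frozenset(randomize_network(net, seed=s).edges) for s in range(30)}
        allowed = {
            frozenset(edges),
            frozenset({("D0", "C00", "T1"), ("D1", "C01", "T0")}),
        }
        assert seen == allowed


class TestNullRateTest:
    def _setup(self):
        proteins = [f"T{i}" for i in range(20)]
        # two classes so that degree-preserving swaps can actually move
        # targets between classes
        edges = {("D0", "C00", t) for t in proteins[:10]} | {
            ("D1", "C01", t) for t in proteins[10:]
        }
        orth = identity_orth({"D0", "D1"} | set(proteins), ["B"])
        return net_from("A", edges), net_from("B", set(edges)), orth

    def test_identical_networks_beat_all_nulls(self):
        a, b, orth = self._setup()
        null = null_rate_test(a, b, orth, 2, 22, 10.0, n_reps=30, seed=1)
        assert null.observed == 0.0
        assert null.p_value == pytest.approx(1 / 31)

    def test_hand_ranked_p_value(self):
        a, b, orth = self._setup()
        null = null_rate_test(a, b, orth, 2, 22, 10.0, n_reps=10, seed=3)
        expected = (1 + sum(r <= null.observed for r in null.replicates)) / 11
        assert null.p_value == pytest.approx(expected)
        assert len(null.replicates) == 10
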