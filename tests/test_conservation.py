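"""Cluster detection, in-degree, correlations, and conservation metrics."""

import math

import numpy as np
import pytest

from prmnet.conservation import (
    column_conservation,
    conservation_fraction,
    detect_clusters,
    domain_conservation_metric,
    indegree,
    sites_overlap,
    spearman,
)
from prmnet.network import SpeciesNetwork
from prmnet.orthology import AlignedFamily
from prmnet.pwm import AMINO_ACIDS, PWM
from tests.conftest import make_site


class TestDetectClusters:
    def test_single_site_single_cluster(self):
        clusters = detect_clusters([make_site(start=5)])
        assert len(clusters) == 1 and clusters[0].size == 1

    def test_half_length_overlap_threshold(self):
        # two 7-mers overlapping by 3 (< 50%): separate clusters
        a, b = make_site(start=0), make_site(start=4)
        assert not sites_overlap(a, b)
        assert len(detect_clusters([a, b])) == 2
        # overlapping by 4 (> 50%): one cluster
        c = make_site(start=3)
        assert sites_overlap(a, c)
        clusters = detect_clusters([a, c])
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_partition_and_pairwise_predicate_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            sites = [
                make_site(
                    start=int(rng.integers(0, 50)),
                    length=int(rng.integers(5, 10)),
                    class_id=f"C{rng.integers(0, 4)}",
                )
                for _ in range(int(rng.integers(1, 30)))
            ]
            clusters = detect_clusters(sites)
            emitted = [m for cl in clusters for m in cl.members]
            # partition: every input site appears exactly once
            assert len(emitted) == len(sites)
            assert {id(m) for m in emitted} == {id(s) for s in sites}
            for cl in clusters:
                for i, a in enumerate(cl.members):
                    for b in cl.members[i + 1 :]:
                        assert sites_overlap(a, b)

    def test_mixed_targets_rejected(self):
        with pytest.raises(ValueError):
            detect_clusters([make_site(target="T1"), make_site(target="T2")])


class TestIndegree:
    def test_star_and_isolated(self):
        edges = {(f"D{i}", f"C0{i}", "hub") for i in range(4)}
        net = SpeciesNetwork("A", set(edges), {}, {"D9"})
        assert indegree(net, "hub") == 4
        with pytest.raises(KeyError):
            indegree(net, "nowhere")

    def test_equals_edge_count_oracle(self):
        rng = np.random.default_rng(3)
        edges = {
            (f"D{rng.integers(0, 3)}", f"C{rng.integers(0, 3)}", f"T{rng.integers(0, 5)}")
            for _ in range(30)
        }
        net = SpeciesNetwork("A", set(edges), {}, set())
        for t in {e[2] for e in edges}:
            expected = len({(d, c) for d, c, tt in edges if tt == t})
            assert indegree(net, t) == expected


class TestConservationFraction:
    def test_everywhere_and_nowhere(self):
        edge = ("D0", "C00", "T0")
        orth = {p: {sp: {p} for sp in "BCDE"} for p in ("D0", "T0")}
        ref = SpeciesNetwork("A", {edge}, {}, {"D0"})
        nets_all = {sp: SpeciesNetwork(sp, {edge}, {}, set()) for sp in "BCDE"}
        recs = conservation_fraction(ref, nets_all, orth)
        assert recs[0].conserved_fraction == 1.0
        nets_none = {sp: SpeciesNetwork(sp, set(), {}, set()) for sp in "BCDE"}
        assert conservation_fraction(ref, nets_none, orth)[0].conserved_fraction == 0.0

    def test_hand_counted_five_species(self):
        edge = ("D0", "C00", "T0")
        orth = {p: {sp: {p} for sp in "BCDEF"} for p in ("D0", "T0")}
        ref = SpeciesNetwork("A", {edge}, {}, {"D0"})
        nets = {
            sp: SpeciesNetwork(sp, {edge} if sp in "BCD" else set(), {}, set())
            for sp in "BCDEF"
        }
        recs = conservation_fraction(ref, nets, orth)
        assert recs[0].conserved_fraction == pytest.approx(3 / 5)


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 9, 16, 25])[0] == pytest.approx(1.0)
        assert spearman(x, [5, 4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_tied_data_matches_pearson_on_midranks(self):
        from scipy import stats as ss

        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 4.0, 7.0]
        rho, _ = spearman(x, y)
        rx, ry = ss.rankdata(x), ss.rankdata(y)
        expected = float(np.corrcoef(rx, ry)[0, 1])
        assert rho == pytest.approx(expected)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestColumnConservation:
    def test_identical_gapless_column(self):
        scores = column_conservation(["AAA", "AAA", "AAA"])
        assert scores == pytest.approx([1.0, 1.0, 1.0])

    def test_all_gap_column_scores_zero(self):
        scores = column_conservation(["A-", "A-", "A-"])
        assert scores[1] == 0.0

    def test_gap_weight_arithmetic(self):
        # 2 gaps, 4 identical residues: 1 * (1 - 2/4) = 0.5
        msa = ["A", "A", "A", "A", "-", "-"]
        assert column_conservation(msa)[0] == pytest.approx(0.5)

    def test_monotone_in_gap_fraction(self):
        def score(n_gaps):
            rows = ["A"] * (6 - n_gaps) + ["-"] * n_gaps
            return column_conservation(rows)[0]

        vals = [score(g) for g in range(4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


def _metric_pwm():
    """1-position PWM with known score ladder: A=1.0, C=0.9, D=0.6."""
    adj = np.full((1, 20), 1e-4)
    adj[0, AMINO_ACIDS.index("A")] = 0.5
    adj[0, AMINO_ACIDS.index("C")] = 0.45
    adj[0, AMINO_ACIDS.index("D")] = 0.3
    return PWM.from_adjusted("m", adj)


class TestDomainConservationMetric:
    def test_fully_conserved_family_is_zero(self):
        pwm = _metric_pwm()
        rows = {sp: "QQQQQAQQQQQ" for sp in ("ref", "B", "C")}
        fam = AlignedFamily("f", "ref", rows)
        site = make_site(target="T", class_id="m", start=5, length=1, score=1.0, peptide="A")
        val = domain_conservation_metric(site, fam, pwm, {"B": 1.0, "C": 2.0}, 0.5)
        assert val.metric == pytest.approx(0.0)
        assert val.n_orthologs == 2

    def test_single_ortholog_delta_is_metric(self):
        pwm = _metric_pwm()
        fam = AlignedFamily(
            "f", "ref", {"ref": "QQQQQAQQQQQ", "B": "CCCCCCCCCCC"}
        )
        site = make_site(target="T", class_id="m", start=5, length=1, score=1.0)
        val = domain_conservation_metric(site, fam, pwm, {"B": 7.0}, 0.5)
        assert val.metric == pytest.approx(-0.1)  # best B score 0.9 vs 1.0

    def test_two_ortholog_weighted_mean_closed_form(self):
        pwm = _metric_pwm()
        fam = AlignedFamily(
            "f", "ref",
            {"ref": "QQQQQAQQQQQ", "B": "CCCCCCCCCCC", "C": "DDDDDDDDDDD"},
        )
        site = make_site(target="T", class_id="m", start=5, length=1, score=1.0)
        val = domain_conservation_metric(site, fam, pwm, {"B": 1.0, "C": 2.0}, 0.5)
        # deltas -0.1 and -0.4, weights 1 and 0.5 -> -0.2
        assert val.metric == pytest.approx((1 * -0.1 + 0.5 * -0.4) / 1.5)

    def test_invariant_to_distance_rescaling(self):
        pwm = _metric_pwm()
        fam = AlignedFamily(
            "f", "ref",
            {"ref": "QQQQQAQQQQQ", "B": "CCCCCCCCCCC", "C": "DDDDDDDDDDD"},
        )
        site = make_site(target="T", class_id="m", start=5, length=1, score=1.0)
        a = domain_conservation_metric(site, fam, pwm, {"B": 1.0, "C": 2.0}, 0.5)
        b = domain_conservation_metric(site, fam, pwm, {"B": 10.0, "C": 20.0}, 0.5)
        assert a.metric == pytest.approx(b.metric)

    def test_flooring_at_twice_worst_network_score(self):
        pwm = _metric_pwm()
        # ortholog window has only weak residues: delta would be ~ -1
        fam = AlignedFamily("f", "ref", {"ref": "QQQQQAQQQQQ", "B": "WWWWWWWWWWW"})
        site = make_site(target="T", class_id="m", start=5, length=1, score=1.0)
        val = domain_conservation_metric(site, fam, pwm, {"B": 1.0}, 0.1)
        assert val.metric == pytest.approx(-0.2)  # floored at -2 * 0.1

    def test_no_orthologs_flagged_undefined(self):
        pwm = _metric_pwm()
        fam = AlignedFamily("f", "ref", {"ref": "QQQQQAQQQQQ"})
        site = make_site(target="T", class_id="m", start=5, length=1, score=1.0)
        val = domain_conservation_metric(site, fam, pwm, {}, 0.5)
        assert val.metric is None and val.n_orthologs == 0
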