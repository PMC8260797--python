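import numpy as np
import pandas as pd
import pytest

from chemophylo import (
    build_network,
    clustering_coefficient,
    compare_coefficients,
    self_loop_summary,
)
from chemophylo.chemoprofile import CompoundCatalog
from chemophylo.olfnet import DetectionNetwork, coefficient_table
from tests.test_phylosignal import enum_ranksum_p


def toy_catalog(producing):
    """producing: dict compound -> iterable of producer species."""
    spec = pd.Series({c: "male_specific" for c in producing})
    species = sorted({s for ps in producing.values() for s in ps})
    return CompoundCatalog(
        specificity=spec,
        producing_species={c: frozenset(p) for c, p in producing.items()},
        calls=pd.DataFrame(columns=["species", "feature", "status"]),
        dimorphic_species=species,
        monomorphic_species=[],
    )


def rm_row(detector, compound, sensillum, resp):
    return {"detector": detector, "compound": compound,
            "sensillum": sensillum, "mean_response": resp, "n": 5}


def random_network(rng, n_species=8, p_edge=0.3):
    species = [f"s{i}" for i in range(n_species)]
    net = DetectionNetwork(species)
    edges = set()
    for d in species:
        for p in species:
            for sens in ("at1", "at4"):
                if rng.random() < p_edge:
                    net.add_detection(d, p, sens, f"c_{p}")
                    edges.add((d, p, sens))
    return net, species, edges


class TestBuildNetwork:
    def test_threshold_is_strict(self):
        cat = toy_catalog({"cB": ["B"]})
        rm = pd.DataFrame([rm_row("A", "cB", "at1", 10.0)])
        net = build_network(cat, rm, threshold=10.0)
        assert net.graph.number_of_edges() == 0

    def test_above_threshold_creates_edge(self):
        cat = toy_catalog({"cB": ["B"]})
        rm = pd.DataFrame([rm_row("A", "cB", "at1", 11.0)])
        net = build_network(cat, rm, threshold=10.0)
        assert net.graph.has_edge("A", "B", key="at1")
        assert not net.graph.has_edge("A", "B", key="at4")

    def test_empty_responses_gives_nodes_only(self):
        cat = toy_catalog({"cB": ["B"], "cA": ["A"]})
        rm = pd.DataFrame(columns=["detector", "compound", "sensillum",
                                   "mean_response"])
        net = build_network(cat, rm)
        assert set(net.species) == {"A", "B"}
        assert net.graph.number_of_edges() == 0

    def test_inhibitory_response_never_creates_edge(self):
        cat = toy_catalog({"cB": ["B"]})
        rm = pd.DataFrame([rm_row("A", "cB", "at1", -40.0)])
        assert build_network(cat, rm).graph.number_of_edges() == 0

    def test_unknown_compound_warns_and_is_ignored(self):
        cat = toy_catalog({"cB": ["B"]})
        rm = pd.DataFrame([rm_row("A", "mystery", "at1", 50.0)])
        with pytest.warns(UserWarning, match="absent from catalog"):
            net = build_network(cat, rm)
        assert net.graph.number_of_edges() == 0

    def test_threshold_monotone(self, rng):
        cat = toy_catalog({f"c{i}": [f"s{i}"] for i in range(6)})
        rows = [
            rm_row(f"s{d}", f"c{i}", sens, float(rng.uniform(0, 120)))
            for d in range(6) for i in range(6) for sens in ("at1", "at4")
        ]
        rm = pd.DataFrame(rows)
        prev = None
        for thr in (5.0, 10.0, 30.0, 60.0, 200.0):
            edges = set(map(
                tuple,
                build_network(cat, rm, threshold=thr)
                .edge_list()[["detector", "producer", "sensillum"]].values,
            ))
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_multi_compound_producer_counted_once(self):
        cat = toy_catalog({"c1": ["B"], "c2": ["B"]})
        rm = pd.DataFrame([rm_row("A", "c1", "at1", 50.0),
                           rm_row("A", "c2", "at1", 60.0)])
        net = build_network(cat, rm)
        assert net.detected_species("A", "at1") == {"B"}


class TestClusteringCoefficient:
    def test_all_detected(self):
        cat = toy_catalog({f"c{i}": [f"s{i}"] for i in range(6)})
        rm = pd.DataFrame([rm_row("s0", f"c{i}", "at1", 50.0)
                           for i in range(1, 6)])
        net = build_network(cat, rm)
        assert clustering_coefficient(net, "s0", "at1") == pytest.approx(1.0)

    def test_none_detected(self):
        cat = toy_catalog({f"c{i}": [f"s{i}"] for i in range(6)})
        rm = pd.DataFrame([rm_row("s0", f"c{i}", "at1", 8.0)
                           for i in range(1, 6)])
        net = build_network(cat, rm)
        assert clustering_coefficient(net, "s0", "at1") == 0.0

    def test_partial_detection(self):
        cat = toy_catalog({f"c{i}": [f"s{i}"] for i in range(6)})
        rm = pd.DataFrame([rm_row("s0", "c1", "at4", 30.0),
                           rm_row("s0", "c2", "at4", 30.0)])
        net = build_network(cat, rm)
        assert clustering_coefficient(net, "s0", "at4") == pytest.approx(0.4)

    def test_self_loop_excluded_from_both_sides(self):
        cat = toy_catalog({"c0": ["s0"], "c1": ["s1"]})
        rm = pd.DataFrame([rm_row("s0", "c0", "at1", 90.0)])
        net = build_network(cat, rm)
        assert net.has_self_loop("s0", "at1")
        assert clustering_coefficient(net, "s0", "at1") == 0.0

    def test_unknown_focal_rejected(self):
        net = DetectionNetwork(["a", "b"])
        with pytest.raises(KeyError):
            clustering_coefficient(net, "zz", "at1")

    def test_matches_bruteforce_on_random_networks(self, rng):
        for _ in range(100):
            net, species, edges = random_network(rng)
            for focal in species:
                for sens in ("at1", "at4"):
                    expected = len(
                        {p for d, p, s in edges
                         if d == focal and s == sens and p != focal}
                    ) / (len(species) - 1)
                    got = clustering_coefficient(net, focal, sens)
                    assert got == pytest.approx(expected)
                    assert 0.0 <= got <= 1.0

    def test_adding_edge_never_decreases(self, rng):
        net, species, _ = random_network(rng, p_edge=0.2)
        before = clustering_coefficient(net, "s0", "at1")
        net.add_detection("s0", "s5", "at1", "c_s5")
        assert clustering_coefficient(net, "s0", "at1") >= before


class TestSelfLoops:
    def test_per_sensillum_flags(self):
        cat = toy_catalog({"c0": ["s0"], "c1": ["s1"]})
        rm = pd.DataFrame([rm_row("s0", "c0", "at4", 70.0)])
        summary = self_loop_summary(build_network(cat, rm))
        assert not summary.loc["s0", "at1"]
        assert summary.loc["s0", "at4"]
        assert summary.attrs["totals"] == {"at1": 0, "at4": 1}

    def test_empty_network_all_false(self):
        summary = self_loop_summary(DetectionNetwork(["a", "b"]))
        assert not summary.values.any()
        assert summary.attrs["totals"] == {"at1": 0, "at4": 0}

    def test_totals_match_hand_count(self, rng):
        net, species, edges = random_network(rng)
        summary = self_loop_summary(net)
        for sens in ("at1", "at4"):
            expected = sum(1 for d, p, s in edges
                           if d == p and s == sens)
            assert summary.attrs["totals"][sens] == expected


class TestCompareCoefficients:
    def test_identical_sensilla_not_significant(self):
        net = DetectionNetwork([f"s{i}" for i in range(5)])
        for sens in ("at1", "at4"):
            net.add_detection("s0", "s1", sens, "c")
        r = compare_coefficients(net)
        assert r.p_value == pytest.approx(1.0)

    def test_extreme_separation_maximal_u(self):
        species = [f"s{i}" for i in range(5)]
        net = DetectionNetwork(species)
        for d in species:  # at1 fully connected, at4 empty
            for p in species:
                if d != p:
                    net.add_detection(d, p, "at1", f"c_{p}")
        tab = coefficient_table(net)
        assert tab["at1"].tolist() == [1.0] * 5
        assert tab["at4"].tolist() == [0.0] * 5
        r = compare_coefficients(net)
        assert r.statistic == 25.0  # every at1 value exceeds every at4 value
        assert r.p_value < 0.01

    def test_tie_free_coefficients_match_enumeration(self):
        species = [f"s{i}" for i in range(5)]
        net = DetectionNetwork(species)
        # staggered detection counts -> distinct coefficients per species
        for i, d in enumerate(species):
            for p in species[:i]:
                net.add_detection(d, p, "at1", f"c_{p}")
        at1 = coefficient_table(net)["at1"].values
        other = np.array([0.05, 0.3, 0.55, 0.8, 0.9])
        from chemophylo.phylosignal import rank_sum_test
        got = rank_sum_test(at1, other)
        assert got.p_value == pytest.approx(enum_ranksum_p(at1, other),
                                            abs=1e-12)

    def test_species_order_invariant(self, rng):
        net, species, edges = random_network(rng)
        r1 = compare_coefficients(net)
        shuffled = DetectionNetwork(list(rng.permutation(species)))
        for d, p, s in edges:
            shuffled.add_detection(d, p, s, f"c_{p}")
        r2 = compare_coefficients(shuffled)
        assert r1.statistic == r2.statistic
        assert r1.p_value == r2.p_value

    def test_too_small_panel_rejected(self):
        with pytest.raises(ValueError):
            compare_coefficients(DetectionNetwork(["only"]))
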