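"""Interaction networks: persistence, threshold knee, hubs, paths."""

import numpy as np
import pytest

from tmdkit.core_model import TrajectoryEnsemble
from tmdkit.network import (
    ContactCriteria,
    Edge,
    InteractionGraph,
    domain_hub_fractions,
    hubs,
    persistence_graph,
    residue_pair_distance,
    select_persistence_threshold,
    shortest_path,
)
from tmdkit.published_hubs import PRESTIN_HUBS, hub_table
from tmdkit.synthetic import BundleSpec, build_bundle, plant_contact_trajectory


def graph_from_edges(edge_tuples, names=None):
    nodes = sorted({r for e in edge_tuples for r in e[:2]})
    return InteractionGraph(
        edges=[Edge(*e) for e in edge_tuples],
        residue_names=names or {r: "ALA" for r in nodes},
    )


class TestPersistenceGraph:
    def test_planted_persistence_recovered_exactly(self, small_bundle):
        spec, top, ref = small_bundle
        ens, _ = plant_contact_trajectory(
            top, ref, [(1, 14, "hydrophobic", 0.5)], 100, 0
        )
        g = persistence_graph(ens, top, ContactCriteria.ca_proxy())
        e = {(e.res_a, e.res_b, e.kind): e.persistence for e in g.edges}
        assert e[(1, 14, "hydrophobic")] == pytest.approx(50.0)

    def test_far_apart_residues_no_edges(self):
        spec = BundleSpec(n_helices=2, residues_per_helix=8, bundle_radius=30.0)
        top, ref = build_bundle(spec, seed=1)
        ens = TrajectoryEnsemble(ref[None], [0.0], top)
        g = persistence_graph(ens, top, ContactCriteria.ca_proxy())
        inter_helix = [e for e in g.edges if (e.res_a <= 8) != (e.res_b <= 8)]
        assert inter_helix == []

    def test_planted_typed_edges_recovered(self, small_bundle):
        # palette positions: 1 LEU, 3 SER, 5 LYS, 8 THR, 14 VAL, 17 GLU
        spec, top, ref = small_bundle
        planted = [
            (1, 14, "hydrophobic", 1.0),
            (3, 18, "hbond", 0.8),  # SER-THR
            (5, 17, "saltbridge", 0.6),  # LYS-GLU
        ]
        ens, truth = plant_contact_trajectory(top, ref, planted, 50, 3)
        g = persistence_graph(ens, top, ContactCriteria.ca_proxy())
        got = {(e.res_a, e.res_b, e.kind): e.persistence for e in g.edges}
        for (ra, rb, kind, frac) in planted:
            key = (min(ra, rb), max(ra, rb), kind)
            assert key in got
            assert got[key] == pytest.approx(100.0 * frac, abs=100.0 / 50)

    def test_matches_brute_force_criterion_evaluation(self, small_bundle):
        # oracle: naive per-frame, per-pair, per-type loop
        spec, top, ref = small_bundle
        ens, _ = plant_contact_trajectory(
            top, ref, [(1, 14, "hydrophobic", 0.4), (3, 18, "hbond", 0.6)], 5, 7
        )
        crit = ContactCriteria.ca_proxy()
        g = persistence_graph(ens, top, crit)
        got = {(e.res_a, e.res_b, e.kind): e.persistence for e in g.edges}

        expected = {}
        protein = top.protein_residues
        for i, ra in enumerate(protein):
            for rb in protein[i + 1:]:
                if abs(ra - rb) <= 1:
                    continue
                for kind in ("hydrophobic", "hbond", "saltbridge"):
                    if not crit.pair_eligible(
                        top.residue(ra).name, top.residue(rb).name, kind
                    ):
                        continue
                    count = 0
                    for f in range(ens.n_frames):
                        pa = ens.coords[f, top.ca_index_of_residue[ra]]
                        pb = ens.coords[f, top.ca_index_of_residue[rb]]
                        if np.linalg.norm(pa - pb) <= crit.cutoff_of(kind):
                            count += 1
                    if count:
                        expected[(ra, rb, kind)] = 100.0 * count / ens.n_frames
        assert got == expected

    def test_adjacent_residues_never_connected(self, small_bundle):
        spec, top, ref = small_bundle
        ens = TrajectoryEnsemble(ref[None], [0.0], top)
        g = persistence_graph(ens, top, ContactCriteria.ca_proxy())
        assert all(abs(e.res_a - e.res_b) > 1 for e in g.edges)


class TestThresholdSelection:
    def test_knee_after_the_drop(self):
        # largest component 10 below/at 30%, 3 above -> knee at 30.5
        chain = [(i, i + 2, "hydrophobic", 30.0) for i in range(1, 19, 2)]
        strong = [(100, 102, "hydrophobic", 90.0),
                  (102, 104, "hydrophobic", 90.0)]
        g = graph_from_edges(chain + strong)
        assert select_persistence_threshold(g) == pytest.approx(30.5)

    def test_single_edge_drop(self):
        g = graph_from_edges([(1, 5, "hydrophobic", 40.0)])
        assert select_persistence_threshold(g) == pytest.approx(40.5)

    def test_flat_curve_returns_midpoint_with_warning(self):
        g = graph_from_edges(
            [(1, 3, "hydrophobic", 100.0), (3, 5, "hydrophobic", 100.0)]
        )
        with pytest.warns(UserWarning, match="flat"):
            t = select_persistence_threshold(g)
        assert t == pytest.approx(50.0)

    def test_no_hydrophobic_edges_is_an_error(self):
        g = graph_from_edges([(1, 5, "hbond", 50.0)])
        with pytest.raises(ValueError, match="hydrophobic"):
            select_persistence_threshold(g)

    def test_ties_resolve_to_lowest_threshold(self):
        # largest-component sizes: 4 (t<=20) -> 2 (t<=60) -> 0: two equal
        # drops of 2; the knee is reported after the first
        g = graph_from_edges(
            [(1, 3, "hydrophobic", 20.0), (3, 5, "hydrophobic", 20.0),
             (5, 7, "hydrophobic", 20.0), (11, 13, "hydrophobic", 60.0)]
        )
        assert select_persistence_threshold(g) == pytest.approx(20.5)


class TestHubs:
    def test_star_centre_identified(self):
        edges = [(10, 10 + 2 * k, "hydrophobic", 80.0) for k in range(1, 9)]
        g = graph_from_edges(edges)
        tab = hubs(g, threshold=50.0, hub_min_degree=7)
        assert list(tab["residue_index"]) == [10]
        assert int(tab["degree"].iloc[0]) == 8

    def test_threshold_above_max_persistence_empty(self):
        g = graph_from_edges([(1, 5, "hydrophobic", 99.0)])
        assert len(hubs(g, threshold=100.0, hub_min_degree=1)) == 0

    def test_planted_two_hub_network(self, small_bundle):
        # two residues with degree 7, everything else sparse
        hub_a, hub_b = 10, 30
        edges = [(hub_a, hub_a + 2 + k, "hydrophobic", 70.0) for k in range(7)]
        edges += [(hub_b, hub_b + 2 + k, "hbond", 70.0) for k in range(7)]
        edges += [(50, 53, "hydrophobic", 70.0)]
        g = graph_from_edges(edges)
        tab = hubs(g, threshold=50.0, hub_min_degree=7)
        assert sorted(tab["residue_index"]) == [hub_a, hub_b]

    def test_degree_counts_each_type_separately(self):
        edges = [
            (1, 5, "hydrophobic", 80.0),
            (1, 5, "hbond", 80.0),
            (1, 7, "hydrophobic", 80.0),
        ]
        g = graph_from_edges(edges)
        tab = hubs(g, threshold=0.0, hub_min_degree=3)
        assert list(tab["residue_index"]) == [1]
        assert int(tab["degree"].iloc[0]) == 3

    def test_monotone_filtration(self):
        rng = np.random.default_rng(2)
        edges = []
        for _ in range(60):
            a, b = rng.choice(np.arange(1, 40, 3), size=2, replace=False)
            edges.append(
                (int(min(a, b)), int(max(a, b)), "hydrophobic",
                 float(rng.uniform(5, 95)))
            )
        edges = list({(a, b, k): (a, b, k, p) for a, b, k, p in edges}.values())
        g = graph_from_edges(edges)
        prev = None
        for t in np.linspace(0, 100, 21):
            tab = hubs(g, threshold=t, hub_min_degree=1)
            degrees = dict(zip(tab["residue_index"], tab["degree"]))
            if prev is not None:
                for r, d in degrees.items():
                    assert d <= prev.get(r, 0) or prev.get(r) is None
                    if r in prev:
                        assert d <= prev[r]
            prev = degrees


class TestDomainHubFractions:
    @pytest.mark.parametrize(
        "system,expected",
        [("rI", (58, 42)), ("rO", (43, 57)), ("zI", (83, 17)), ("zO", (75, 25))],
    )
    def test_published_tables_reproduce_reported_percentages(self, system, expected):
        assert domain_hub_fractions(hub_table(system)) == expected

    def test_all_core_is_100_0(self):
        import pandas as pd

        tab = pd.DataFrame(
            {"residue_index": [1, 2], "residue_name": ["ALA", "VAL"],
             "degree": [7, 7], "domain": ["core", "core"]}
        )
        assert domain_hub_fractions(tab) == (100, 0)

    def test_unmapped_residue_is_an_error(self):
        import pandas as pd

        tab = pd.DataFrame(
            {"residue_index": [1], "residue_name": ["ALA"],
             "degree": [7], "domain": [None]}
        )
        with pytest.raises(ValueError, match="residue 1"):
            domain_hub_fractions(tab)

    def test_percentages_sum_to_100(self):
        import pandas as pd

        for n_core in range(0, 8):
            rows = [
                {"residue_index": i, "residue_name": "ALA", "degree": 7,
                 "domain": "core" if i < n_core else "gate"}
                for i in range(7)
            ]
            c, g = domain_hub_fractions(pd.DataFrame(rows))
            assert c + g == 100


class TestShortestPath:
    def test_chain_path(self):
        g = graph_from_edges(
            [(1, 3, "hydrophobic", 80.0), (3, 5, "hydrophobic", 80.0)]
        )
        paths = shortest_path(g, 50.0, 1, 5)
        assert paths == [[1, 3, 5]]

    def test_planted_geodesic_passes_through_bridge(self):
        # r5 is the unique bridge between two cliques around r1 and r9
        edges = [(1, 3, "hydrophobic", 90.0), (1, 5, "hydrophobic", 90.0),
                 (3, 5, "hydrophobic", 90.0), (5, 9, "hydrophobic", 90.0),
                 (9, 11, "hydrophobic", 90.0)]
        g = graph_from_edges(edges)
        paths = shortest_path(g, 50.0, 1, 9)
        assert all(5 in p for p in paths)

    def test_identical_endpoints(self):
        g = graph_from_edges([(1, 3, "hydrophobic", 80.0)])
        assert shortest_path(g, 0.0, 1, 1) == [[1]]

    def test_disconnected_pair_returns_empty(self):
        g = graph_from_edges(
            [(1, 3, "hydrophobic", 80.0), (10, 12, "hydrophobic", 80.0)]
        )
        assert shortest_path(g, 0.0, 1, 12) == []


class TestResiduePairDistance:
    def test_static_ca_distance_constant(self, small_bundle):
        spec, top, ref = small_bundle
        coords = ref.copy()
        ca1, ca2 = top.ca_index_of_residue[1], top.ca_index_of_residue[14]
        coords[ca2] = coords[ca1] + np.array([28.0, 0.0, 0.0])
        ens = TrajectoryEnsemble(np.repeat(coords[None], 4, axis=0),
                                 np.arange(4.0), top)
        d = residue_pair_distance(ens, top, 1, 14, scheme="ca")
        assert np.allclose(d, 28.0)

    def test_same_residue_all_zero(self, static_ensemble, small_bundle):
        _, top, _ = small_bundle
        d = residue_pair_distance(static_ensemble, top, 5, 5)
        assert np.allclose(d, 0.0)

    def test_scripted_approach_ramp(self, small_bundle):
        spec, top, ref = small_bundle
        F = 100
        coords = np.repeat(ref[None], F, axis=0)
        ca1, ca2 = top.ca_index_of_residue[1], top.ca_index_of_residue[14]
        ramp = np.linspace(30.0, 4.0, F)
        for f in range(F):
            coords[f, ca2] = coords[f, ca1] + np.array([ramp[f], 0.0, 0.0])
        ens = TrajectoryEnsemble(coords, np.arange(float(F)), top)
        d = residue_pair_distance(ens, top, 1, 14, scheme="ca")
        assert np.allclose(d, ramp, atol=1e-9)

    def test_unknown_residue_rejected(self, static_ensemble, small_bundle):
        _, top, _ = small_bundle
        with pytest.raises(ValueError):
            residue_pair_distance(static_ensemble, top, 1, 9999)


class TestPublishedHubTables:
    def test_row_counts_match_reported_tables(self):
        assert len(PRESTIN_HUBS["rI"]) == 19
        assert len(PRESTIN_HUBS["rO"]) == 7
        assert len(PRESTIN_HUBS["zI"]) == 12
        assert len(PRESTIN_HUBS["zO"]) == 8

    def test_every_degree_reaches_hub_cutoff(self):
        for rows in PRESTIN_HUBS.values():
            assert all(deg >= 7 for (_, _, deg, _) in rows)
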