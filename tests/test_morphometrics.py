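"""Morphometrics against generator ground truth and geometric invariances."""

import numpy as np
import pytest
from scipy import stats

from dendrocensus.morphometrics import (
    apical_width,
    compartment_length,
    compute_morphometrics,
)
from dendrocensus.skeleton import Compartment, SkeletonGraph
from dendrocensus.synth_neurons import (
    InfeasibleSpecError,
    SyntheticNeuronSpec,
    generate_cohort,
    generate_synthetic_neuron,
)

GT_FIELDS = ["soma_depth", "height", "total_apical_length", "apical_width",
             "total_basal_length", "basal_bias"]


def straight_chain(n_edges, compartment, start=(0.0, 100.0, 0.0), step=(0, 1.0, 0)):
    pos = [np.array(start, float)]
    comp = [int(Compartment.SOMA)]
    parents = [-1]
    for i in range(n_edges):
        pos.append(pos[-1] + np.array(step))
        comp.append(int(compartment))
        parents.append(i + 1)
    n = len(pos)
    return SkeletonGraph(np.arange(1, n + 1), np.array(pos), np.full(n, np.nan),
                         np.array(comp), np.array(parents))


class TestCompartmentLength:
    def test_straight_polyline_of_unit_edges(self):
        g = straight_chain(30, Compartment.APICAL, step=(0, -1.0, 0))
        assert compartment_length(g, Compartment.APICAL) == pytest.approx(30.0)

    def test_empty_compartment_is_zero(self):
        g = straight_chain(5, Compartment.APICAL)
        assert compartment_length(g, Compartment.BASAL) == 0.0

    def test_realistic_apical_length_round_trip(self):
        # 1423 μm is a realistic superficial-layer mean apical length
        spec = SyntheticNeuronSpec(
            soma_position=(0.0, 300.0, 0.0), apical_total_length=1423.0,
            apical_width=1423.0 - 280.0, tuft_class="tufted",
            basal_total_length=1200.0, basal_bias=10.0, oblique_count=2,
            height=480.0, seed=4,
        )
        g = generate_synthetic_neuron(spec)
        assert compartment_length(g, Compartment.APICAL) == pytest.approx(
            1423.0, abs=1e-6
        )


class TestApicalWidth:
    def test_three_four_five(self):
        g = SkeletonGraph(
            [1, 2, 3],
            [[5, 100, 5], [0, 90, 0], [3, 95, 4]],
            [np.nan] * 3,
            [Compartment.SOMA, Compartment.APICAL, Compartment.APICAL],
            [-1, 1, 2],
        )
        assert apical_width(g) == pytest.approx(5.0)

    def test_single_apical_node_is_zero(self):
        g = straight_chain(1, Compartment.APICAL, step=(0, -1.0, 0))
        g2 = straight_chain(1, Compartment.BASAL)
        assert apical_width(g2) == 0.0

    def test_matches_brute_force_on_random_tuft(self, rng):
        pts = rng.normal(size=(100, 3)) * [50, 5, 50]
        n = len(pts) + 1
        g = SkeletonGraph(
            np.arange(1, n + 1),
            np.vstack([[0, 0, 0], pts]),
            np.full(n, np.nan),
            np.array([1] + [4] * (n - 1)),
            np.array([-1] + [1] * (n - 1)),
        )
        xz = pts[:, [0, 2]]
        brute = max(
            np.linalg.norm(xz[i] - xz[j])
            for i in range(len(xz))
            for j in range(i + 1, len(xz))
        )
        assert apical_width(g) == pytest.approx(brute, abs=1e-9)


class TestComputeMorphometrics:
    def test_depth_and_height_definitions(self):
        g = straight_chain(0, Compartment.APICAL, start=(0.0, 120.0, 0.0))
        # add nodes spanning y in [10, 310]
        g = SkeletonGraph(
            [1, 2, 3],
            [[0, 120, 0], [0, 10, 0], [0, 310, 0]],
            [np.nan] * 3,
            [Compartment.SOMA, Compartment.APICAL, Compartment.BASAL],
            [-1, 1, 1],
        )
        rec = compute_morphometrics(g)
        assert rec.soma_depth == pytest.approx(120.0)
        assert rec.height == pytest.approx(300.0)

    def test_basal_bias_sign_convention(self):
        # symmetric basal arbor centred 20 μm above the soma -> bias = -20
        g = SkeletonGraph(
            [1, 2, 3],
            [[0, 100, 0], [-10, 80, 0], [10, 80, 0]],
            [np.nan] * 3,
            [Compartment.SOMA, Compartment.BASAL, Compartment.BASAL],
            [-1, 1, 1],
        )
        rec = compute_morphometrics(g)
        assert rec.basal_bias == pytest.approx(-10.0)  # midpoints at y=90
        spec = SyntheticNeuronSpec(
            soma_position=(0.0, 400.0, 0.0), apical_total_length=450.0,
            apical_width=100.0, tuft_class="tufted", basal_total_length=1400.0,
            basal_bias=-20.0, oblique_count=0, height=500.0, seed=1,
        )
        rec2 = compute_morphometrics(generate_synthetic_neuron(spec))
        assert rec2.basal_bias == pytest.approx(-20.0, abs=1e-6)

    def test_round_trip_on_cohort(self, feasible_specs, volume_frame):
        for spec in feasible_specs[:10]:
            g = generate_synthetic_neuron(spec, volume=volume_frame)
            rec = compute_morphometrics(g, frame=volume_frame)
            for k, v in spec.ground_truth().items():
                assert getattr(rec, k) == pytest.approx(v, abs=1e-6), k

    def test_axon_nodes_ignored(self):
        g = SkeletonGraph(
            [1, 2, 3],
            [[0, 100, 0], [0, 90, 0], [0, 1000, 0]],
            [np.nan] * 3,
            [Compartment.SOMA, Compartment.BASAL, Compartment.AXON],
            [-1, 1, 1],
        )
        rec = compute_morphometrics(g)
        assert rec.height == pytest.approx(10.0)

    def test_missing_soma_is_structural_error(self):
        g = straight_chain(3, Compartment.BASAL)
        g.compartments[0] = int(Compartment.BASAL)
        with pytest.raises(Exception, match="soma"):
            compute_morphometrics(g)

    def test_no_basal_edges_flags_undefined_bias(self):
        g = straight_chain(5, Compartment.APICAL, step=(0, -1.0, 0))
        assert compute_morphometrics(g).basal_bias is None


class TestInvariances:
    def test_y_rotation_and_translation(self, feasible_specs):
        g = generate_synthetic_neuron(feasible_specs[2])
        base = compute_morphometrics(g)
        th = 0.7
        c, s = np.cos(th), np.sin(th)
        rot = g.copy()
        x, z = g.positions[:, 0], g.positions[:, 2]
        rot.positions[:, 0] = c * x + s * z
        rot.positions[:, 2] = -s * x + c * z
        r1 = compute_morphometrics(rot)
        for f in GT_FIELDS:
            assert getattr(r1, f) == pytest.approx(getattr(base, f), abs=1e-8)

        tr = g.copy()
        tr.positions = tr.positions + [55.0, 0.0, -20.0]
        r2 = compute_morphometrics(tr)
        for f in GT_FIELDS:
            assert getattr(r2, f) == pytest.approx(getattr(base, f), abs=1e-8)

        tr.positions[:, 1] += 33.0
        r3 = compute_morphometrics(tr)
        assert r3.soma_depth == pytest.approx(base.soma_depth + 33.0)
        for f in ["height", "total_apical_length", "total_basal_length",
                  "basal_bias", "apical_width"]:
            assert getattr(r3, f) == pytest.approx(getattr(base, f), abs=1e-8)

    def test_edge_subdivision_changes_nothing(self, feasible_specs):
        g = generate_synthetic_neuron(feasible_specs[3])
        base = compute_morphometrics(g)
        # insert a midpoint into every edge
        edges = g.edges()
        ids = list(g.ids)
        pos = list(g.positions)
        comp = list(g.compartments)
        par = list(g.parents)
        next_id = int(g.ids.max()) + 1
        for p_row, c_row in edges:
            mid = 0.5 * (g.positions[p_row] + g.positions[c_row])
            ids.append(next_id)
            pos.append(mid)
            comp.append(g.compartments[c_row])
            par.append(int(g.ids[p_row]))
            par[c_row] = next_id
            next_id += 1
        g2 = SkeletonGraph(np.array(ids), np.array(pos),
                           np.full(len(ids), np.nan), np.array(comp),
                           np.array(par))
        rec = compute_morphometrics(g2)
        for f in GT_FIELDS:
            assert getattr(rec, f) == pytest.approx(getattr(base, f), abs=1e-9)


class TestCohortTrends:
    def test_injected_depth_width_trend_recovered(self):
        specs, graphs = generate_cohort(100, seed=3, depth_width_slope=-0.4)
        depths = [s.soma_position[1] for s in specs]
        widths = [compute_morphometrics(g).apical_width for g in graphs]
        rho = stats.spearmanr(depths, widths).statistic
        assert rho < -0.5

    def test_depth_height_positive_correlation(self):
        specs, graphs = generate_cohort(80, seed=4)
        depths = [s.soma_position[1] for s in specs]
        heights = [compute_morphometrics(g).height for g in graphs]
        assert stats.spearmanr(depths, heights).statistic > 0.5


def test_infeasible_specs_rejected():
    with pytest.raises(InfeasibleSpecError):
        generate_synthetic_neuron(
            SyntheticNeuronSpec(
                soma_position=(0, 400.0, 0), apical_total_length=100.0,
                apical_width=50.0, tuft_class="tufted",
                basal_total_length=1000.0, basal_bias=0.0, oblique_count=0,
                height=400.0, seed=0,
            )
        )  # tufted apical far too short to approach the pia
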