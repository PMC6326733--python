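"""Multilevel simulation model: edge equation, designs, calibration."""

import numpy as np
import pytest

from connsim._rng import substream
from connsim.groundtruth import ConfigurationError
from connsim.simulate import (
    CalibrationError,
    DesignError,
    ExperimentDesign,
    NodeManipulation,
    NoiseParams,
    calibrate_negative_shift,
    make_module_design,
    make_whack_design,
    simulate_cohort,
    simulate_subject,
)

SILENT = NoiseParams(sigma_b=0, sigma_w=0, sigma_e=0)


def design(groundtruth, manipulations=(), noise=SILENT, **kw):
    return ExperimentDesign(
        n_patients=kw.pop("n_patients", 3),
        n_controls=kw.pop("n_controls", 3),
        noise=noise,
        manipulations=manipulations,
        n_replications=1,
        seed=kw.pop("seed", 0),
    )


class TestEdgeEquation:
    def test_all_zero_variances_reproduce_groundtruth(self, small_groundtruth):
        d = design(small_groundtruth)
        subj = simulate_subject(small_groundtruth, d, "patient", substream(0, 1))
        np.testing.assert_array_equal(subj.values, small_groundtruth.values)

    def test_sigma_b_shifts_every_edge_by_the_same_constant(self, small_groundtruth):
        d = design(small_groundtruth, noise=NoiseParams(sigma_b=0.2, sigma_w=0, sigma_e=0))
        subj = simulate_subject(small_groundtruth, d, "control", substream(0, 2))
        n = small_groundtruth.n_nodes
        iu = np.triu_indices(n, k=1)
        w = small_groundtruth.values[iu]
        unclipped = np.abs(w + subj.b_s) < 0.999  # strong edges may clip
        diffs = subj.values[iu] - w
        assert unclipped.mean() > 0.9
        assert np.ptp(diffs[unclipped]) < 1e-12
        assert diffs[unclipped][0] == pytest.approx(subj.b_s)
        assert abs(subj.b_s) > 0

    def test_pure_shift_raises_incident_edges_exactly(self, small_groundtruth):
        targets = (2, 5, 9)
        man = NodeManipulation(targets, mu_a=0.14, sigma_a=0, sigma_v=0)
        d = design(small_groundtruth, (man,))
        subj = simulate_subject(small_groundtruth, d, "patient", substream(0, 3))
        delta = subj.values - small_groundtruth.values
        n = small_groundtruth.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                touched = i in targets or j in targets
                expected = 0.14 if touched else 0.0
                assert delta[i, j] == pytest.approx(expected), (i, j)

    def test_edge_between_two_targets_shifted_once_not_twice(self, small_groundtruth):
        man = NodeManipulation((2, 5), mu_a=0.14, sigma_a=0, sigma_v=0)
        d = design(small_groundtruth, (man,))
        subj = simulate_subject(small_groundtruth, d, "patient", substream(0, 4))
        delta = subj.values - small_groundtruth.values
        assert delta[2, 5] == pytest.approx(0.14)  # not 0.28

    def test_control_group_untouched_by_patient_manipulation(self, small_groundtruth):
        man = NodeManipulation((2,), mu_a=0.5, sigma_a=0, sigma_v=0)
        d = design(small_groundtruth, (man,))
        subj = simulate_subject(small_groundtruth, d, "control", substream(0, 5))
        np.testing.assert_array_equal(subj.values, small_groundtruth.values)

    def test_monte_carlo_mean_matches_analytic_expectation(self, small_groundtruth):
        # empirical mean of r_ijs over many subjects ~ w_ij + mu_a on
        # targeted edges, within 3 standard errors
        noise = NoiseParams(sigma_b=0.05, sigma_w=0.05, sigma_e=0.05)
        man = NodeManipulation((0,), mu_a=0.1, sigma_a=0.05, sigma_v=0.05)
        d = ExperimentDesign(n_patients=2, n_controls=2, noise=noise,
                             manipulations=(man,), n_replications=1, seed=0)
        n_draws = 1000
        rng = substream(0, 6)
        target_edge = np.empty(n_draws)
        untouched_edge = np.empty(n_draws)
        for k in range(n_draws):
            subj = simulate_subject(small_groundtruth, d, "patient", rng)
            target_edge[k] = subj.values[0, 7]
            untouched_edge[k] = subj.values[3, 7]
        w = small_groundtruth.values
        sd_edge = np.sqrt(0.05**2 * 3 + 0.05**2 + 0.05**2)  # b,u,e + a,v
        se = sd_edge / np.sqrt(n_draws)
        assert abs(target_edge.mean() - (w[0, 7] + 0.1)) < 3 * se
        assert abs(untouched_edge.mean() - w[3, 7]) < 3 * se

    def test_variance_decomposition_at_untargeted_edge(self, small_groundtruth):
        noise = NoiseParams(sigma_b=0.1, sigma_w=0.07, sigma_e=0.05)
        d = design(small_groundtruth, noise=noise)
        rng = substream(0, 7)
        vals = np.array([
            simulate_subject(small_groundtruth, d, "patient", rng).values[1, 4]
            for _ in range(1500)
        ])
        expected_var = 0.1**2 + 0.07**2 + 0.05**2
        assert vals.var(ddof=1) == pytest.approx(expected_var, rel=0.15)

    def test_symmetry_and_finiteness_with_all_components_active(self, small_groundtruth):
        man = NodeManipulation((1, 2), mu_a=0.3, sigma_a=0.1, sigma_v=0.1)
        d = design(small_groundtruth, (man,), noise=NoiseParams(0.2, 0.2, 0.2))
        subj = simulate_subject(small_groundtruth, d, "patient", substream(0, 8))
        np.testing.assert_array_equal(subj.values, subj.values.T)
        assert np.isfinite(subj.values).all()
        assert np.abs(subj.values[~np.eye(subj.n_nodes, dtype=bool)]).max() <= 0.999

    def test_proportional_mode_leaves_zero_strength_edges_unshifted(self, small_partition):
        from connsim.groundtruth import GroundTruthMatrix

        n = small_partition.n_nodes
        w = np.full((n, n), 0.2)
        w[0, 1] = w[1, 0] = 0.0  # a dead edge on the targeted node
        np.fill_diagonal(w, 1.0)
        same = small_partition.assignments[:, None] == small_partition.assignments[None, :]
        w[~same] = 0.1
        gt = GroundTruthMatrix(values=(w + w.T) / 2, partition=small_partition)
        man = NodeManipulation((0,), mu_a=0.1, sigma_a=0, sigma_v=0, mode="proportional")
        d = design(gt, (man,))
        subj = simulate_subject(gt, d, "patient", substream(0, 9))
        assert subj.values[0, 1] == 0.0
        assert subj.values[0, 2] > gt.values[0, 2]


class TestCohort:
    def test_cohort_counts_and_groups(self, small_groundtruth):
        d = ExperimentDesign(n_patients=5, n_controls=4, noise=NoiseParams(),
                             n_replications=1, seed=1)
        cohort = simulate_cohort(small_groundtruth, d, replication_id=0)
        assert cohort.n_subjects == 9
        assert (cohort.groups == "patient").sum() == 5
        assert (cohort.groups == "control").sum() == 4

    def test_same_seed_and_replication_reproduce_cohort(self, small_groundtruth):
        d = ExperimentDesign(noise=NoiseParams(), n_replications=2, seed=3,
                             n_patients=3, n_controls=3)
        a = simulate_cohort(small_groundtruth, d, replication_id=1)
        b = simulate_cohort(small_groundtruth, d, replication_id=1)
        np.testing.assert_array_equal(a.edge_values, b.edge_values)
        np.testing.assert_array_equal(a.b_s, b.b_s)

    def test_replications_are_independent_substreams(self, small_groundtruth):
        d = ExperimentDesign(noise=NoiseParams(), n_replications=2, seed=3,
                             n_patients=3, n_controls=3)
        a = simulate_cohort(small_groundtruth, d, replication_id=1)
        b = simulate_cohort(small_groundtruth, d, replication_id=2)
        assert not np.array_equal(a.b_s, b.b_s)

    def test_export_cohort_writes_matrices_and_manifest(self, small_groundtruth, tmp_path):
        import pandas as pd

        from connsim.groundtruth import load_partition
        from connsim.simulate import export_cohort

        d = ExperimentDesign(noise=NoiseParams(), n_replications=1, seed=8,
                             n_patients=2, n_controls=2)
        cohort = simulate_cohort(small_groundtruth, d, replication_id=3)
        manifest = export_cohort(cohort, tmp_path)
        assert list(manifest.columns) == ["subject_id", "group", "file", "b_s"]
        assert len(manifest) == 4
        on_disk = pd.read_csv(tmp_path / manifest.file.iloc[0], sep="\t", index_col=0)
        np.testing.assert_allclose(on_disk.to_numpy(), cohort.matrix(0), atol=1e-9)
        np.testing.assert_allclose(manifest.b_s.to_numpy(), cohort.b_s)

    def test_subject_matrices_roundtrip(self, small_groundtruth):
        d = ExperimentDesign(noise=NoiseParams(), n_replications=1, seed=4,
                             n_patients=2, n_controls=2)
        cohort = simulate_cohort(small_groundtruth, d, replication_id=0)
        subj = cohort.subjects[0]
        np.testing.assert_array_equal(subj.values, subj.values.T)
        assert subj.group == "patient"


class TestDesigns:
    def test_whack_sets_disjoint_and_sized(self, small_groundtruth):
        d = make_whack_design(small_groundtruth, seed=5)
        sets = [set(v.tolist()) for v in d.node_classes.values()]
        assert all(len(s) == 3 for s in sets)
        assert len(sets[0] | sets[1] | sets[2]) == 9
        assert [m.mu_a for m in d.manipulations] == [0.14, -0.04]
        assert [m.sigma_a for m in d.manipulations] == [0.07, 0.02]

    def test_whack_flipped_swaps_signs(self, small_groundtruth):
        d = make_whack_design(small_groundtruth, flipped=True, seed=5)
        assert [m.mu_a for m in d.manipulations] == [-0.14, 0.04]

    def test_whack_capacity_bound(self, small_groundtruth):
        make_whack_design(small_groundtruth, n_each=13, seed=0)  # 39 <= 40
        with pytest.raises(DesignError):
            make_whack_design(small_groundtruth, n_each=14, seed=0)

    def test_module_design_targets_and_scopes(self, small_groundtruth):
        d = make_module_design(small_groundtruth, seed=6)
        part = small_groundtruth.partition
        fpn_dan = set(part.nodes_of("FPN")) | set(part.nodes_of("DAN"))
        by_label = {m.label: m for m in d.manipulations}
        assert set(by_label["FPN+DAN between"].target_nodes) == fpn_dan
        assert set(by_label["DMN within"].target_nodes) == set(part.nodes_of("DMN"))
        assert by_label["FPN+DAN between"].group == "control"
        assert by_label["DMN between"].group == "patient"
        assert by_label["DMN between"].mu_a == 0.2
        assert by_label["DMN within"].mu_a == 0.1

    def test_module_design_zero_sd_shifts_exact(self, small_groundtruth):
        d = make_module_design(
            small_groundtruth, seed=7, noise=SILENT,
            sigma_a_between=0, sigma_v_between=0, sigma_a_within=0, sigma_v_within=0,
        )
        subj = simulate_subject(small_groundtruth, d, "control", substream(0, 10))
        delta = subj.values - small_groundtruth.values
        part = small_groundtruth.partition
        fpn = part.nodes_of("FPN")
        vis = part.nodes_of("Visual")
        dmn = part.nodes_of("DMN")
        # between-scope FPN edge to another network: exactly +0.2
        assert delta[fpn[0], vis[0]] == pytest.approx(0.2)
        # within-FPN edge: +0.1
        assert delta[fpn[0], fpn[1]] == pytest.approx(0.1)
        # Visual-Visual edge untouched in both groups
        assert delta[vis[0], vis[1]] == 0.0
        # DMN edges untouched in controls (DMN-to-FPN is an FPN between edge)
        assert delta[dmn[0], dmn[1]] == 0.0

    def test_module_design_missing_label_is_design_error(self, small_groundtruth):
        from connsim.groundtruth import generate_groundtruth, generate_partition

        part = generate_partition(20, module_sizes=[10, 10])  # DMN, FPN only
        gt = generate_groundtruth(part, n_timepoints=200, seed=0)
        with pytest.raises(DesignError, match="DAN"):
            make_module_design(gt, seed=0)

    def test_overlapping_same_scope_targets_rejected(self):
        with pytest.raises(DesignError, match="share target nodes"):
            ExperimentDesign(
                manipulations=(
                    NodeManipulation((1, 2), 0.1),
                    NodeManipulation((2, 3), 0.2),
                ),
            )

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            NodeManipulation((1,), 0.1, sigma_a=-0.1)
        with pytest.raises(ConfigurationError):
            NoiseParams(sigma_b=-1)

    def test_target_out_of_range_rejected(self, small_groundtruth):
        man = NodeManipulation((99,), 0.1)
        d = design(small_groundtruth, (man,))
        with pytest.raises(DesignError, match="out of range"):
            simulate_subject(small_groundtruth, d, "patient", substream(0, 11))


class TestCalibration:
    def test_mean_p_monotone_in_shift_magnitude(self, small_groundtruth):
        from connsim.simulate import _weighted_negative_mean_p

        template = {"shift_positive": 0.14, "n_each": 3, "n_patients": 20,
                    "n_controls": 20, "noise": NoiseParams(0.05, 0.1, 0.1)}
        ps = [
            _weighted_negative_mean_p(small_groundtruth, template, s, 6, seed=1)[0]
            for s in (0.0, -0.05, -0.15)
        ]
        assert ps[0] > ps[1] > ps[2]

    def test_near_null_target_returns_small_shift(self, small_groundtruth):
        res = calibrate_negative_shift(
            small_groundtruth,
            {"n_patients": 20, "n_controls": 20, "noise": NoiseParams(0.05, 0.1, 0.1)},
            target_mean_p=0.45, tolerance=0.05, n_replications=6, seed=2,
        )
        assert abs(res.shift) < 0.05
        assert abs(res.achieved_mean_p - 0.45) <= 0.05

    def test_unattainable_tolerance_raises_with_trace(self, small_groundtruth):
        with pytest.raises(CalibrationError) as err:
            calibrate_negative_shift(
                small_groundtruth,
                {"n_patients": 10, "n_controls": 10, "noise": NoiseParams(0.05, 0.1, 0.1)},
                target_mean_p=0.3, tolerance=0.0, max_iter=3,
                n_replications=4, seed=3,
            )
        assert len(err.value.trace) >= 3
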