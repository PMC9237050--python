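import numpy as np
import pytest

from neurocrit import (
    HealthyCalibration,
    LesionSpec,
    apply_lesion,
    contiguous_lesion,
    generate_behavior,
    generate_healthy_connectome,
    generate_parcellation,
    homeostatic_normalize,
    remodel_recovery,
    threshold_connectome,
)
from neurocrit.connectome import graph_metrics, structural_entropy


class TestParcellation:
    def test_default_hemisphere_split(self):
        parc = generate_parcellation(seed=0)
        assert (parc.hemisphere == "L").sum() == 159
        assert (parc.hemisphere == "R").sum() == 165

    def test_small_parcellation_fully_labeled(self):
        parc = generate_parcellation(n_nodes=4, n_networks=2, seed=1)
        assert set(parc.network) <= {"VIS", "DMN"}
        assert len(parc.network) == 4
        for i, h in enumerate(parc.homotope):
            if h >= 0:
                assert parc.homotope[h] == i
                assert parc.hemisphere[h] != parc.hemisphere[i]

    def test_deterministic_for_seed(self):
        a = generate_parcellation(n_nodes=50, seed=42).to_frame()
        b = generate_parcellation(n_nodes=50, seed=42).to_frame()
        assert a.equals(b)

    def test_networks_bilateral(self):
        parc = generate_parcellation(n_nodes=60, n_networks=5, seed=3)
        for net in set(parc.network):
            hemis = set(parc.hemisphere[parc.network == net])
            assert hemis == {"L", "R"}

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_parcellation(n_nodes=4, n_networks=5)
        with pytest.raises(ValueError):
            generate_parcellation(n_nodes=1)


class TestHealthyConnectome:
    def test_symmetric_integer_nonnegative(self, healthy40):
        W = healthy40.W
        assert np.array_equal(W, W.T)
        assert np.all(np.diag(W) == 0)
        assert np.all(W >= 0)
        assert np.issubdtype(W.dtype, np.integer)

    def test_deterministic_for_seed(self, parc40, small_calibration):
        a = generate_healthy_connectome(parc40, small_calibration, seed=5)
        b = generate_healthy_connectome(parc40, small_calibration, seed=5)
        assert np.array_equal(a.W, b.W)

    def test_infeasible_calibration_raises(self, parc40):
        cal = HealthyCalibration(strong_degree=30, medium_degree=30, weak_degree=30)
        with pytest.raises(ValueError, match="infeasible"):
            generate_healthy_connectome(parc40, cal)

    def test_counts_span_streamline_threshold(self, healthy40):
        vals = healthy40.W[healthy40.W > 0]
        assert (vals <= 3).any()          # sub-threshold entries exist
        assert (vals > 3).any()

    def test_homotopic_weight_elevated(self, parc40, small_calibration):
        # ensemble mean homotopic weight exceeds non-homotopic inter-hemispheric
        homo, cross = [], []
        left = parc40.hemisphere == "L"
        pairs = parc40.homotopic_pairs()
        is_homo = np.zeros((40, 40), bool)
        is_homo[pairs[:, 0], pairs[:, 1]] = True
        is_homo |= is_homo.T
        inter = left[:, None] != left[None, :]
        for s in range(20):
            W = generate_healthy_connectome(parc40, small_calibration, seed=s).W
            homo.append(W[is_homo & (W > 0)].mean())
            other = W[inter & ~is_homo & (W > 0)]
            cross.append(other.mean() if other.size else 0.0)
        assert np.mean(homo) > np.mean(cross)

    def test_distance_dependence(self, parc40, small_calibration):
        # connection probability is higher for near pairs than far pairs
        pos = parc40.position
        d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
        present = np.zeros_like(d)
        for s in range(15):
            present += generate_healthy_connectome(
                parc40, small_calibration, seed=100 + s
            ).W > 0
        iu, ju = np.triu_indices(40, 1)
        near = d[iu, ju] < np.median(d[iu, ju])
        assert present[iu, ju][near].mean() > present[iu, ju][~near].mean()


class TestLesion:
    def test_empty_spec_is_identity(self, healthy40):
        out = apply_lesion(healthy40, LesionSpec())
        assert np.array_equal(out.W, healthy40.W)

    def test_lesioned_rows_zeroed_and_degree_drops(self, healthy40):
        nodes = list(range(10))
        out = apply_lesion(healthy40, LesionSpec(lesioned_nodes=nodes))
        assert not np.any(out.W[nodes, :])
        assert not np.any(out.W[:, nodes])
        assert (out.W > 0).sum() < (healthy40.W > 0).sum()

    def test_interhemispheric_scaling(self, parc40, healthy40):
        out = apply_lesion(healthy40, LesionSpec(interhemispheric_scale=0.0))
        left = parc40.hemisphere == "L"
        cross = left[:, None] != left[None, :]
        assert not out.W[cross].any()
        assert np.array_equal(out.W[~cross], healthy40.W[~cross])

    def test_output_symmetric(self, healthy40):
        spec = LesionSpec(lesioned_nodes=[3, 4], interhemispheric_scale=0.5,
                          edge_dropout=0.2, seed=9)
        out = apply_lesion(healthy40, spec)
        assert np.array_equal(out.W, out.W.T)

    def test_invalid_spec(self, healthy40):
        with pytest.raises(ValueError):
            apply_lesion(healthy40, LesionSpec(lesioned_nodes=[99]))
        with pytest.raises(ValueError):
            apply_lesion(healthy40, LesionSpec(edge_dropout=1.5))

    def test_severity_degrades_metrics(self, parc40, small_calibration):
        # K, H_SC, E decrease and Q increases with severity (ensemble means)
        rows = {0: [], 1: []}
        for s in range(6):
            base = generate_healthy_connectome(parc40, small_calibration, seed=200 + s)
            for level, spec in enumerate([
                LesionSpec(),
                LesionSpec(lesioned_nodes=contiguous_lesion(parc40, 8, seed=s),
                           interhemispheric_scale=0.3, edge_dropout=0.3, seed=s),
            ]):
                norm = homeostatic_normalize(
                    threshold_connectome(apply_lesion(base, spec))
                )
                rows[level].append(graph_metrics(norm, louvain_seed=s))
        mean = lambda lvl, attr: np.mean([getattr(m, attr) for m in rows[lvl]])
        assert mean(1, "K") < mean(0, "K")
        assert mean(1, "H_SC") < mean(0, "H_SC")
        assert mean(1, "E_global") < mean(0, "E_global")
        assert mean(1, "Q") > mean(0, "Q")

    def test_contiguous_lesion_single_hemisphere(self, parc40):
        nodes = contiguous_lesion(parc40, 6, seed=2)
        assert len(set(parc40.hemisphere[nodes])) == 1
        assert len(nodes) == 6


class TestRecovery:
    def test_full_recovery_restores_template(self, parc40, small_calibration):
        base = generate_healthy_connectome(parc40, small_calibration, seed=31)
        nodes = contiguous_lesion(parc40, 5, seed=31)
        lesioned = apply_lesion(base, LesionSpec(lesioned_nodes=nodes,
                                                 edge_dropout=0.2, seed=31))
        out = remodel_recovery(lesioned, base, recovery_fraction=1.0,
                               rewire_fraction=0.0)
        alive = np.setdiff1d(np.arange(40), nodes)
        # dead nodes keep zero rows, surviving submatrix equals the template
        assert not out.W[nodes, :].any()
        assert np.array_equal(out.W[np.ix_(alive, alive)],
                              base.W[np.ix_(alive, alive)])

    def test_invalid_fractions(self, healthy40):
        with pytest.raises(ValueError):
            remodel_recovery(healthy40, healthy40, recovery_fraction=1.5)
        with pytest.raises(ValueError):
            remodel_recovery(healthy40, healthy40, 0.5, rewire_fraction=-0.1)

    def test_degree_monotone_in_recovery(self, parc40, small_calibration):
        # ensemble-mean K is non-decreasing along a recovery grid
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = np.zeros(len(grid))
        for s in range(10):
            base = generate_healthy_connectome(parc40, small_calibration, seed=400 + s)
            lesioned = apply_lesion(base, LesionSpec(
                lesioned_nodes=contiguous_lesion(parc40, 8, seed=s),
                interhemispheric_scale=0.4, edge_dropout=0.3, seed=s))
            for g, f in enumerate(grid):
                out = remodel_recovery(lesioned, base, f, seed=s)
                thr = threshold_connectome(out)
                means[g] += (thr.W > 0).sum() / 40
        assert np.all(np.diff(means) >= -1e-9)

    def test_rewiring_adds_novel_edges(self, parc40, small_calibration):
        base = generate_healthy_connectome(parc40, small_calibration, seed=55)
        lesioned = apply_lesion(base, LesionSpec(edge_dropout=0.5, seed=55))
        out = remodel_recovery(lesioned, base, 0.5, rewire_fraction=0.3, seed=55)
        novel = (out.W > 0) & (base.W == 0)
        assert novel.any()


class TestBehavior:
    def test_noise_free_is_linear(self):
        i1 = np.array([1.0, 2.0, 3.0, 4.0])
        i2 = np.array([0.5, 0.4, 0.3, 0.2])
        b = generate_behavior(i1, i2, coefficients=(1.0, 2.0, 3.0), noise_sd=0.0)
        raw = 1.0 + 2.0 * i1 - 3.0 * i2
        expected = (raw - raw.mean()) / raw.std()
        np.testing.assert_allclose(b, expected, atol=1e-12)

    def test_deterministic(self):
        i1 = np.linspace(0, 1, 8)
        i2 = np.linspace(1, 0, 8)
        a = generate_behavior(i1, i2, noise_sd=0.5, seed=4)
        b = generate_behavior(i1, i2, noise_sd=0.5, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_control_standardization(self):
        rng = np.random.default_rng(0)
        i1, i2 = rng.normal(size=50), rng.normal(size=50)
        mask = np.zeros(50, bool)
        mask[:20] = True
        b = generate_behavior(i1, i2, noise_sd=0.1, seed=1, control_mask=mask)
        assert abs(b[mask].mean()) < 1e-10
        assert abs(b[mask].std() - 1.0) < 1e-10

    def test_negative_noise_raises(self):
        with pytest.raises(ValueError):
            generate_behavior(np.ones(3), np.ones(3), noise_sd=-1.0)

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            generate_behavior(np.array([np.nan]), np.array([1.0]))


def test_recovery_indexes_correlated(parc40, small_calibration):
    # K(t2-t1) and H_SC(t2-t1) positively correlated across a patient cohort
    dk, dh = [], []
    for s in range(12):
        base = generate_healthy_connectome(parc40, small_calibration, seed=600 + s)
        rng = np.random.default_rng(s)
        lesioned = apply_lesion(base, LesionSpec(
            lesioned_nodes=contiguous_lesion(parc40, int(rng.integers(4, 12)), seed=s),
            interhemispheric_scale=float(rng.uniform(0.2, 0.8)),
            edge_dropout=float(rng.uniform(0.1, 0.5)), seed=s))
        t2 = remodel_recovery(lesioned, base, float(rng.uniform(0.1, 1.0)), seed=s)
        m1 = homeostatic_normalize(threshold_connectome(lesioned))
        m2 = homeostatic_normalize(threshold_connectome(t2))
        dk.append((m2.adjacency.sum() - m1.adjacency.sum()) / 40)
        dh.append(structural_entropy(m2.W_tilde) - structural_entropy(m1.W_tilde))
    assert np.corrcoef(dk, dh)[0, 1] > 0.3
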