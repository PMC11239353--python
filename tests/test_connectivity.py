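import numpy as np
import pytest
from scipy import stats

from fcdecode import (CohortConfig, average_matrices, classify_edge_strength,
                      compute_fc, compute_isfc, edge_ttests, generate_cohort)
from fcdecode.cohort import BoldTimeSeries
from fcdecode.connectivity import ConnectivityMatrix, DegenerateSignalError
from fcdecode.rois import EventWindow, RoiSet, TOM, PAIN, default_rois


def _ts(data, subject_id="sub-000"):
    n = data.shape[1]
    names = tuple(f"R{i}" for i in range(n))
    nets = tuple(TOM if i < n // 2 else PAIN for i in range(n))
    rois = RoiSet(names=names, networks=nets, mni=tuple((i, 0, 0) for i in range(n)))
    window = EventWindow(TOM, 0, data.shape[0])
    return BoldTimeSeries(subject_id, data, (window,), rois), window


def _random_matrix(rng, n=12, kind="FC"):
    x = rng.standard_normal((40, n))
    r = np.corrcoef(x, rowvar=False)
    rois = default_rois()
    return ConnectivityMatrix(r, kind, "s", "w", rois)


class TestComputeFC:
    def test_identical_rois_give_unit_edge(self, rng):
        base = rng.standard_normal(20)
        data = np.column_stack([base, base, rng.standard_normal(20)])
        ts, w = _ts(data)
        assert compute_fc(ts, w).values[0, 1] == pytest.approx(1.0)

    def test_negated_roi_gives_minus_one(self, rng):
        base = rng.standard_normal(20)
        data = np.column_stack([base, -base])
        ts, w = _ts(data)
        assert compute_fc(ts, w).values[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_pearson_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 2.5])
        y = np.array([1.0, 3.0, 2.0, 4.0, 0.5])
        # direct formula, computed independently of corrcoef
        xc, yc = x - x.mean(), y - y.mean()
        expected = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
        ts, w = _ts(np.column_stack([x, y]))
        assert compute_fc(ts, w).values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_fc_invariants_on_random_input(self, rng):
        ts, w = _ts(rng.standard_normal((30, 8)))
        m = compute_fc(ts, w).values
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert np.max(np.abs(m)) <= 1.0 + 1e-12

    def test_zero_variance_roi_named_in_error(self, rng):
        data = rng.standard_normal((20, 3))
        data[:, 1] = 7.0
        ts, w = _ts(data)
        with pytest.raises(DegenerateSignalError, match="R1"):
            compute_fc(ts, w)


class TestComputeISFC:
    def test_requires_two_subjects(self, rng):
        ts, w = _ts(rng.standard_normal((20, 4)))
        with pytest.raises(ValueError, match=">=2 subjects"):
            compute_isfc([ts], w)

    def test_shared_signal_diagonal_is_one(self, rng):
        shared = rng.standard_normal((20, 4))
        subjects = [_ts(shared.copy(), f"s{i}")[0] for i in range(3)]
        w = subjects[0].windows[0]
        for m in compute_isfc(subjects, w):
            assert np.allclose(np.diag(m.values), 1.0, atol=1e-12)

    def test_matches_fc_when_signal_fully_shared(self, rng):
        shared = rng.standard_normal((25, 6))
        subjects = [_ts(shared.copy(), f"s{i}")[0] for i in range(4)]
        w = subjects[0].windows[0]
        fc = compute_fc(subjects[0], w).values
        for m in compute_isfc(subjects, w):
            assert np.allclose(m.values, fc, atol=1e-10)

    def test_white_noise_isfc_centred_on_zero(self, rng):
        # independent noise per subject: ISFC entries average to zero
        subjects = [_ts(rng.standard_normal((17, 6)), f"s{i}")[0]
                    for i in range(1000)]
        w = subjects[0].windows[0]
        mats = compute_isfc(subjects, w)
        assert abs(float(np.mean([m.values for m in mats]))) < 0.02

    def test_isfc_suppresses_intrinsic_coupling(self):
        # generator with intrinsic dominating (b >> a): off-network coupling
        # shows in FC but is suppressed in ISFC (one-sided test, n=200)
        cfg = CohortConfig(n_subjects=200, group_sizes={"pass": 200},
                           age_groups={"5-12yr": 200},
                           snr_multipliers={"5-12yr": 1.0},
                           mix_weights=(0.1, 1.0, 0.1), seed=6)
        cohort = generate_cohort(cfg)
        roi = cfg.roi_set
        off = np.ix_(roi.indices(TOM), roi.indices(PAIN))
        w = cohort[0].timeseries.windows[0]
        fc_vals = [np.abs(compute_fc(r.timeseries, w).values[off]).mean()
                   for r in cohort]
        isfc = compute_isfc([r.timeseries for r in cohort], w)
        isfc_vals = [np.abs(m.values[off]).mean() for m in isfc]
        t, p = stats.ttest_rel(fc_vals, isfc_vals, alternative="greater")
        assert p < 0.01


class TestAverageMatrices:
    def test_single_matrix_is_identity_operation(self, rng):
        m = _random_matrix(rng)
        avg = average_matrices([m], fisher=True)
        assert np.allclose(avg.values, m.values, atol=1e-10)

    def test_fisher_mean_of_r_and_minus_r_is_zero(self, rng):
        m = _random_matrix(rng)
        v = -m.values.copy()  # negate edges, restore the unit diagonal
        np.fill_diagonal(v, 1.0)
        neg = ConnectivityMatrix(v, "FC", "s2", "w", m.roi_set)
        avg = average_matrices([m, neg], fisher=True)
        off = ~np.eye(12, dtype=bool)
        assert np.allclose(avg.values[off], 0.0, atol=1e-10)

    def test_fisher_mean_closed_form(self):
        rois = default_rois().subset(["PCC", "RTPJ"])
        def mat(r):
            return ConnectivityMatrix(np.array([[1.0, r], [r, 1.0]]),
                                      "FC", "s", "w", rois)
        avg = average_matrices([mat(0.3), mat(0.7)], fisher=True)
        expected = np.tanh((np.arctanh(0.3) + np.arctanh(0.7)) / 2)
        assert avg.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_matrices([])


class TestEdgeTTests:
    def test_constant_nonzero_edges_survive_with_degenerate_flag(self, rng):
        rois = default_rois()
        v = np.full((12, 12), 0.8)
        np.fill_diagonal(v, 1.0)
        mats = [ConnectivityMatrix(v, "FC", f"s{i}", "w", rois) for i in range(5)]
        table = edge_ttests(mats).table
        assert table["survives"].all()
        assert table["degenerate"].all()

    def test_null_edges_rarely_survive_fdr(self, rng):
        # global null: iid noise edges, FDR at alpha=0.01 -> false survivals
        # are rare (simulation oracle)
        rois = default_rois()
        survived = 0
        for rep in range(100):
            mats = []
            for s in range(30):
                x = rng.standard_normal((20, 12))
                mats.append(ConnectivityMatrix(np.corrcoef(x, rowvar=False),
                                               "FC", f"s{s}", "w", rois))
            survived += edge_ttests(mats, alpha=0.01).n_surviving()
        assert survived / 100 < 0.5  # well under one false edge per dataset

    def test_fewer_than_three_matrices_rejected(self, rng):
        m = _random_matrix(rng)
        with pytest.raises(ValueError, match="3"):
            edge_ttests([m, m])

    def test_q_values_dominate_p_values(self, rng):
        mats = [_random_matrix(rng) for _ in range(10)]
        table = edge_ttests(mats).table
        assert (table["q"] >= table["p"] - 1e-15).all()


class TestEdgeStrength:
    @pytest.mark.parametrize("value,expected", [
        (0.9, "strong"), (0.5, "moderate"), (0.52, "moderate"),
        (-0.2, "weak"), (0.3, "weak"), (0.56, "strong")])
    def test_classification_rule(self, value, expected):
        assert classify_edge_strength(value, band=0.05) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_edge_strength(1.5)
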