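import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycodrug.normalization import (
    NormalizationError,
    QQLine,
    apply_qq_transform,
    coefficient_of_variation,
    filter_low_counts,
    fit_qq_line,
    household_norm,
    household_normalize,
    log_transform,
    merge_instruments,
    normalize_pipeline,
    select_household_proteins,
)
from glycodrug.synthetic import InstrumentProfile, distort_counts, generate_spectral_counts


class TestQQLine:
    def test_recovers_affine_distortion(self):
        rng = np.random.default_rng(3)
        reference = rng.gamma(2.0, 20.0, 5000)
        target = (reference - 4.0) / 2.5  # reference = 2.5*target + 4
        line = fit_qq_line(reference, target, n_quantiles=99)
        assert abs(line.slope - 2.5) / 2.5 < 0.01
        assert abs(line.intercept - 4.0) < 0.2

    def test_identity_on_identical_vectors(self):
        x = np.linspace(1, 100, 500)
        line = fit_qq_line(x, x)
        assert abs(line.slope - 1.0) < 1e-9
        assert abs(line.intercept) < 1e-7

    def test_transform_clips_negatives(self):
        m = pd.DataFrame([[0.0, 1.0]], index=["P0"], columns=["A", "B"])
        out = apply_qq_transform(m, QQLine(slope=1.0, intercept=-0.5, n_quantiles=99))
        assert out.loc["P0", "A"] == 0.0
        assert out.loc["P0", "B"] == 0.5

    def test_degenerate_inputs_raise(self):
        with pytest.raises(NormalizationError):
            fit_qq_line([], [1.0])
        with pytest.raises(NormalizationError):
            fit_qq_line([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        with pytest.raises(NormalizationError):
            QQLine(slope=0.0, intercept=1.0, n_quantiles=99)


class TestHousehold:
    def test_selects_lowest_cv_features(self):
        m = pd.DataFrame(
            {
                "A": [100.0, 10.0, 50.0],
                "B": [101.0, 90.0, 50.0],
                "C": [99.0, 30.0, 50.0],
            },
            index=["steady", "noisy", "flat"],
        )
        assert select_household_proteins(m, 2) == ["flat", "steady"]

    def test_household_selection_matches_cv_oracle(self, count_matrix_22x185):
        picked = select_household_proteins(count_matrix_22x185, 7)
        cv = coefficient_of_variation(count_matrix_22x185)
        finite = cv[np.isfinite(cv)].sort_values()
        assert set(picked) == set(finite.index[:7])

    def test_generator_anchors_are_recovered(self):
        m = generate_spectral_counts(22, 185, 7, seed=21)
        picked = select_household_proteins(m, 7)
        true_anchors = set(m.index[:7])
        assert len(true_anchors & set(picked)) >= 6

    def test_normalize_is_idempotent_and_scale_invariant(self, count_matrix_22x185):
        hh = list(count_matrix_22x185.index[:7])
        ref_len = household_norm(count_matrix_22x185, hh)
        once = household_normalize(count_matrix_22x185, hh, ref_len * 0.5)
        twice = household_normalize(once, hh, ref_len * 0.5)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)
        scaled_in = count_matrix_22x185 * 7.25
        from_scaled = household_normalize(scaled_in, hh, ref_len * 0.5)
        assert np.allclose(once.to_numpy(), from_scaled.to_numpy(), atol=1e-12)

    def test_zero_length_household_raises(self):
        m = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["h", "x"], columns=["A", "B"])
        with pytest.raises(NormalizationError):
            household_normalize(m, ["h"], 10.0)


class TestFilterAndLog:
    def test_filter_matches_bruteforce_oracle(self, count_matrix_22x185):
        kept = filter_low_counts(count_matrix_22x185, 100)
        expected = [
            fid
            for fid in count_matrix_22x185.index
            if float(count_matrix_22x185.loc[fid].sum()) >= 100
        ]
        assert kept.index.tolist() == expected

    def test_filter_keeps_boundary(self):
        m = pd.DataFrame(
            {"A": [50.0, 49.0], "B": [50.0, 50.0]}, index=["edge", "below"]
        )
        kept = filter_low_counts(m, 100)
        assert kept.index.tolist() == ["edge"]

    def test_log_transform_matches_oracle_and_transposes(self, count_matrix_22x185):
        out = log_transform(count_matrix_22x185)
        assert out.shape == count_matrix_22x185.shape[::-1]
        i, j = "CL03", "P0010"
        assert out.loc[i, j] == pytest.approx(
            np.log10(float(count_matrix_22x185.loc[j, i]) + 1.0), abs=1e-12
        )

    @given(st.integers(min_value=0, max_value=10_000))
    def test_log_transform_pointwise(self, c):
        m = pd.DataFrame([[float(c)]], index=["P"], columns=["CL"])
        assert log_transform(m).iloc[0, 0] == pytest.approx(np.log10(c + 1.0), rel=1e-12)


class TestMerge:
    def test_target_only_lines_land_on_reference_scale(self):
        true = generate_spectral_counts(22, 185, 7, seed=31)
        cells = list(true.columns)
        reference = true[cells[:18]]
        target = distort_counts(true, InstrumentProfile(scale=2.5, offset=1.0))
        merged, diag = merge_instruments(
            reference, target, cells[18:], household_k=7, return_diagnostics=True
        )
        assert merged.columns.tolist() == cells
        # reference cell lines pass through untouched
        assert np.allclose(merged[cells[:18]].to_numpy(float), reference.to_numpy(float))
        # appended lines should be near the undistorted truth after rescaling
        appended = merged[cells[18:]].to_numpy(float)
        truth = true[cells[18:]].to_numpy(float)
        rel_err = np.abs(appended.sum() - truth.sum()) / truth.sum()
        assert rel_err < 0.1
        # Q-Q line sees the planted distortion: mapping target->reference
        # inverts scale 2.5, so slope ~ 1/2.5
        assert diag.qq_line.slope == pytest.approx(1 / 2.5, rel=0.05)

    def test_duplicate_cell_line_rejected(self, count_matrix_22x185):
        with pytest.raises(NormalizationError):
            merge_instruments(
                count_matrix_22x185, count_matrix_22x185, [count_matrix_22x185.columns[0]]
            )

    def test_missing_household_in_target_rejected(self):
        true = generate_spectral_counts(10, 50, 5, seed=8)
        reference = true[true.columns[:8]]
        target = true.drop(index=true.index[:5])  # drop the stable anchors
        with pytest.raises(NormalizationError):
            merge_instruments(reference, target, list(true.columns[8:]), household_k=5)

    def test_normalize_pipeline_shape_and_orientation(self):
        true = generate_spectral_counts(12, 80, 5, seed=13)
        reference = true[true.columns[:10]]
        target = distort_counts(true, InstrumentProfile(scale=2.0))
        expr = normalize_pipeline(reference, target, list(true.columns[10:]), household_k=5)
        assert expr.index.tolist() == list(true.columns)
        assert expr.shape[1] <= 80
        assert (expr.to_numpy() >= 0).all()
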