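"""Error-class cascade, multiplier search, full-pipeline fault injection."""

import numpy as np
import pandas as pd
import pytest

from helical_validate import (
    ComparisonMetrics,
    CorrelationScores,
    ErrorClass,
    HelicalParams,
    IndexingResult,
    ValidationConfig,
    classify,
    default_model,
    find_multiplier,
    flip_sign,
    make_half_maps,
    make_helical_map,
    n_fold,
    swap,
    validate_entry,
    write_report,
    wrap_twist,
)


class TestFindMultiplier:
    def test_published_partial_symmetry_pair(self):
        # deposited coarse (-0.3 deg, 111.12 A) vs validated (65.42 deg, 5.07 A)
        rel = find_multiplier(
            HelicalParams(-0.3, 111.12), HelicalParams(65.42, 5.07),
            n_max=100, tol_rise=0.02, tol_twist=1.0,
        )
        assert rel is not None
        assert rel.n == 22
        assert rel.rise_error == pytest.approx(0.0038, abs=3e-4)
        assert rel.twist_error == pytest.approx(0.46, abs=0.01)
        assert rel.deposited_is_coarser

    def test_exact_multiple_has_zero_errors(self):
        p = HelicalParams(57.0, 12.0)
        rel = find_multiplier(n_fold(p, 3), p)
        assert rel.n == 3
        assert rel.rise_error == pytest.approx(0.0, abs=1e-12)
        assert rel.twist_error == pytest.approx(0.0, abs=1e-9)

    def test_roles_exchanged_when_deposited_is_finer(self):
        p = HelicalParams(57.0, 12.0)
        rel = find_multiplier(p, n_fold(p, 3))
        assert rel.n == 3
        assert not rel.deposited_is_coarser

    def test_unrelated_pair_returns_none(self):
        assert find_multiplier(HelicalParams(31.0, 17.3), HelicalParams(57.0, 12.0)) is None

    @pytest.mark.parametrize("n", range(2, 51))
    def test_nfold_recovered_exhaustively(self, n):
        p = HelicalParams(65.42, 5.07)
        rel = find_multiplier(n_fold(p, n), p)
        assert rel is not None and rel.n == n

    def test_agrees_with_brute_force_minimizer(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            p_val = HelicalParams(
                float(rng.uniform(-179, 179)), float(rng.uniform(0.5, 20.0))
            )
            true_n = int(rng.integers(2, 40))
            jitter_rise = 1.0 + float(rng.normal(0, 0.004))
            jitter_twist = float(rng.normal(0, 0.2))
            p_dep = HelicalParams(
                wrap_twist(true_n * p_val.twist + jitter_twist),
                true_n * p_val.rise * jitter_rise,
            )
            rel = find_multiplier(p_dep, p_val)
            # brute-force oracle: scan every candidate multiplier
            best_n, best_err = None, np.inf
            for n in range(2, 101):
                err = abs(p_dep.rise - n * p_val.rise) / p_dep.rise
                if err < best_err:
                    best_n, best_err = n, err
            twist_err = abs(wrap_twist(best_n * p_val.twist - p_dep.twist))
            accepted = best_err <= 0.02 and twist_err <= 1.0
            if accepted:
                assert rel is not None and rel.n == best_n
            else:
                assert rel is None


def _fake_detected(params: HelicalParams) -> IndexingResult:
    return IndexingResult(
        params=params, peak=(params.twist, params.rise), peak_score=0.95,
        lattice=(), angular_step=1.0, axial_step=1.0,
    )


def _metrics(cc_dep: float, cc_val: float, radius: float = 20.0) -> ComparisonMetrics:
    return ComparisonMetrics(
        normalized=None,
        vector=None,
        cc=CorrelationScores(cc_dep, cc_val, 10),
        radius=radius,
    )


class TestClassifyCascade:
    """Decision rules exercised directly on constructed inputs (no maps)."""

    DET = HelicalParams(57.0, 12.0)

    def test_missing_deposited_is_no_values(self):
        rec = classify(None, _fake_detected(self.DET), _metrics(np.nan, 0.99), 4.0)
        assert rec.error_class is ErrorClass.NO_VALUES
        assert rec.corrected == self.DET

    def test_indexing_failure_is_not_validated(self):
        rec = classify(self.DET, None, None, 4.0)
        assert rec.error_class is ErrorClass.NOT_VALIDATED

    def test_both_correlations_low_is_not_validated(self):
        rec = classify(
            HelicalParams(30.0, 8.0), _fake_detected(self.DET), _metrics(0.2, 0.3), 4.0
        )
        assert rec.error_class is ErrorClass.NOT_VALIDATED

    def test_matching_parameters_consistent(self):
        near = HelicalParams(57.3, 12.2)
        rec = classify(near, _fake_detected(self.DET), _metrics(0.97, 0.98), 4.0)
        assert rec.error_class is ErrorClass.CONSISTENT

    def test_swapped_parameters_detected(self):
        det = HelicalParams(130.78, 9.68)
        rec = classify(
            swap(det), _fake_detected(det), _metrics(0.6, 0.99), 4.0,
            voxel_size=2.0, box_height=128.0,
        )
        assert rec.error_class is ErrorClass.TWIST_RISE_SWAPPED

    def test_sign_flip_detected(self):
        det = HelicalParams(-75.13, 11.54)
        rec = classify(flip_sign(det), _fake_detected(det), _metrics(0.6, 0.99), 4.0)
        assert rec.error_class is ErrorClass.INCORRECT_TWIST_SIGN

    def test_partial_symmetry_needs_close_high_correlations(self):
        det = HelicalParams(65.42, 5.07)
        dep = HelicalParams(-0.3, 111.12)
        rec = classify(dep, _fake_detected(det), _metrics(0.93, 0.98), 4.0)
        assert rec.error_class is ErrorClass.PARTIAL_SYMMETRY
        assert rec.multiplier == 22
        # same relation but discordant correlations: falls through
        rec2 = classify(dep, _fake_detected(det), _metrics(0.4, 0.98), 4.0)
        assert rec2.error_class is ErrorClass.INCORRECT_VALUES

    def test_significantly_higher_validated_score_is_incorrect_values(self):
        dep = HelicalParams(100.0, 19.0)
        rec = classify(dep, _fake_detected(self.DET), _metrics(0.5, 0.95), 4.0)
        assert rec.error_class is ErrorClass.INCORRECT_VALUES

    def test_ambiguous_scores_not_validated(self):
        dep = HelicalParams(100.0, 19.0)
        rec = classify(dep, _fake_detected(self.DET), _metrics(0.93, 0.98), 4.0)
        assert rec.error_class is ErrorClass.NOT_VALIDATED

    def test_implausible_swap_not_relabelled(self):
        # amyloid-style deposited twist 0.8 deg: the swapped reading would
        # put a 0.8 A rise below the voxel size, so the numeric coincidence
        # with the detected values must not be labelled a swap
        dep = HelicalParams(0.8, 4.8)
        det = HelicalParams(4.8, 0.8)
        rec = classify(
            dep, _fake_detected(det), _metrics(0.95, 0.97), 4.0,
            voxel_size=2.0, box_height=128.0,
        )
        assert rec.error_class is not ErrorClass.TWIST_RISE_SWAPPED

    def test_tolerance_perturbation_keeps_class(self):
        det = HelicalParams(65.42, 5.07)
        dep = HelicalParams(-0.3, 111.12)
        for f in (0.8, 1.0, 1.2):
            config = ValidationConfig(
                tol_rise=0.02 * f, tol_twist=1.0 * f,
                cc_high=0.5 * f, cc_close=0.1 * f, cc_significant=0.1 * f,
            )
            rec = classify(dep, _fake_detected(det), _metrics(0.95, 0.98), 4.0, config)
            assert rec.error_class is ErrorClass.PARTIAL_SYMMETRY


@pytest.fixture(scope="module")
def noisy_map(helix_c1):
    m, _ = make_half_maps(helix_c1, 0.15, seed=5)
    return m


class TestValidateEntryPipeline:
    """Full pipeline on synthetic maps with injected metadata faults."""

    def test_true_parameters_are_consistent(self, noisy_map, params_c1):
        rec = validate_entry(noisy_map, params_c1, reported_resolution=5.0)
        assert rec.error_class is ErrorClass.CONSISTENT

    def test_missing_parameters_recovered(self, noisy_map, params_c1):
        rec = validate_entry(noisy_map, None, reported_resolution=5.0)
        assert rec.error_class is ErrorClass.NO_VALUES
        assert abs(rec.corrected.twist - params_c1.twist) <= 1.0
        assert abs(rec.corrected.rise - params_c1.rise) <= 1.0

    def test_injected_swap_detected(self):
        true = HelicalParams(130.78, 9.68)
        m, _ = make_half_maps(make_helical_map(default_model(), true), 0.15, seed=6)
        rec = validate_entry(m, swap(true), reported_resolution=5.0)
        assert rec.error_class is ErrorClass.TWIST_RISE_SWAPPED
        assert abs(rec.corrected.twist - true.twist) <= 1.0

    def test_injected_sign_flip_detected(self, noisy_map, params_c1):
        rec = validate_entry(noisy_map, flip_sign(params_c1), reported_resolution=5.0)
        assert rec.error_class is ErrorClass.INCORRECT_TWIST_SIGN

    def test_injected_partial_symmetry_detected(self, noisy_map, params_c1):
        rec = validate_entry(noisy_map, n_fold(params_c1, 5), reported_resolution=5.0)
        assert rec.error_class is ErrorClass.PARTIAL_SYMMETRY
        assert rec.multiplier == 5

    def test_injected_incorrect_values_detected(self, noisy_map):
        rec = validate_entry(noisy_map, HelicalParams(94.0, 19.3), reported_resolution=5.0)
        assert rec.error_class is ErrorClass.INCORRECT_VALUES

    def test_deterministic(self, noisy_map, params_c1):
        a = validate_entry(noisy_map, n_fold(params_c1, 3), reported_resolution=5.0)
        b = validate_entry(noisy_map, n_fold(params_c1, 3), reported_resolution=5.0)
        assert a.error_class is b.error_class and a.multiplier == b.multiplier


class TestWriteReport:
    def test_empty_records_header_only(self, tmp_path):
        path = tmp_path / "r.csv"
        write_report([], path)
        df = pd.read_csv(path)
        assert len(df) == 0
        assert "error_class" in df.columns

    def test_round_trip_to_two_decimals(self, tmp_path, helix_c1, params_c1):
        rec = validate_entry(helix_c1, params_c1, reported_resolution=5.0, entry_id="a")
        rec2 = validate_entry(helix_c1, n_fold(params_c1, 2), reported_resolution=5.0, entry_id="b")
        path = tmp_path / "r.csv"
        write_report([rec, rec2], path)
        df = pd.read_csv(path)
        assert list(df["entry_id"]) == ["a", "b"]  # order preserved
        assert df.loc[0, "deposited_twist"] == pytest.approx(params_c1.twist, abs=0.01)
        assert df.loc[1, "multiplier"] == 2
        assert df.loc[0, "error_class"] == "consistent"
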