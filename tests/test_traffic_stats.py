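from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from netbridge import synthetic_data as sd
from netbridge import traffic_stats as ts


class TestTrafficEfficiency:
    def test_constant_ratio(self):
        im = ts.traffic_efficiency([2.0] * 21, [4.0] * 21, "img1")
        assert im.median_te == 0.5 and im.qc_pass

    def test_below_min_cells_fails_qc(self):
        im = ts.traffic_efficiency([2.0] * 19, [4.0] * 19, "img2")
        assert not im.qc_pass

    def test_median_of_enumerated_ratios(self):
        ratios = [0.1 * k for k in range(1, 26)]
        im = ts.traffic_efficiency(ratios, [1.0] * 25)
        assert im.median_te == pytest.approx(1.3)

    def test_non_positive_total_raises_naming_cell(self):
        with pytest.raises(ValueError, match="index 1"):
            ts.traffic_efficiency([1.0, 1.0], [2.0, 0.0], "imgX")

    def test_condition_mean_uses_only_qc_passing_images(self):
        images = [
            ts.traffic_efficiency([1.0] * 25, [2.0] * 25, "a"),
            ts.traffic_efficiency([3.0] * 25, [4.0] * 25, "b"),
            ts.traffic_efficiency([9.0] * 5, [1.0] * 5, "too_few"),
        ]
        mean, n = ts.summarize_condition(images)
        assert n == 2 and mean == pytest.approx((0.5 + 0.75) / 2)


class TestDeviationScore:
    @pytest.mark.parametrize(
        "te,mean,sem,expected",
        [
            (0.6, 0.6, 0.05, 0.0),
            (0.7, 0.6, 0.05, 1.0),  # two SEMs above control -> DS = 1
            (0.8, 0.6, 0.05, 2.0),
        ],
    )
    def test_worked_values(self, te, mean, sem, expected):
        assert ts.deviation_score(te, mean, sem) == pytest.approx(expected)

    def test_affine_equivariance(self):
        base = ts.deviation_score(0.8, 0.6, 0.05)
        scaled = ts.deviation_score(0.8 * 3.7, 0.6 * 3.7, 0.05 * 3.7)
        assert scaled == pytest.approx(base)

    def test_non_positive_sem_rejected(self):
        with pytest.raises(ValueError):
            ts.deviation_score(0.5, 0.5, 0.0)

    def test_control_stats_sem_definition(self):
        wells = [0.5, 0.6, 0.7]
        mean, sem = ts.control_stats(wells)
        assert mean == pytest.approx(0.6)
        assert sem == pytest.approx(np.std(wells, ddof=1) / np.sqrt(3))


def matrix_from_means(means: dict[str, tuple[float, float, float]]) -> pd.DataFrame:
    """Balanced DS matrix whose replicates equal the per-type means exactly."""
    rows = []
    for sirna, per_type in means.items():
        for t, m in zip(ts.CFTR_TYPES, per_type):
            for rep in (1, 2, 3):
                rows.append(
                    {"sirna": sirna, "cftr_type": t, "replicate": rep, "ds": m}
                )
    return pd.DataFrame(rows)


class TestSirnaEffect:
    def test_reported_screen_rows_reproduced(self):
        # arithmetically exact published screen rows
        matrix = matrix_from_means(
            {
                "NF2_1": (-0.701, 0.319, -0.761),
                "IQGAP1_1": (0.536, 0.264, 0.044),
            }
        )
        effect_nf2, _ = ts.sirna_effect(matrix, "NF2_1")
        effect_iqgap, _ = ts.sirna_effect(matrix, "IQGAP1_1")
        assert effect_nf2 == pytest.approx(1.781, abs=1e-3)
        assert effect_iqgap == pytest.approx(0.844, abs=1e-3)

    def test_zero_matrix_gives_zero_effect(self):
        matrix = matrix_from_means({"a": (0.0, 0.0, 0.0)})
        effect, means = ts.sirna_effect(matrix, "a")
        assert effect == 0.0 and all(m == 0.0 for m in means.values())

    def test_effect_dominates_each_component(self, rng):
        means = tuple(rng.normal(size=3))
        matrix = matrix_from_means({"a": means})
        effect, per_type = ts.sirna_effect(matrix, "a")
        assert all(effect >= abs(m) - 1e-12 for m in per_type.values())

    def test_missing_type_raises(self):
        matrix = matrix_from_means({"a": (1.0, 2.0, 3.0)})
        partial = matrix[matrix["cftr_type"] != "wt"].copy()
        other = matrix_from_means({"b": (0.0, 0.0, 0.0)})
        combined = pd.concat([partial, other])
        with pytest.raises(ValueError, match="no DS values"):
            ts.sirna_effect(combined, "a")


class TestPermutationTest:
    def test_constant_matrix_gives_p_one(self):
        matrix = matrix_from_means({f"s{i}": (0.5, 0.5, 0.5) for i in range(4)})
        results = ts.permutation_test(matrix, n_perm=200, rng=3)
        assert all(r.p == 1.0 for r in results)

    def test_planted_strong_effect_detected(self):
        spec = sd.ScreenSpec(
            n_sirnas=12, planted_effects={"si000": (3.0, 3.0, 3.0)}
        )
        matrix, _ = sd.generate_screen(spec, seed=1)
        results = {r.sirna: r for r in ts.permutation_test(matrix, n_perm=1000, rng=2)}
        assert results["si000"].p < 0.05

    def test_p_invariant_to_sirna_relabeling(self):
        matrix = matrix_from_means(
            {"a": (1.0, 0.5, 0.2), "b": (0.1, 0.2, 0.3), "c": (0.0, 0.0, 0.0)}
        )
        renamed = matrix.replace({"sirna": {"a": "zz", "b": "a", "c": "b"}})
        n_perm = 4000
        p1 = {r.sirna: r.p for r in ts.permutation_test(matrix, n_perm=n_perm, rng=9)}
        p2 = {r.sirna: r.p for r in ts.permutation_test(renamed, n_perm=n_perm, rng=9)}
        # labels only index the matrix; p matches up to Monte-Carlo resolution
        for old, new in (("a", "zz"), ("b", "a"), ("c", "b")):
            assert p1[old] == pytest.approx(p2[new], abs=0.05)

    def test_p_floored_at_one_over_n_perm(self):
        spec = sd.ScreenSpec(
            n_sirnas=8, planted_effects={"si000": (8.0, 8.0, 8.0)}, noise_sd=0.1
        )
        matrix, _ = sd.generate_screen(spec, seed=5)
        results = {r.sirna: r for r in ts.permutation_test(matrix, n_perm=500, rng=6)}
        assert results["si000"].p == 1 / 500

    def test_incomplete_matrix_rejected(self):
        matrix = matrix_from_means({"a": (1.0, 1.0, 1.0)})
        with pytest.raises(ValueError, match="balanced"):
            ts.permutation_test(matrix.iloc[:-1], n_perm=100, rng=0)


class TestFitDecay:
    def test_noiseless_model_recovered_exactly(self):
        t, f = sd.generate_decay_trace(
            amplitude=1.0, rate=0.1, offset=0.0, noise_sd=0.0
        )
        fit = ts.fit_decay(t, f, baseline_end=10.0)
        assert fit.rate == pytest.approx(0.1, abs=1e-8)
        assert fit.initial_slope == pytest.approx(-0.1, abs=1e-8)

    def test_constant_trace_gives_zero_slope(self):
        t = np.arange(0.0, 70.0, 0.5)
        f = np.ones_like(t)
        fit = ts.fit_decay(t, f, baseline_end=10.0)
        assert fit.initial_slope == pytest.approx(0.0, abs=1e-8)

    def test_offset_model_recovery(self):
        t, f = sd.generate_decay_trace(
            amplitude=0.9, rate=0.08, offset=0.1, noise_sd=0.0
        )
        fit = ts.fit_decay(t, f, baseline_end=10.0)
        assert fit.amplitude == pytest.approx(0.9, abs=1e-6)
        assert fit.offset == pytest.approx(0.1, abs=1e-6)
        assert fit.initial_slope == pytest.approx(-0.072, abs=1e-6)

    def test_noisy_slope_recovery_within_five_percent(self):
        true_slope = -0.9 * 0.08
        errors = []
        for seed in range(100):
            t, f = sd.generate_decay_trace(noise_sd=0.01, seed=seed)
            fit = ts.fit_decay(t, f, baseline_end=10.0)
            errors.append(abs(fit.initial_slope - true_slope) / abs(true_slope))
        assert np.median(errors) < 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ts.fit_decay([0, 1, 2], [1, 1, 1], baseline_end=1.5)


class TestSurfaceRetention:
    @pytest.mark.parametrize(
        "signal,reference,expected",
        [(0.7, 0.7, 100.0), (0.46, 1.0, 46.0), (0.0, 0.5, 0.0)],
    )
    def test_percentages(self, signal, reference, expected):
        assert ts.surface_retention(signal, reference) == pytest.approx(expected)

    def test_non_positive_reference_rejected(self):
        with pytest.raises(ValueError):
            ts.surface_retention(1.0, 0.0)
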