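"""Cosinor rhythmicity, peak-phase windows, and the crosstalk summary."""

import numpy as np
import pandas as pd
import pytest

import stressdiel as sd
from stressdiel.errors import ValidationError
from stressdiel.phases import EVEN_HOURS, PHASE_ORDER, PHASE_WINDOWS, validate_windows


def two_day_hours(n_stages: int = 1) -> np.ndarray:
    return np.array(list(EVEN_HOURS) * 2 * n_stages)


class TestPhaseWindows:
    def test_windows_partition_even_hours(self):
        validate_windows()  # raises on violation
        all_hours = [h for hours in PHASE_WINDOWS.values() for h in hours]
        assert sorted(all_hours) == sorted(EVEN_HOURS)

    def test_midnight_wraps_across_zero(self):
        assert {22, 0, 2} <= PHASE_WINDOWS["midnight"]

    def test_broken_partition_rejected(self):
        bad = {k: v for k, v in PHASE_WINDOWS.items()}
        bad["midday"] = frozenset({8, 10, 12, 14})  # drops 16
        with pytest.raises(ValidationError):
            validate_windows(bad)


class TestRhythmicityScore:
    def test_pure_cosine_scores_one(self):
        t = two_day_hours()
        y = 2.0 + 1.5 * np.cos(2 * np.pi * (t - 7.0) / 24.0)
        assert sd.rhythmicity_score(y, t) == pytest.approx(1.0)

    def test_constant_series_scores_zero_by_convention(self):
        t = two_day_hours()
        assert sd.rhythmicity_score(np.full_like(t, 3.0, dtype=float), t) == 0.0

    def test_white_noise_expectation_matches_null(self):
        """For noise, E[R2] ~ 2/(n-1): two cosinor df over n-1 total."""
        rng = np.random.default_rng(0)
        t = two_day_hours(n_stages=9)  # n = 216
        n = len(t)
        scores = [
            sd.rhythmicity_score(rng.normal(size=n), t) for _ in range(300)
        ]
        assert np.mean(scores) == pytest.approx(2 / (n - 1), rel=0.25)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValidationError):
            sd.rhythmicity_score(np.arange(4.0), np.array([0.0, 2.0, 4.0, 6.0]))


class TestAssignPhase:
    @pytest.mark.parametrize(
        "peak,expected",
        [(12.0, "midday"), (5.0, "predawn"), (19.0, "lateday"), (0.0, "midnight")],
    )
    def test_noiseless_cosine_peak(self, peak, expected):
        t = two_day_hours()
        y = np.cos(2 * np.pi * (t - peak) / 24.0)
        phase, means = sd.assign_phase(y, t)
        assert phase == expected
        assert means[expected] == max(means.values())

    def test_all_equal_breaks_tie_in_fixed_order(self):
        t = two_day_hours()
        phase, _ = sd.assign_phase(np.zeros_like(t, dtype=float), t)
        assert phase == PHASE_ORDER[0] == "predawn"

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        t = two_day_hours(2)
        y = rng.normal(size=len(t))
        phase_a, _ = sd.assign_phase(y, t)
        phase_b, _ = sd.assign_phase(3.0 * y + 10.0, t)
        assert phase_a == phase_b

    def test_empty_window_rejected(self):
        # only midday hours sampled: the other windows have no samples
        t = np.array([8, 10, 12, 14, 16] * 6)
        with pytest.raises(ValueError, match="no samples"):
            sd.assign_phase(np.arange(30.0), t)


class TestClusterDiurnal:
    def test_default_k_produces_seven_groups(self, diurnal_data):
        matrix, _, _ = diurnal_data
        km = sd.cluster_diurnal(sd.log2_normalize(matrix), seed=0)
        assert km.k == 7
        assert set(km.assignments) <= set(range(7))

    def test_duplicated_genes_cocluster(self):
        rng = np.random.default_rng(3)
        t = two_day_hours()
        base = pd.DataFrame(
            rng.normal(size=(10, len(t))), index=[f"g{i}" for i in range(10)]
        )
        dup = base.copy()
        dup.index = [f"g{i}_copy" for i in range(10)]
        both = pd.concat([base, dup])
        km = sd.cluster_diurnal(both, k=3, seed=0)
        s = km.assignments_series()
        for i in range(10):
            assert s[f"g{i}"] == s[f"g{i}_copy"]

    def test_two_phase_groups_separate(self):
        """Peaks 5 h apart at low noise split cleanly at k=2."""
        rng = np.random.default_rng(4)
        t = two_day_hours()
        rows, truth = [], []
        for i in range(60):
            peak = 4.0 if i < 30 else 9.0
            truth.append(int(i >= 30))
            rows.append(
                np.cos(2 * np.pi * (t - peak) / 24.0) + rng.normal(0, 0.1, len(t))
            )
        km = sd.cluster_diurnal(pd.DataFrame(rows), k=2, seed=0)
        labels = km.assignments
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]


class TestCallDiurnal:
    def test_recovery_with_planted_rhythms(self):
        """Amplitude 1.0 at noise 0.25: >=90% called rhythmic, correct phase."""
        cfg = sd.SimConfig(
            n_genes=400, frac_rhythmic=1.0, amplitude=1.0, noise_sd=0.25, seed=6
        )
        matrix, meta, truth = sd.generate_diurnal_course(cfg)
        calls = sd.call_diurnal(sd.log2_normalize(matrix), meta, seed=0)
        merged = calls.merge(truth, on="gene_id")
        assert merged["rhythmic"].mean() >= 0.90
        called = merged[merged["rhythmic"]]
        assert (called["phase"] == called["true_phase"]).mean() >= 0.90

    def test_null_course_yields_no_rhythmic_calls(self):
        cfg = sd.SimConfig(
            n_genes=300, frac_rhythmic=0.0, noise_sd=0.25, seed=7
        )
        matrix, meta, _ = sd.generate_diurnal_course(cfg)
        calls = sd.call_diurnal(sd.log2_normalize(matrix), meta, seed=0)
        assert calls["rhythmic"].mean() <= 0.02

    def test_stage_shift_does_not_move_phase(self, diurnal_data):
        """Adding a constant to one stage's samples leaves phases unchanged."""
        matrix, meta, _ = diurnal_data
        log2 = sd.log2_normalize(matrix)
        calls_a = sd.call_diurnal(log2, meta, seed=0)
        shifted = log2.values.copy()
        stage1 = meta.loc[meta["stage"] == 1, "sample_id"]
        shifted[stage1] = shifted[stage1] + 2.0
        # per-gene window means shift equally in every window only if the
        # stage contributes the same sample count per window - true here
        calls_b = sd.call_diurnal(
            sd.ExpressionMatrix(shifted, scale="log2"), meta, seed=0
        )
        rhythmic = calls_a["rhythmic"] & calls_b["rhythmic"]
        assert (
            calls_a.loc[rhythmic, "phase"] == calls_b.loc[rhythmic, "phase"]
        ).mean() >= 0.98


class TestCrosstalkSummary:
    @staticmethod
    def _tables(n_up, n_up_d, n_down, n_down_d):
        genes = [f"g{i}" for i in range(n_up + n_down)]
        labels = pd.DataFrame(
            {
                "gene_id": genes,
                "drought_class": ["up"] * n_up + ["down"] * n_down,
            }
        )
        rhythmic = (
            [True] * n_up_d
            + [False] * (n_up - n_up_d)
            + [True] * n_down_d
            + [False] * (n_down - n_down_d)
        )
        phases = [
            "predawn" if r else None for r in rhythmic
        ]
        calls = pd.DataFrame(
            {"gene_id": genes, "rhythmic": rhythmic, "phase": phases}
        )
        return labels, calls

    def test_reported_study_arithmetic(self):
        """403/712 up and 363/761 down give 56.6% / 47.7% and 766 total."""
        labels, calls = self._tables(712, 403, 761, 363)
        summary = sd.crosstalk_summary(labels, calls)
        assert summary.pct_up_diurnal == 56.6
        assert summary.pct_down_diurnal == 47.7
        assert summary.n_crosstalk == 766

    def test_counts_conserved(self):
        labels, calls = self._tables(50, 20, 30, 10)
        summary = sd.crosstalk_summary(labels, calls)
        assert summary.n_up_diurnal <= summary.n_up
        assert summary.n_down_diurnal <= summary.n_down
        assert summary.n_up + summary.n_down == len(labels)

    def test_phase_proportions_sum_to_100(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        labels = pd.DataFrame(
            {"gene_id": genes, "drought_class": rng.choice(["up", "down"], 200)}
        )
        calls = pd.DataFrame(
            {
                "gene_id": genes,
                "rhythmic": True,
                "phase": rng.choice(PHASE_ORDER, 200),
            }
        )
        summary = sd.crosstalk_summary(labels, calls)
        for props in (summary.phase_proportions_up, summary.phase_proportions_down):
            assert sum(props.values()) == pytest.approx(100.0, abs=0.05)

    def test_zero_diurnal_gives_zero_percent(self):
        labels, calls = self._tables(10, 0, 5, 0)
        summary = sd.crosstalk_summary(labels, calls)
        assert summary.pct_up_diurnal == 0.0
        assert summary.pct_down_diurnal == 0.0

    def test_empty_direction_reports_absent_not_zero(self):
        labels, calls = self._tables(10, 5, 0, 0)
        summary = sd.crosstalk_summary(labels, calls)
        assert summary.pct_down_diurnal is None
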