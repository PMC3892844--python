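"""Agreement, reliability and confusion statistics.

The frozen expected values for the 5-point agreement fixture and the 2x2
reliability table were computed with an independent least-squares /
ANOVA oracle (scipy.stats.linregress plus chi-square limits, and a hand
variance decomposition) before the implementation existed.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from racewalk import (
    AgreementError,
    StepComparison,
    agreement,
    agreement_from_comparisons,
    confusion,
    reliability,
)

# 5 paired (camera, sensor) values, seconds
FIVE_POINT_CAMERA = [0.00, 0.02, -0.04, 0.05, -0.01]
FIVE_POINT_SENSOR = [0.01, 0.05, -0.02, 0.04, 0.02]
# frozen oracle output for the fixture above
FIVE_POINT_EXPECTED = {
    "pearson_r": 0.8690007145497095,
    "tee": 0.01564729235721294,
    "tee_lower_cl": 0.008864027552990348,
    "tee_upper_cl": 0.05834166929256659,
    "bias_mean": 0.016,
    "bias_sd": 0.016733200530681513,
}

RELIABILITY_2X2 = [[10, 10], [20, 22]]
RELIABILITY_2X2_EXPECTED = {
    "typical_error": 1.0,  # sqrt(SSW/df) = sqrt(2/2)
    "te_lower_cl": 0.5206582666988174,
    "te_upper_cl": 6.2847346964853825,
    "icc": 120 / 122,  # (MSB - MSE)/(MSB + MSE) = (121-1)/(121+1)
}


def comparisons_from_cells(illegal_agree, illegal_missed, legal_agree, legal_flagged):
    pairs = []
    cells = [
        (illegal_agree, "illegal", "illegal", -0.02, 0.05),
        (illegal_missed, "illegal", "legal", -0.008, 0.03),
        (legal_agree, "legal", "legal", 0.02, 0.01),
        (legal_flagged, "legal", "illegal", 0.008, 0.04),
    ]
    k = 0
    for count, cam, sen, overlap, offset in cells:
        for _ in range(count):
            pairs.append(StepComparison(k, overlap, offset, cam, sen))
            k += 1
    return pairs


class TestAgreement:
    def test_identical_measures(self):
        x = [0.01, 0.02, -0.03, 0.05]
        rep = agreement(x, x)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.tee == pytest.approx(0.0, abs=1e-15)
        assert rep.bias_mean == pytest.approx(0.0, abs=1e-15)

    def test_pure_offset(self):
        x = np.array([0.0, 0.02, -0.04, 0.05])
        rep = agreement(x, x + 0.02)
        assert rep.bias_mean == pytest.approx(0.02)
        assert rep.tee == pytest.approx(0.0, abs=1e-12)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.bias_sd == pytest.approx(0.0, abs=1e-12)

    def test_five_point_fixture_matches_frozen_oracle(self):
        rep = agreement(FIVE_POINT_CAMERA, FIVE_POINT_SENSOR)
        for field, expected in FIVE_POINT_EXPECTED.items():
            assert getattr(rep, field) == pytest.approx(expected, abs=1e-10), field
        assert rep.n == 5

    def test_against_linregress_oracle(self):
        """Independent route: scipy's regression machinery on fresh data."""
        rng = np.random.default_rng(21)
        x = rng.normal(0, 0.03, 40)
        y = 0.8 * x + rng.normal(0.01, 0.01, 40)
        rep = agreement(x, y)
        lr = sstats.linregress(x, y)
        resid = y - (lr.intercept + lr.slope * x)
        see = np.sqrt((resid**2).sum() / (len(x) - 2))
        assert rep.pearson_r == pytest.approx(lr.rvalue, abs=1e-12)
        assert rep.tee == pytest.approx(see, abs=1e-12)

    def test_confidence_limits_bracket_tee(self):
        rep = agreement(FIVE_POINT_CAMERA, FIVE_POINT_SENSOR)
        assert rep.tee_lower_cl <= rep.tee <= rep.tee_upper_cl

    def test_permutation_invariance(self):
        perm = [3, 0, 4, 1, 2]
        a = agreement(FIVE_POINT_CAMERA, FIVE_POINT_SENSOR)
        b = agreement(
            [FIVE_POINT_CAMERA[i] for i in perm], [FIVE_POINT_SENSOR[i] for i in perm]
        )
        assert a.n == b.n
        for field in ("pearson_r", "tee", "tee_lower_cl", "tee_upper_cl", "bias_mean", "bias_sd"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), abs=1e-12)

    def test_tee_decreases_with_noise(self):
        """TEE shrinks monotonically as residual noise around a perfect
        pairing is reduced."""
        rng = np.random.default_rng(5)
        x = rng.uniform(-0.05, 0.05, 200)
        tees = []
        for sd in (0.05, 0.02, 0.01, 0.0):
            noise = rng.normal(0, sd, 200) if sd else np.zeros(200)
            tees.append(agreement(x, x + noise).tee)
        assert all(a > b for a, b in zip(tees, tees[1:], strict=False) if a != b)
        assert tees[0] > tees[-1]

    def test_too_few_pairs_rejected(self):
        with pytest.raises(AgreementError):
            agreement([0.1, 0.2], [0.1, 0.2])

    def test_zero_criterion_variance_rejected(self):
        with pytest.raises(AgreementError):
            agreement([0.1, 0.1, 0.1], [0.0, 0.1, 0.2])

    def test_from_comparisons_uses_signed_margin(self):
        pairs = [
            StepComparison(0, 0.02, 0.01, "legal", "legal"),
            StepComparison(1, -0.03, 0.06, "illegal", "illegal"),
            StepComparison(2, 0.0, 0.03, "threshold", "legal"),
            StepComparison(3, -0.01, 0.04, "illegal", "illegal"),
        ]
        rep = agreement_from_comparisons(pairs, threshold=0.03)
        # margins (0.02, -0.03, 0.0, -0.01) equal the camera overlaps here
        assert rep.bias_mean == pytest.approx(0.0, abs=1e-15)
        assert rep.pearson_r == pytest.approx(1.0)


class TestReliability:
    def test_identical_repeats(self):
        table = np.tile(np.array([3.0, 9.0, 14.0, 21.0])[:, None], (1, 3))
        rep = reliability(table)
        assert rep.typical_error == 0.0
        assert rep.icc == pytest.approx(1.0)

    def test_2x2_fixture_matches_hand_anova(self):
        rep = reliability(RELIABILITY_2X2)
        for field, expected in RELIABILITY_2X2_EXPECTED.items():
            assert getattr(rep, field) == pytest.approx(expected, abs=1e-10), field

    def test_consistency_icc_ignores_repeat_offsets(self):
        """A fixed shift per repeat leaves the consistency ICC at 1."""
        base = np.array([10.0, 20.0, 35.0, 50.0])
        table = base[:, None] + np.array([0.0, 2.0, -1.0])[None, :]
        rep = reliability(table)
        assert rep.icc == pytest.approx(1.0)

    def test_zero_between_event_variance_gives_nan_icc(self):
        rep = reliability(np.full((4, 3), 7.0))
        assert np.isnan(rep.icc)
        assert rep.typical_error == 0.0

    def test_matches_pingouin_icc3_single(self):
        """Cross-check the two-way mixed consistency single-measure ICC
        against pingouin on a 12x3 table."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        table = rng.normal(50, 10, size=(12, 1)) + rng.normal(0, 1, size=(12, 3))
        long = pd.DataFrame(
            {
                "event": np.repeat(np.arange(12), 3),
                "repeat": np.tile(np.arange(3), 12),
                "frame": table.ravel(),
            }
        )
        icc_pg = (
            pg.intraclass_corr(long, "event", "repeat", "frame")
            .set_index("Type")
            .loc["ICC(C,1)", "ICC"]
        )
        assert reliability(table).icc == pytest.approx(float(icc_pg), abs=1e-10)

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            reliability([[1.0, 2.0]])  # single event
        with pytest.raises(ValueError):
            reliability([[1.0], [2.0]])  # single repeat


class TestConfusion:
    def test_study_cell_counts(self):
        """57 camera-illegal (4 missed) + 23 camera-legal (3 flagged)
        -> 91.25% overall, 91% rounded, 96.25% illegal-only."""
        pairs = comparisons_from_cells(53, 4, 20, 3)
        summary = confusion(pairs)
        assert summary.total == 80
        assert summary.accuracy_pct == pytest.approx(91.25)
        assert summary.accuracy_pct_rounded == 91
        assert summary.illegal_only_pct == pytest.approx(96.25)
        assert summary.misidentified == 7

    def test_all_agree(self):
        assert confusion(comparisons_from_cells(5, 0, 5, 0)).accuracy_pct == 100.0

    def test_symmetric_half(self):
        assert confusion(comparisons_from_cells(10, 10, 10, 10)).accuracy_pct == 50.0

    def test_threshold_steps_count_as_legal(self):
        pairs = [
            StepComparison(0, 0.0, 0.03, "threshold", "legal"),
            StepComparison(1, 0.0, 0.04, "threshold", "illegal"),
        ]
        summary = confusion(pairs)
        assert summary.legal_agree == 1
        assert summary.legal_flagged == 1
        assert summary.illegal_agree == summary.illegal_missed == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion([])

    @settings(deadline=None, max_examples=50)
    @given(
        cells=st.tuples(*[st.integers(0, 30)] * 4).filter(lambda c: sum(c) > 0)
    )
    def test_cells_conserve_input_count(self, cells):
        pairs = comparisons_from_cells(*cells)
        summary = confusion(pairs)
        assert summary.total == len(pairs)
        assert 0.0 <= summary.accuracy_pct <= 100.0
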