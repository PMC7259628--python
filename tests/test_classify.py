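"""Slope classes, TISD flag, summary tables, cross-tab and response rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorkinetics.classify import (
    IMPROVING,
    STABLE,
    WORSENING,
    PatientClassification,
    classify_patient,
    crosstab_bor_slope,
    response_rates,
    slope_category,
    summarize_rates,
    summary_frame,
)
from tumorkinetics.errors import JoinError
from tumorkinetics.recist import BorResult
from tumorkinetics.segmented import SegmentedFit


def make_fit(pid="P1", rg=0.0, rs=0.0):
    return SegmentedFit(
        patient_id=pid, y0_hat=60.0, rg_hat=rg, rs_hat=rs, sigma_hat=0.1,
        n_obs=5, dof=2, saturated=False, se_rg=0.05, se_rs=0.05, rss=0.02,
    )


def make_bor(pid="P1", bor="SD"):
    return BorResult(pid, 60.0, [(1.4, bor)] if bor != "UE" else [], [60.0], bor)


def make_class(pid, d, bor="SD", rg=0.0, cutoff=0.05):
    cls = slope_category(d, cutoff)
    return PatientClassification(
        patient_id=pid, rg_hat=rg, rs_hat=rg + d, d_hat=d, slope_class=cls,
        tisd=cls == IMPROVING and rg > cutoff, bor=bor,
        responder_recist=bor in ("CR", "PR"), responder_model=d < -cutoff,
    )


class TestClassifyPatient:
    def test_growth_arrest_with_growing_tumor_is_tisd(self):
        c = classify_patient(make_fit(rg=0.10, rs=0.00), make_bor())
        assert c.d_hat == pytest.approx(-0.10)
        assert c.slope_class == IMPROVING
        assert c.tisd

    def test_flat_on_flat_is_stable_not_tisd(self):
        c = classify_patient(make_fit(rg=0.0, rs=0.0), make_bor())
        assert c.slope_class == STABLE and not c.tisd

    def test_improving_but_slow_growing_tumor_is_not_tisd(self):
        c = classify_patient(make_fit(rg=-0.02, rs=-0.10), make_bor())
        assert c.slope_class == IMPROVING
        assert not c.tisd  # pre-treatment growth was negligible

    def test_boundary_d_values_are_stable(self):
        for d in (-0.05, 0.05):
            assert slope_category(d) == STABLE

    def test_tisd_can_be_restricted_to_recist_sd(self):
        fit = make_fit(rg=0.10, rs=-0.05)
        assert classify_patient(fit, make_bor(bor="PR"), tisd_requires_sd=True).tisd is False
        assert classify_patient(fit, make_bor(bor="SD"), tisd_requires_sd=True).tisd is True

    def test_mismatched_ids_raise(self):
        with pytest.raises(JoinError):
            classify_patient(make_fit(pid="A"), make_bor(pid="B"))

    @given(d=st.floats(min_value=-2, max_value=2, allow_nan=False))
    @settings(derandomize=True, max_examples=300)
    def test_partition_is_exhaustive_and_exclusive(self, d):
        assert slope_category(d) in {IMPROVING, STABLE, WORSENING}

    @given(
        d=st.floats(min_value=-2, max_value=2, allow_nan=False),
        small=st.floats(min_value=0.0, max_value=0.5),
        growth=st.floats(min_value=0.0, max_value=0.5),
    )
    @settings(derandomize=True, max_examples=300)
    def test_cutoff_monotonicity(self, d, small, growth):
        """Enlarging the negligible band never un-stabilizes a patient."""
        big = small + growth
        if slope_category(d, small) == STABLE:
            assert slope_category(d, big) == STABLE


class TestSummaries:
    def test_single_group_moments(self):
        classes = [make_class(f"P{i}", d) for i, d in enumerate((-0.1, -0.2, -0.3))]
        rows = {r.param: r for r in summarize_rates(classes, grouping="all")}
        assert rows["d"].mean == pytest.approx(-0.2)
        assert rows["d"].median == pytest.approx(-0.2)
        assert (rows["d"].minimum, rows["d"].maximum) == (-0.3, -0.1)
        assert rows["d"].ci_low < -0.2 < rows["d"].ci_high

    def test_group_of_one_has_no_ci(self):
        rows = summarize_rates([make_class("P1", -0.1)], grouping="all")
        assert math.isnan(rows[0].ci_low) and math.isnan(rows[0].ci_high)

    def test_responder_grouping_preserves_signs(self):
        classes = [
            make_class(f"R{i}", d=-0.4, bor="PR", rg=0.0) for i in range(4)
        ] + [make_class(f"N{i}", d=0.1, bor="PD", rg=0.05) for i in range(4)]
        frame = summary_frame(summarize_rates(classes))
        resp_rs = frame.query("group == 'responders' and param == 'rs'")["mean"].iloc[0]
        assert resp_rs < 0
        assert set(frame["group"]) == {"all", "responders", "non_responders"}

    def test_t_interval_matches_scipy_reference(self, rng):
        from scipy import stats

        values = rng.normal(0, 0.2, 12)
        classes = [make_class(f"P{i}", float(v)) for i, v in enumerate(values)]
        row = {r.param: r for r in summarize_rates(classes, grouping="all")}["d"]
        lo, hi = stats.t.interval(
            0.95, len(values) - 1, loc=values.mean(), scale=stats.sem(values)
        )
        assert row.ci_low == pytest.approx(lo)
        assert row.ci_high == pytest.approx(hi)


class TestCrosstab:
    def test_empty_input_gives_zero_table(self):
        table, ue = crosstab_bor_slope([])
        assert table.loc["Total", "Total"] == 0 and ue == 0

    def test_trial_shaped_margins_reproduced(self):
        """A cohort built to a published cross-tab shape reproduces its cells."""
        cells = {
            "CR": (0, 0, 2),
            "PR": (1, 0, 13),
            "SD": (2, 5, 9),
            "PD": (11, 11, 9),
        }
        classes = []
        i = 0
        for bor, (n_w, n_s, n_i) in cells.items():
            for d, count in ((0.2, n_w), (0.0, n_s), (-0.2, n_i)):
                for _ in range(count):
                    classes.append(make_class(f"P{i}", d, bor=bor))
                    i += 1
        for _ in range(5):
            classes.append(make_class(f"P{i}", 0.0, bor="UE"))
            i += 1
        table, ue = crosstab_bor_slope(classes)
        assert ue == 5
        assert tuple(table.loc["SD", ["worsening", "stable", "improving"]]) == (2, 5, 9)
        assert table.loc["Total", "Total"] == 63
        assert tuple(table["Total"][:4]) == (2, 14, 16, 31)
        assert tuple(table.loc["Total"][:3]) == (14, 16, 33)

    def test_column_totals_conserve_classified_n(self, rng):
        classes = [
            make_class(f"P{i}", float(d), bor=rng.choice(["CR", "PR", "SD", "PD"]))
            for i, d in enumerate(rng.normal(0, 0.2, 40))
        ]
        table, ue = crosstab_bor_slope(classes)
        assert table.loc["Total", "Total"] == 40 - ue == 40


class TestResponseRates:
    def test_rates_with_counts(self):
        classes = [make_class(f"R{i}", -0.2, bor="PR") for i in range(16)]
        classes += [make_class(f"M{i}", -0.2, bor="SD") for i in range(8)]
        classes += [make_class(f"N{i}", 0.0, bor="PD") for i in range(44)]
        rates = response_rates(classes)
        assert rates.n_evaluable == 68
        assert rates.n_recist == 16 and rates.n_model == 24
        assert rates.recist_rate == pytest.approx(100 * 16 / 68)
        assert rates.model_rate == pytest.approx(100 * 24 / 68)

    def test_zero_responders(self):
        rates = response_rates([make_class("P1", 0.0, bor="SD")])
        assert rates.recist_rate == 0.0 and rates.model_rate == 0.0

    def test_empty_undefined(self):
        with pytest.raises(ValueError):
            response_rates([])
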