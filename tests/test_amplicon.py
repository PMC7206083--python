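"""Ultra-deep amplicon calling: the quality frequency-ratio statistic,
inclusive thresholds, the published validation-table rows, and the
longitudinal / confinement / cohort summaries."""

import pytest

from clonetrack._util import round_half_away
from clonetrack.amplicon import (
    AmpliconThresholds,
    base_quality_frequency_ratio,
    call_amplicon_variant,
    cohort_prevalence,
    confinement_report,
    track_vaf,
)
from clonetrack.fixtures import amplicon_pileup
from clonetrack.somatic import QualityPileup


def _pileup(depth, var_calls, q_ref=36.0, q_var=36.0):
    ref_calls = depth - var_calls
    return QualityPileup(
        chrom="1", pos=11182160, ref_base="G", var_base="C",
        ref_calls=ref_calls, var_calls=var_calls,
        qsum_ref=q_ref * ref_calls, qsum_var=q_var * var_calls,
    )


class TestFrequencyRatio:
    def test_uniform_quality_gives_exactly_one(self):
        assert base_quality_frequency_ratio(_pileup(1000, 100)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_half_quality_variant_support(self):
        # variant mean quality = 0.5 x overall mean -> ratio 0.5
        p = QualityPileup(
            chrom="1", pos=1, ref_base="G", var_base="C",
            ref_calls=900, var_calls=100,
            qsum_ref=900 * 42.0, qsum_var=100 * 20.0,
        )
        overall_mean = (900 * 42.0 + 100 * 20.0) / 1000
        assert base_quality_frequency_ratio(p) == pytest.approx(
            20.0 / overall_mean
        )

    def test_invert_flag_is_reciprocal(self):
        p = _pileup(1000, 100, q_ref=40.0, q_var=30.0)
        r = base_quality_frequency_ratio(p)
        assert base_quality_frequency_ratio(p, invert=True) == pytest.approx(1.0 / r)

    def test_no_variant_reads_raises(self):
        with pytest.raises(ValueError):
            base_quality_frequency_ratio(_pileup(1000, 0))

    def test_printed_table_ratios_reconstruct(self, amplicon_rows):
        # fixture pileups are built to reproduce the printed Freq_Ratio
        for row in amplicon_rows:
            ratio = base_quality_frequency_ratio(amplicon_pileup(row))
            assert ratio == pytest.approx(row["freq_ratio"], rel=1e-9)


class TestCallAmpliconVariant:
    def test_high_depth_clone_is_called(self):
        # 191,784 variant reads of 1,000,004 -> VAF 19.2, called
        m = call_amplicon_variant(_pileup(1000004, 191784))
        assert m.vaf == 19.2
        assert m.called

    def test_below_threshold_not_called(self):
        assert not call_amplicon_variant(_pileup(1000, 4)).called

    def test_vaf_threshold_boundary_is_inclusive(self):
        m = call_amplicon_variant(_pileup(1000, 5))
        assert m.vaf == 0.5 and m.called

    def test_ratio_threshold_boundary_is_inclusive(self):
        depth, var = 1000, 100
        # choose qualities so the ratio is exactly 0.9
        q_all = 36.0 * depth
        qsum_var = 0.9 * (var / depth) * q_all
        p = QualityPileup(
            chrom="1", pos=1, ref_base="G", var_base="C",
            ref_calls=depth - var, var_calls=var,
            qsum_ref=q_all - qsum_var, qsum_var=qsum_var,
        )
        m = call_amplicon_variant(p)
        assert m.freq_ratio == pytest.approx(0.9)
        assert m.called

    def test_low_quality_variant_support_fails_ratio(self):
        m = call_amplicon_variant(_pileup(100000, 600, q_ref=38.0, q_var=20.0))
        assert m.vaf >= 0.5 and not m.called

    def test_published_rows_reproduce_when_internally_consistent(self, amplicon_rows):
        th = AmpliconThresholds()
        for row in amplicon_rows:
            m = call_amplicon_variant(amplicon_pileup(row))
            assert m.ref_calls + m.var_calls == m.call_depth
            if row["consistent"]:
                assert m.vaf == row["vaf"]
                expected_call = (
                    row["vaf"] >= th.min_vaf and row["freq_ratio"] >= th.min_freq_ratio
                )
                assert m.called == expected_call


def _measurement(year, compartment, vaf, called=True, subject="index", gene="mTOR"):
    depth = 100000
    var = int(round(vaf * depth / 100))
    return call_amplicon_variant(
        _pileup(depth, var), subject=subject, sample_year=year,
        compartment=compartment, gene=gene,
    )


class TestTrackVaf:
    def test_index_cd4_series_is_non_decreasing(self):
        ms = [
            _measurement(2013, "CD4", 17.3),
            _measurement(2015, "CD4", 19.2),
            _measurement(2017, "CD4", 20.5),
            _measurement(2019, "CD4", 23.4),
        ]
        s = track_vaf(ms, "index", "mTOR", "CD4")
        assert s.years == (2013, 2015, 2017, 2019)
        assert s.vafs == (17.3, 19.2, 20.5, 23.4)
        assert s.direction == "non-decreasing"
        assert s.slope_pct_per_year == pytest.approx(1.0, abs=0.1)

    def test_single_measurement_has_no_slope(self):
        s = track_vaf([_measurement(2013, "CD4", 17.3)], "index", "mTOR", "CD4")
        assert s.direction == "n/a" and s.slope_pct_per_year is None

    def test_constant_series_has_zero_slope(self):
        ms = [_measurement(y, "CD4", 10.0) for y in (2013, 2015, 2017)]
        s = track_vaf(ms, "index", "mTOR", "CD4")
        assert s.direction == "stable" and s.slope_pct_per_year == 0.0

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            track_vaf([], "index", "mTOR", "CD4")


class TestConfinement:
    def test_sorted_vb20_fraction_is_the_carrier(self):
        ms = [
            _measurement(2017, "CD4Vb20", 44.7),
            _measurement(2017, "CD4CD8Vb20", 35.5),
            _measurement(2017, "CD4", 20.5),
        ]
        rep = confinement_report(ms)
        assert rep["CD4Vb20"].flag == "carrier"
        assert rep["CD4"].flag == "trace"  # 20.5 < 0.5 x 44.7
        assert rep["CD4CD8Vb20"].flag == "shared"

    def test_single_compartment_is_carrier(self):
        rep = confinement_report([_measurement(2017, "CD4", 20.0)])
        assert rep["CD4"].flag == "carrier"

    def test_trace_ratio_is_reported(self):
        ms = [_measurement(2017, "A", 40.0), _measurement(2017, "B", 4.0)]
        rep = confinement_report(ms)
        assert rep["B"].flag == "trace"
        assert rep["B"].ratio_to_max == pytest.approx(0.10)

    def test_uncalled_compartment_is_absent(self):
        ms = [_measurement(2017, "A", 40.0), _measurement(2017, "B", 0.1)]
        rep = confinement_report(ms)
        assert rep["B"].flag == "absent"


class TestCohortPrevalence:
    @pytest.mark.parametrize(
        "carriers,total,pct", [(3, 135, 2.2), (21, 134, 15.7), (5, 54, 9.3), (0, 54, 0.0)]
    )
    def test_published_cohort_arithmetic(self, carriers, total, pct):
        flags = [True] * carriers + [False] * (total - carriers)
        assert cohort_prevalence(flags) == (carriers, total, pct)

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            cohort_prevalence([])


def test_rounding_is_half_away_from_zero():
    assert round_half_away(0.45, 1) == 0.5
    assert round_half_away(-0.45, 1) == -0.5
    assert round_half_away(13.2596685, 2) == 13.26
    assert round_half_away(2.25, 1) == 2.3
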