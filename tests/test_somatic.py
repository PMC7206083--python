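"""Paired-fraction somatic calling: VAF arithmetic, the one-tailed Fisher
test against an exact enumeration oracle, filter ordering, and VCF output."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonetrack.somatic import (
    CallerParams,
    QualityPileup,
    call_paired_somatic,
    compute_vaf,
    somatic_fisher_p,
    write_vcf,
)


def hypergeom_tail_oracle(nr: int, nv: int, tr: int, tv: int) -> float:
    """P(X >= tv) by direct summation of the hypergeometric pmf with exact
    integer combinatorics — independent of any scipy code path."""
    total, n_var, n_tumor = nr + nv + tr + tv, nv + tv, tr + tv
    denom = math.comb(total, n_tumor)
    num = sum(
        math.comb(n_var, k) * math.comb(total - n_var, n_tumor - k)
        for k in range(tv, min(n_var, n_tumor) + 1)
    )
    return num / denom


class TestComputeVaf:
    @pytest.mark.parametrize(
        "ref,var,expected",
        [(157, 24, 13.26), (104, 10, 8.77), (147, 99, 40.24), (500, 0, 0.0)],
    )
    def test_published_panel_vafs(self, ref, var, expected):
        assert compute_vaf(ref, var) == expected

    def test_zero_depth_raises(self):
        with pytest.raises(ZeroDivisionError):
            compute_vaf(0, 0)

    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    @settings(derandomize=True, max_examples=100)
    def test_complement_sums_to_100(self, a, b):
        if a + b == 0:
            return
        assert compute_vaf(a, b, ndigits=None) + compute_vaf(
            b, a, ndigits=None
        ) == pytest.approx(100.0, abs=1e-9)


class TestSomaticFisherP:
    def test_no_variant_reads_gives_p_one(self):
        assert somatic_fisher_p(10, 0, 10, 0) == 1.0

    @pytest.mark.parametrize(
        "counts,printed",
        [
            ((179, 8, 157, 24), 0.00178),
            ((116, 2, 104, 10), 0.0145),
            ((150, 68, 147, 99), 0.0266),
            ((14, 0, 26, 3), 0.29609),
            ((7, 0, 11, 2), 0.41053),
        ],
    )
    def test_one_tailed_convention_reproduces_panel_values(self, counts, printed):
        # the published somatic p-values are upper-tail (tumor-enriched)
        assert somatic_fisher_p(*counts) == pytest.approx(printed, rel=1e-3)

    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(1, 15)
    )
    @settings(derandomize=True, max_examples=200)
    def test_matches_enumeration_oracle(self, nr, nv, tr, tv):
        assert somatic_fisher_p(nr, nv, tr, tv) == pytest.approx(
            hypergeom_tail_oracle(nr, nv, tr, tv), rel=1e-12, abs=1e-300
        )

    def test_monotone_in_tumor_variant_support(self):
        ps = [somatic_fisher_p(100, 5, 100 - k, 5 + k) for k in range(0, 20)]
        assert all(b <= a for a, b in zip(ps, ps[1:]))

    def test_degenerate_table_raises(self):
        with pytest.raises(ValueError):
            somatic_fisher_p(0, 0, 0, 0)

    def test_two_tailed_is_at_least_one_tailed_p(self):
        one = somatic_fisher_p(179, 8, 157, 24)
        two = somatic_fisher_p(179, 8, 157, 24, two_tailed=True)
        assert two >= one


def _pileup(chrom, pos, ref_calls, var_calls, ref="G", var="C"):
    q = 30.0
    return QualityPileup(
        chrom=chrom, pos=pos, ref_base=ref, var_base=var,
        ref_calls=ref_calls, var_calls=var_calls,
        qsum_ref=q * ref_calls, qsum_var=q * var_calls,
    )


class TestCallPairedSomatic:
    def test_panel_fixture_orders_drivers_first(self, panel_maps):
        normal, tumor, genes = panel_maps
        calls = call_paired_somatic(normal, tumor, genes=genes)
        assert len(calls) == 14
        assert all(c.status == "candidate" for c in calls)
        assert [c.gene for c in calls[:3]] == ["MTOR", "TLR2", "GYPE"]
        ps = [c.somatic_p for c in calls]
        assert ps == sorted(ps)
        assert calls[0].somatic_p == pytest.approx(0.00178, rel=1e-3)
        assert calls[1].somatic_p == pytest.approx(0.0145, rel=1e-3)
        assert calls[2].somatic_p == pytest.approx(0.0266, rel=1e-3)

    def test_low_coverage_filter_precedes_low_vaf(self):
        # depth 5 < 6 AND vaf 1/5 below nothing: coverage label must win
        normal = [_pileup("1", 10, 50, 0)]
        tumor = [_pileup("1", 10, 4, 1)]
        (call,) = call_paired_somatic(normal, tumor)
        assert call.status == "filtered_low_coverage"

    def test_low_vaf_filter(self):
        (call,) = call_paired_somatic(
            [_pileup("1", 10, 500, 0)], [_pileup("1", 10, 499, 1)]
        )
        assert call.status == "filtered_low_vaf"

    def test_known_variant_filter(self):
        params = CallerParams(known_variant_set=frozenset({("1", 10, "C")}))
        (call,) = call_paired_somatic(
            [_pileup("1", 10, 50, 0)], [_pileup("1", 10, 40, 10)], params
        )
        assert call.status == "filtered_known_variant"

    def test_site_missing_from_normal_is_flagged_not_fatal(self):
        (call,) = call_paired_somatic([], [_pileup("1", 10, 40, 10)])
        assert call.normal_missing
        assert (call.normal_ref, call.normal_var) == (0, 0)

    def test_spiked_clone_is_called(self):
        from clonetrack.synthetic import FractionSimConfig, simulate_paired_fractions

        cfg = FractionSimConfig(
            clone_vaf=0.15, host_fractions=("CD8", "CD4"),
            carrier_fraction="CD4", depths={"CD4": 200, "CD8": 200},
            contamination=0.0, error_rate=0.0, seed=11,
        )
        fr = simulate_paired_fractions(cfg)
        calls = call_paired_somatic([fr["CD8"]], [fr["CD4"]])
        assert len(calls) == 1 and calls[0].status == "candidate"
        assert calls[0].somatic_p < 0.05


class TestWriteVcf:
    def test_empty_call_list_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_vcf([], str(path))
        lines = path.read_text().splitlines()
        assert all(line.startswith("#") for line in lines)
        assert lines[0] == "##fileformat=VCFv4.2"

    def test_panel_roundtrip_through_pysam(self, panel_maps, tmp_path):
        pysam = pytest.importorskip("pysam")
        normal, tumor, genes = panel_maps
        calls = call_paired_somatic(normal, tumor, genes=genes)
        path = tmp_path / "panel.vcf"
        write_vcf(calls, str(path))
        records = list(pysam.VariantFile(str(path)))
        assert len(records) == 14
        by_site = {(r.chrom, r.pos): r for r in records}
        for c in calls:
            r = by_site[(c.chrom, c.pos)]
            assert r.info["TR"] == c.tumor_ref
            assert r.info["TV"] == c.tumor_var
            assert r.info["NR"] == c.normal_ref
            assert r.info["NV"] == c.normal_var
            assert r.info["SPV"] == pytest.approx(c.somatic_p, rel=1e-5)
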