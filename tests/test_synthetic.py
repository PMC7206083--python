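"""Synthetic-data generators: count conservation, seed determinism, mean
recovery against the configured expectations, and the shapes the analysis
modules assume."""

import numpy as np
import pytest
from scipy.stats import binom

from clonetrack.synthetic import (
    FractionSimConfig,
    KillingSimConfig,
    RepertoireSimConfig,
    SeqSimConfig,
    simulate_dose_response,
    simulate_impedance,
    simulate_paired_fractions,
    simulate_pileup,
    simulate_repertoire,
)


class TestSimulatePileup:
    def test_no_variant_no_error_gives_zero_variant_reads(self):
        p = simulate_pileup(SeqSimConfig(true_vaf=0.0, depth=1000, error_rate=0.0))
        assert p.var_calls == 0 and p.qsum_var == 0.0

    def test_pure_variant_no_error_gives_all_variant_reads(self):
        p = simulate_pileup(SeqSimConfig(true_vaf=1.0, depth=500, error_rate=0.0))
        assert p.var_calls == 500

    def test_counts_conserve_depth(self):
        for seed in range(20):
            p = simulate_pileup(SeqSimConfig(true_vaf=0.3, depth=777, seed=seed))
            assert p.ref_calls + p.var_calls == 777

    def test_seed_determinism(self):
        cfg = SeqSimConfig(true_vaf=0.1, depth=5000, seed=99)
        a, b = simulate_pileup(cfg), simulate_pileup(cfg)
        assert a == b

    def test_deep_pileup_vaf_within_binomial_interval(self):
        cfg = SeqSimConfig(true_vaf=0.192, depth=1000004, seed=3)
        p = simulate_pileup(cfg)
        e = cfg.error_rate
        prob = 0.192 * (1 - e) + (1 - 0.192) * e / 3
        lo, hi = binom.ppf([0.0005, 0.9995], cfg.depth, prob)
        assert lo <= p.var_calls <= hi

    def test_mean_vaf_recovery_over_replicates(self):
        # empirical mean within 3 standard errors of the model expectation
        depth, vaf = 2000, 0.05
        e = 1e-3
        prob = vaf * (1 - e) + (1 - vaf) * e / 3
        draws = [
            simulate_pileup(
                SeqSimConfig(true_vaf=vaf, depth=depth, seed=s)
            ).var_calls
            for s in range(1000)
        ]
        se = np.sqrt(prob * (1 - prob) * depth / len(draws))
        assert abs(np.mean(draws) - prob * depth) < 3 * se

    def test_invalid_config_raises(self):
        with pytest.raises(ValueError):
            SeqSimConfig(true_vaf=1.5, depth=100)
        with pytest.raises(ValueError):
            SeqSimConfig(true_vaf=0.1, depth=0)
        with pytest.raises(ValueError):
            SeqSimConfig(true_vaf=0.1, depth=100, error_rate=float("nan"))


class TestSimulatePairedFractions:
    CFG = dict(
        clone_vaf=0.192,
        host_fractions=("CD4", "CD8"),
        carrier_fraction="CD4",
        depths={"CD4": 20000, "CD8": 20000},
    )

    def test_unknown_carrier_raises(self):
        with pytest.raises(ValueError):
            FractionSimConfig(**{**self.CFG, "carrier_fraction": "NK"})

    def test_seed_determinism(self):
        cfg = FractionSimConfig(**self.CFG, contamination=0.1, seed=4)
        a = simulate_paired_fractions(cfg)
        b = simulate_paired_fractions(cfg)
        assert a == b

    def test_zero_contamination_non_carrier_at_error_floor(self):
        cfg = FractionSimConfig(**self.CFG, contamination=0.0, seed=1)
        fr = simulate_paired_fractions(cfg)
        # non-carrier variant reads come from the error floor e/3 only
        e = cfg.error_rate / 3
        hi = binom.ppf(0.9999, 20000, e)
        assert fr["CD8"].var_calls <= hi

    def test_contamination_product_recovered_by_monte_carlo(self):
        cfg_base = {**self.CFG, "contamination": 0.3}
        counts = [
            simulate_paired_fractions(FractionSimConfig(**cfg_base, seed=s))[
                "CD8"
            ].var_calls
            for s in range(300)
        ]
        e = 1e-3
        v = 0.3 * 0.192  # expected non-carrier VAF ~ 0.0576
        prob = v * (1 - e) + (1 - v) * e / 3
        se = np.sqrt(prob * (1 - prob) * 20000 / len(counts))
        assert abs(np.mean(counts) - prob * 20000) < 3 * se


class TestSimulateRepertoire:
    def test_single_clone_when_fraction_one(self):
        rep = simulate_repertoire(
            RepertoireSimConfig(
                n_cells=100, expanded_clone_fraction=1.0,
                orphan_split_fraction=0.0, n_background_clones=0,
            )
        )
        assert len(rep.clonotypes) == 1 and rep.total_cells == 100

    def test_published_clone_structure_in_expectation(self):
        cfg = RepertoireSimConfig(
            n_cells=14111, expanded_clone_fraction=0.475,
            orphan_split_fraction=0.30, seed=0,
        )
        rep = simulate_repertoire(cfg)
        assert rep.total_cells == 14111
        paired = max(
            (c for c in rep.clonotypes if c.is_paired), key=lambda c: c.cells
        )
        orphan = max(
            (c for c in rep.clonotypes if c.is_beta_only), key=lambda c: c.cells
        )
        # 4669-like and 2038-like cell counts
        assert paired.cells == pytest.approx(4692, abs=5)
        assert orphan.cells == pytest.approx(2011, abs=5)
        assert orphan.beta_nt == paired.beta_nt
        assert orphan.beta_key == paired.beta_key

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError):
            RepertoireSimConfig(n_cells=10, expanded_clone_fraction=1.2)


class TestSimulateImpedance:
    def test_zero_killing_rate_matches_control(self):
        traces = simulate_impedance(
            KillingSimConfig(killing_rate=0.0, et_ratios=(8.0,), noise_sd=0.0)
        )
        np.testing.assert_allclose(traces[1].resistance, traces[0].resistance)

    def test_terminal_nci_monotone_in_et_ratio(self):
        traces = simulate_impedance(KillingSimConfig(noise_sd=0.0))
        finals = [t.resistance[-1] for t in traces]
        # control highest, then strictly decreasing with E:T ratio
        assert all(b < a for a, b in zip(finals, finals[1:]))

    def test_noise_free_repeat_runs_identical(self):
        cfg = KillingSimConfig(noise_sd=0.0, seed=1)
        a = simulate_impedance(cfg)
        b = simulate_impedance(cfg)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.resistance, tb.resistance)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            KillingSimConfig(dt=0.0)
        with pytest.raises(ValueError):
            KillingSimConfig(t_add=50.0, duration=45.0)


class TestSimulateDoseResponse:
    def test_inactive_drug_inhibition_zero_everywhere(self):
        curve = simulate_dose_response(50.0, 1.0, top=100.0, bottom=100.0)
        assert curve.flat
        assert all(y == 0.0 for y in curve.inhibition)

    def test_default_doses_span_ten_thousand_fold(self):
        curve = simulate_dose_response(50.0, 1.0)
        assert curve.doses[-1] / curve.doses[0] == pytest.approx(1e4)

    def test_noise_is_seeded(self):
        a = simulate_dose_response(50.0, 1.0, noise_sd=3.0, seed=7)
        b = simulate_dose_response(50.0, 1.0, noise_sd=3.0, seed=7)
        assert a.inhibition == b.inhibition
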