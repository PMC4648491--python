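import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smartddpcr import (
    ChannelConcentration,
    DropletWell,
    clone_population,
    estimate_channel_concentration,
    simulate_sample,
    simulate_well,
)
from smartddpcr.droplet import simulate_droplet_classes
from smartddpcr.errors import SaturationError, ValidationError

VOL = 0.00085


class TestEstimateChannelConcentration:
    def test_no_positive_droplets_gives_zero(self):
        est = estimate_channel_concentration(0, 10000, VOL)
        assert est.concentration_copies_per_ul == 0.0
        assert est.lambda_hat == 0.0
        assert est.ci_low == 0.0

    def test_half_positive_closed_form(self):
        # independent closed form: -ln(0.5) / V
        expected = -math.log(0.5) / VOL
        est = estimate_channel_concentration(5000, 10000, VOL)
        assert est.lambda_hat == pytest.approx(math.log(2), abs=1e-12)
        assert est.concentration_copies_per_ul == pytest.approx(expected, rel=1e-12)
        assert est.concentration_copies_per_ul == pytest.approx(815.47, abs=0.01)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            estimate_channel_concentration(10000, 10000, VOL)

    @pytest.mark.parametrize(
        "n_pos,n_total,vol", [(-1, 100, VOL), (5, 0, VOL), (200, 100, VOL), (5, 100, 0.0)]
    )
    def test_validation_errors(self, n_pos, n_total, vol):
        with pytest.raises(ValidationError):
            estimate_channel_concentration(n_pos, n_total, vol)

    def test_strictly_increasing_in_n_pos(self):
        concs = [
            estimate_channel_concentration(k, 5000, VOL).concentration_copies_per_ul
            for k in range(0, 5000, 61)
        ]
        assert all(b > a for a, b in zip(concs, concs[1:]))

    def test_lambda_equals_concentration_times_volume(self):
        est = estimate_channel_concentration(1234, 9876, VOL)
        assert est.lambda_hat == pytest.approx(
            est.concentration_copies_per_ul * VOL, rel=1e-12
        )

    def test_ci_brackets_point_estimate(self):
        for n_pos in (1, 50, 9999):
            est = estimate_channel_concentration(n_pos, 10000, VOL)
            assert est.ci_low <= est.concentration_copies_per_ul <= est.ci_high


class TestSimulateWell:
    def test_zero_concentration_zero_positives(self):
        well = simulate_well(0.0, 0.0, 10000, VOL, seed=7)
        assert well.n_fam_pos == 0
        assert well.n_vic_pos == 0

    def test_reproducible_bit_exact(self):
        a = simulate_well(800.0, 400.0, 20000, VOL, seed=99)
        b = simulate_well(800.0, 400.0, 20000, VOL, seed=99)
        assert (a.n_fam_pos, a.n_vic_pos) == (b.n_fam_pos, b.n_vic_pos)
        c = simulate_well(800.0, 400.0, 20000, VOL, seed=100)
        assert (a.n_fam_pos, a.n_vic_pos) != (c.n_fam_pos, c.n_vic_pos)

    def test_saturated_channel_fails_downstream(self):
        well = simulate_well(1e7, 0.0, 1000, VOL, seed=3)
        assert well.n_fam_pos == well.n_total
        with pytest.raises(SaturationError):
            estimate_channel_concentration(well.n_fam_pos, well.n_total, VOL)

    def test_ci_coverage_at_800(self):
        hits = 0
        for seed in range(200):
            well = simulate_well(800.0, 800.0, 10000, VOL, seed=seed)
            est = estimate_channel_concentration(well.n_fam_pos, well.n_total, VOL)
            hits += est.ci_low <= 800.0 <= est.ci_high
        assert hits >= 0.95 * 200

    @pytest.mark.parametrize("lam", [0.05, 0.2, 0.5, 1.0])
    def test_round_trip_mean_and_coverage(self, lam):
        conc_true = lam / VOL
        n_droplets = 20000
        estimates, covered = [], 0
        for seed in range(200):
            well = simulate_well(conc_true, 0.0, n_droplets, VOL, seed=10_000 + seed)
            est = estimate_channel_concentration(well.n_fam_pos, n_droplets, VOL)
            estimates.append(est.concentration_copies_per_ul)
            covered += est.ci_low <= conc_true <= est.ci_high
        assert np.mean(estimates) == pytest.approx(conc_true, rel=0.02)
        assert covered >= 0.93 * 200

    def test_channel_independence_double_positive_rate(self):
        n = 200000
        neg, fam_only, vic_only, double = simulate_droplet_classes(
            600.0, 900.0, n, VOL, seed=5
        )
        p_fam = (fam_only + double) / n
        p_vic = (vic_only + double) / n
        # independence: double-positive rate ~ product of marginals
        se = math.sqrt(p_fam * p_vic * (1 - p_fam * p_vic) / n)
        assert double / n == pytest.approx(p_fam * p_vic, abs=4 * se)

    def test_cross_reactivity_increases_positives(self):
        clean = simulate_well(0.0, 900.0, 50000, VOL, seed=11)
        leaky = simulate_well(0.0, 900.0, 50000, VOL, seed=11, cross_reactivity=0.5)
        assert clean.n_fam_pos == 0
        assert leaky.n_fam_pos > 0


class TestClonePopulation:
    def test_diploid_heterozygote(self):
        pop = clone_population([(1.0, 1, 1, 2)], 800.0)
        assert pop.expected_proportion() == pytest.approx(0.5)
        assert pop.expected_normalized_cn() == pytest.approx(1.0)

    def test_subclonal_hemizygous_deletion(self):
        # half the cells lost the protective allele: weighted copies
        # risk = 1, prot = 0.5, control = 2 -> proportion 1/1.5, cn 1.5/2
        pop = clone_population([(0.5, 1, 0, 2), (0.5, 1, 1, 2)], 800.0)
        assert pop.expected_proportion() == pytest.approx(1 / 1.5)
        assert pop.expected_normalized_cn() == pytest.approx(0.75)

    def test_clonal_trisomy(self):
        pop = clone_population([(1.0, 2, 1, 2)], 800.0)
        assert pop.expected_proportion() == pytest.approx(2 / 3)
        assert pop.expected_normalized_cn() == pytest.approx(1.5)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            clone_population([(0.5, 1, 1, 2), (0.4, 1, 1, 2)], 800.0)

    def test_all_zero_control_copies_rejected(self):
        with pytest.raises(ValidationError):
            clone_population([(1.0, 1, 1, 0)], 800.0)


class TestSimulateSample:
    def test_replicate_structure_and_determinism(self):
        pop = clone_population([(1.0, 1, 1, 2)], 800.0)
        snp, ctrl = simulate_sample(pop, 15000, VOL, n_replicates=2, seed=42)
        snp2, ctrl2 = simulate_sample(pop, 15000, VOL, n_replicates=2, seed=42)
        assert len(snp) == len(ctrl) == 2
        assert snp == snp2 and ctrl == ctrl2
        assert all(w.assay_id == "snp" for w in snp)
        assert all(w.assay_id == "control" for w in ctrl)
        # control assay is single-channel
        assert all(w.n_vic_pos == 0 for w in ctrl)

    def test_replicates_differ_between_each_other(self):
        pop = clone_population([(1.0, 1, 1, 2)], 800.0)
        snp, _ = simulate_sample(pop, 15000, VOL, n_replicates=2, seed=42)
        assert (snp[0].n_fam_pos, snp[0].n_vic_pos) != (snp[1].n_fam_pos, snp[1].n_vic_pos)

    def test_invalid_replicates(self):
        pop = clone_population([(1.0, 1, 1, 2)], 800.0)
        with pytest.raises(ValidationError):
            simulate_sample(pop, 15000, VOL, n_replicates=0, seed=1)


class TestDomainTypes:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_total=0, n_fam_pos=0, n_vic_pos=0),
            dict(n_total=100, n_fam_pos=101, n_vic_pos=0),
            dict(n_total=100, n_fam_pos=0, n_vic_pos=-1),
            dict(n_total=100, n_fam_pos=0, n_vic_pos=0, droplet_volume_ul=0.0),
        ],
    )
    def test_well_invariants(self, kwargs):
        base = dict(well_id="w", sample_id="s", assay_id="a", droplet_volume_ul=VOL)
        base.update(kwargs)
        with pytest.raises(ValidationError):
            DropletWell(**base)

    def test_channel_concentration_interval_invariant(self):
        with pytest.raises(ValidationError):
            ChannelConcentration(
                concentration_copies_per_ul=10.0, ci_low=11.0, ci_high=12.0, lambda_hat=0.0085
            )

    @given(
        n_total=st.integers(min_value=10, max_value=30000),
        frac=st.floats(min_value=0.0, max_value=0.999),
    )
    @settings(max_examples=60, deadline=None)
    def test_estimator_monotone_property(self, n_total, frac):
        n_pos = int(frac * n_total)
        est = estimate_channel_concentration(n_pos, n_total, VOL)
        if n_pos + 1 < n_total:
            est2 = estimate_channel_concentration(n_pos + 1, n_total, VOL)
            assert est2.concentration_copies_per_ul > est.concentration_copies_per_ul
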