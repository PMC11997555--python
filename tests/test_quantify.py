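import math

import numpy as np
import pytest

from ddvcn import (
    ConcentrationEstimate,
    aggregate_replicates,
    compute_vcn_bulk,
    estimate_concentration,
)
from ddvcn.quantify import ReferenceFailureError, SaturationError, VCNResult


def make_estimate(conc, n=20000, v=0.00085):
    """Back out the negative count yielding the requested concentration."""
    n_neg = round(n * math.exp(-conc * v))
    return estimate_concentration(n_neg, n, v)


class TestEstimateConcentration:
    def test_all_negative_gives_zero_with_zero_lower_bound(self):
        est = estimate_concentration(10000, 10000, 0.00085)
        assert est.copies_per_ul == 0
        assert est.ci_low == 0

    def test_direct_formula_arithmetic(self):
        # negative fraction 0.3679 => lambda ~ 1.0 => ~1176.5 copies/ul
        est = estimate_concentration(7358, 20000, 0.00085)
        assert est.copies_per_ul == pytest.approx(1176.5, abs=0.5)
        assert est.ci_low < est.copies_per_ul < est.ci_high

    def test_saturated_well_rejected(self):
        with pytest.raises(SaturationError):
            estimate_concentration(0, 20000, 0.00085)

    def test_empty_well_rejected(self):
        with pytest.raises(ValueError):
            estimate_concentration(0, 0, 0.00085)

    def test_exact_inverse_of_partitioning_model(self):
        """-ln(e^-cV)/V returns c to machine precision for any c, V."""
        for conc in [5.0, 120.0, 1176.47, 2500.0]:
            v = 0.00085
            p_neg = math.exp(-conc * v)
            lam = -math.log(p_neg) / v
            assert lam == pytest.approx(conc, rel=1e-12)


class TestComputeVcnBulk:
    def test_equal_concentrations_give_diploid_two(self):
        res = compute_vcn_bulk(make_estimate(200), make_estimate(200))
        assert res.vcn_bulk == pytest.approx(2.0, rel=1e-6)

    def test_quarter_ratio(self):
        res = compute_vcn_bulk(make_estimate(50), make_estimate(200))
        assert res.vcn_bulk == pytest.approx(0.5, rel=2e-3)

    def test_zero_reference_is_an_error(self):
        with pytest.raises(ReferenceFailureError):
            compute_vcn_bulk(make_estimate(50), estimate_concentration(100, 100, 0.00085))

    def test_scale_invariance(self):
        """Multiplying both channel concentrations by c leaves VCN unchanged."""
        a = compute_vcn_bulk(make_estimate(50), make_estimate(100)).vcn_bulk
        b = compute_vcn_bulk(make_estimate(250), make_estimate(500)).vcn_bulk
        assert a == pytest.approx(b, rel=2e-3)

    def test_below_lloq_flagging(self):
        res = compute_vcn_bulk(make_estimate(3), make_estimate(200), lloq=6.4)
        assert "below_lloq" in res.qc_flags
        res = compute_vcn_bulk(make_estimate(50), make_estimate(200), lloq=6.4)
        assert "below_lloq" not in res.qc_flags

    def test_ci_brackets_estimate(self):
        res = compute_vcn_bulk(make_estimate(80), make_estimate(300))
        lo, hi = res.vcn_bulk_ci
        assert lo <= res.vcn_bulk <= hi


class TestAggregateReplicates:
    def _result(self, vcn, n=20000):
        return VCNResult(
            sample_id="s",
            vcn_bulk=vcn,
            wpre=make_estimate(100, n=n),
            tert=make_estimate(100, n=n),
        )

    def test_single_replicate_flagged(self):
        agg = aggregate_replicates([self._result(2.0)])
        assert agg.vcn_bulk == 2.0
        assert math.isnan(agg.replicate_sd)
        assert "single_replicate" in agg.qc_flags

    def test_identical_replicates_zero_cv(self):
        agg = aggregate_replicates([self._result(2.0)] * 3)
        assert agg.vcn_bulk == 2.0
        assert agg.replicate_cv_pct == 0.0

    def test_hand_computed_dispersion(self):
        agg = aggregate_replicates([self._result(v) for v in (1.9, 2.0, 2.1)])
        assert agg.vcn_bulk == pytest.approx(2.0)
        assert agg.replicate_sd == pytest.approx(0.1)
        assert agg.replicate_cv_pct == pytest.approx(5.0)

    def test_weighting_by_accepted_droplets(self):
        heavy = self._result(3.0, n=40000)
        light = self._result(1.0, n=10000)
        agg = aggregate_replicates([heavy, light])
        assert agg.vcn_bulk == pytest.approx((3.0 * 40000 + 1.0 * 10000) / 50000)

    def test_mixed_sample_ids_rejected(self):
        a = self._result(2.0)
        b = self._result(2.0)
        b.sample_id = "other"
        with pytest.raises(ValueError):
            aggregate_replicates([a, b])


def test_concentration_estimate_invariants_enforced():
    with pytest.raises(ValueError):
        ConcentrationEstimate(10, 20, 30, 100, 50, 0.00085)  # CI above estimate
    with pytest.raises(ValueError):
        ConcentrationEstimate(10, 5, 30, 100, 200, 0.00085)  # n_negative > n
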