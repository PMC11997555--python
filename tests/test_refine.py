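import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ddvcn import (
    CellProductConfig,
    adjust_vcn,
    simulate_cell_product,
    untransduced_fraction_check,
    vcn_distribution,
)
from conftest import PRODUCT_TABLE


class TestAdjustVcn:
    @pytest.mark.parametrize(
        "bulk, adj", [(v[0], v[1]) for v in PRODUCT_TABLE.values()]
    )
    def test_reference_products(self, bulk, adj):
        """Zero-truncated adjustment reproduces the six reference products
        at 2-decimal precision."""
        vcn_adj, _ = adjust_vcn(bulk)
        assert round(vcn_adj, 2) == adj

    def test_putative_transduction_hand_value(self):
        _, transduction = adjust_vcn(0.57)
        assert transduction == pytest.approx(1 - math.exp(-0.57), abs=1e-12)
        assert transduction == pytest.approx(0.4345, abs=5e-5)

    def test_zero_bulk_yields_undefined_sentinel(self):
        vcn_adj, transduction = adjust_vcn(0.0)
        assert math.isnan(vcn_adj)
        assert transduction == 0.0

    def test_negative_bulk_rejected(self):
        with pytest.raises(ValueError):
            adjust_vcn(-0.1)

    def test_small_bulk_limit_approaches_one(self):
        vcn_adj, _ = adjust_vcn(1e-9)
        assert vcn_adj == pytest.approx(1.0, abs=1e-8)

    @given(st.floats(1e-6, 20))
    @settings(max_examples=200)
    def test_inverse_identity(self, bulk):
        """vcn_adj * (1 - e^-bulk) == bulk to near machine precision."""
        vcn_adj, transduction = adjust_vcn(bulk)
        assert vcn_adj * transduction == pytest.approx(bulk, rel=1e-12)
        assert vcn_adj >= max(1.0, bulk)

    def test_monotone_and_asymptotic(self):
        xs = np.linspace(0.01, 10, 500)
        adj = np.array([adjust_vcn(x)[0] for x in xs])
        assert (np.diff(adj) > 0).all()
        assert adj[-1] - xs[-1] < 1e-3  # difference vanishes at large bulk VCN


class TestVcnDistribution:
    def test_poisson_zero_class(self):
        d = vcn_distribution(1.0)
        assert d.pmf[0] == pytest.approx(math.exp(-1.0), abs=1e-12)

    @pytest.mark.parametrize("lam", [0.57, 1.07, 2.23, 2.97, 8.47, 9.00])
    def test_normalisation_and_truncated_mean(self, lam):
        full = vcn_distribution(lam, support_max=200)
        trunc = vcn_distribution(lam, support_max=200, truncated=True)
        for d in (full, trunc):
            assert sum(d.pmf.values()) == pytest.approx(1.0, abs=1e-9)
        assert trunc.pmf[0] == 0.0
        mean_trunc = sum(k * p for k, p in trunc.pmf.items())
        assert mean_trunc == pytest.approx(adjust_vcn(lam)[0], abs=1e-8)
        mean_full = sum(k * p for k, p in full.pmf.items())
        assert mean_full == pytest.approx(lam, abs=1e-8)

    def test_high_copy_product_tail(self):
        """At lambda = 9, about 41% of cells exceed VCN 9 — roughly half the
        product carries more copies than the mean."""
        d = vcn_distribution(9.0)
        assert d.cdf[9] == pytest.approx(0.587, abs=0.001)
        assert d.fraction_above(9) == pytest.approx(0.413, abs=0.001)

    def test_cdf_nondecreasing_and_default_support(self):
        d = vcn_distribution(2.5)
        vals = [d.cdf[k] for k in sorted(d.cdf)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert d.cdf[d.support_max] >= 0.9999
        assert d.cdf[d.support_max - 1] < 0.9999

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            vcn_distribution(0.0)

    def test_simulation_closure_chi_square(self):
        """Empirical per-cell VCN histogram matches the Poisson pmf."""
        lam, n = 2.0, 100000
        prod = simulate_cell_product(CellProductConfig(n_cells=n, lambda_vcn=lam, seed=77))
        kmax = int(prod.copies_per_cell.max())
        observed = np.bincount(prod.copies_per_cell, minlength=kmax + 1).astype(float)
        expected = stats.poisson.pmf(np.arange(kmax + 1), lam) * n
        # pool the sparse tail so every expected count is >= 5
        cut = np.searchsorted(np.cumsum(expected[::-1]), 5)
        cut = len(expected) - cut
        obs = np.append(observed[:cut], observed[cut:].sum())
        exp = np.append(expected[:cut], expected[cut:].sum())
        stat, p = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 0.001


class TestUntransducedFractionCheck:
    def test_reference_sample_direction(self):
        chk = untransduced_fraction_check(0.57, 1 - 0.272)
        assert chk.theoretical_negative == pytest.approx(0.5655, abs=5e-4)
        assert not chk.theory_exceeds_flow

    def test_zero_bulk_all_untransduced(self):
        chk = untransduced_fraction_check(0.0, 0.5)
        assert chk.theoretical_negative == 1.0
        assert chk.theory_exceeds_flow

    def test_all_reference_products_theory_below_flow(self):
        """Poisson-predicted untransduced fraction sits below the flow
        value for every product: marker-negative cells can carry vector."""
        for bulk, _, flow_pct in PRODUCT_TABLE.values():
            chk = untransduced_fraction_check(bulk, 1 - flow_pct / 100)
            assert not chk.theory_exceeds_flow
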