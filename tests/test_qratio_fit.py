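"""Wasserstein machinery, q fitting, bootstrap and flux accounting."""

import math

import numpy as np
import pytest
from scipy import stats

from synflux.jump_model import tabulate_pmf
from synflux.qratio_fit import (
    _bootstrap_ranks,
    bootstrap_q,
    fit_q,
    flux_accounting,
    pair_discrepancy,
    total_discrepancy,
    wasserstein1,
)
from synflux.synteny_metrics import GeneContentSummary, PairComparison, SBLDistribution
from synflux.synthetic_data import SyntheticParams, make_clade
from synflux.synteny_metrics import compare_all_pairs


def model_pair(name, d, lam, summary=GeneContentSummary(1000, 1000, 900)):
    """A pair whose observed SBL is exactly the model pmf at the given lambda."""
    p = tabulate_pmf(lam)
    sbl = SBLDistribution({k + 1: float(x) for k, x in enumerate(p)})
    return PairComparison(f"{name}a", f"{name}b", summary, d, sbl, None)


class TestWasserstein1:
    @pytest.mark.parametrize(
        "p,q,expected",
        [
            ({1: 0.5, 2: 0.5}, {1: 0.5, 2: 0.5}, 0.0),
            ({1: 1.0}, {3: 1.0}, 2.0),
            ({1: 0.5, 2: 0.5}, {1: 1.0}, 0.5),
        ],
    )
    def test_hand_computed_examples(self, p, q, expected):
        assert wasserstein1(p, q) == pytest.approx(expected, abs=1e-12)
        assert wasserstein1(q, p) == pytest.approx(expected, abs=1e-12)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            wasserstein1({1: 0.5, 2: 0.6}, {1: 1.0})

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            ka = np.unique(rng.integers(1, 40, size=rng.integers(1, 8)))
            kb = np.unique(rng.integers(1, 40, size=rng.integers(1, 8)))
            wa = rng.dirichlet(np.ones(len(ka)))
            wb = rng.dirichlet(np.ones(len(kb)))
            mine = wasserstein1(dict(zip(ka.tolist(), wa)), dict(zip(kb.tolist(), wb)))
            ref = stats.wasserstein_distance(ka, kb, wa, wb)
            assert mine == pytest.approx(ref, abs=1e-9)


class TestPairDiscrepancy:
    def test_zero_when_observed_equals_model(self):
        pair = model_pair("p", d=0.05, lam=0.2 * 0.05)
        assert pair_discrepancy(pair, 0.2) < 1e-9

    def test_gcd_zero_is_an_error(self):
        pair = PairComparison("a", "b", GeneContentSummary(10, 10, 10), 0.0,
                              SBLDistribution({5: 2}), 5.0)
        with pytest.raises(ValueError, match="gcd"):
            pair_discrepancy(pair, 0.5)

    def test_true_q_beats_distant_q_on_synthetic_clades(self):
        q_true = 0.2
        wins = 0
        for seed in range(5):
            ds, _ = make_clade(SyntheticParams(n_genes=2000, q_true=q_true,
                                               d_range=(0.04, 0.1), seed=seed))
            pairs = [p for p in compare_all_pairs(ds) if p.usable]
            if total_discrepancy(pairs, q_true) < total_discrepancy(pairs, 10 * q_true):
                wins += 1
        assert wins >= 4


class TestFitQ:
    def test_self_consistency_recovers_q(self):
        pairs = [model_pair(f"p{i}", d, 0.2 * d) for i, d in enumerate([0.03, 0.05, 0.08, 0.1])]
        fit = fit_q(pairs)
        assert fit.q_star == pytest.approx(0.2, rel=1e-3)
        assert fit.boundary_flag == "interior"
        assert fit.n_pairs_used == 4

    def test_no_usable_pairs_raises(self):
        pair = PairComparison("a", "b", GeneContentSummary(5, 5, 5), 0.0, None, None,
                              usable=False, reason="identical")
        with pytest.raises(ValueError, match="no usable"):
            fit_q([pair])

    def test_fully_scrambled_pairs_hit_high_bound(self):
        pairs = [
            PairComparison(f"a{i}", f"b{i}", GeneContentSummary(600, 600, 500), 0.05,
                           SBLDistribution({1: 500}), 1.0)
            for i in range(3)
        ]
        assert fit_q(pairs).boundary_flag == "high_bound"

    def test_refined_optimum_never_exceeds_grid_best(self):
        pairs = [model_pair(f"p{i}", d, 0.31 * d) for i, d in enumerate([0.04, 0.09])]
        fit = fit_q(pairs)
        grid = np.geomspace(1e-3, 10.0, 200)
        grid_best = min(total_discrepancy(pairs, q) for q in grid)
        assert fit.objective_at_optimum <= grid_best + 1e-12


class TestBootstrap:
    def test_rank_indices(self):
        assert _bootstrap_ranks(100) == (6, 95)
        lo, hi = _bootstrap_ranks(50)
        assert 1 <= lo < hi <= 50

    def test_deterministic_given_seed(self):
        ds, _ = make_clade(SyntheticParams(n_genes=1000, q_true=0.3,
                                           d_range=(0.04, 0.12), seed=2))
        pairs = compare_all_pairs(ds)
        b1 = bootstrap_q(pairs, B=20, seed=9)
        b2 = bootstrap_q(pairs, B=20, seed=9)
        assert b1 == b2

    def test_degenerate_identical_pairs_are_robust(self):
        pair = model_pair("p", d=0.05, lam=0.01)
        boot = bootstrap_q([pair, pair], B=100, seed=1)
        assert boot.rank_low == boot.rank_high
        assert boot.robust

    def test_conflicting_pairs_are_not_robust(self):
        # one near-intact pair (favors tiny q) vs one scrambled pair (favors huge q)
        calm = model_pair("calm", d=0.05, lam=0.005)
        wild = PairComparison("wa", "wb", GeneContentSummary(600, 600, 500), 0.05,
                              SBLDistribution({1: 500}), 1.0)
        boot = bootstrap_q([calm, wild], B=100, seed=4)
        assert boot.rank_high / boot.rank_low > 2
        assert not boot.robust

    def test_fewer_than_two_pairs_raises(self):
        with pytest.raises(ValueError, match=">= 2"):
            bootstrap_q([model_pair("p", 0.05, 0.01)], B=10, seed=0)


class TestFluxAccounting:
    @pytest.mark.parametrize(
        "q,pairs_per,flux_frac",
        [(0.2, 5.0, 1 / 1.2), (1 / 13, 13.0, 13 / 14), (1.0, 1.0, 0.5)],
    )
    def test_convention(self, q, pairs_per, flux_frac):
        acct = flux_accounting(q)
        assert acct.pairs_per_translocation == pytest.approx(pairs_per)
        assert acct.flux_fraction == pytest.approx(flux_frac)

    def test_flux_and_translocation_fractions_sum_to_one(self):
        for q in (0.05, 0.13, 0.7, 2.5):
            acct = flux_accounting(q)
            translocation_fraction = q / (1 + q)
            assert acct.flux_fraction + translocation_fraction == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("bad", [0.0, -0.3, math.inf])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            flux_accounting(bad)
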