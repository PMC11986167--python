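"""Band-search correctness: OLS oracle, naive-loop equivalence, ranking rules."""

import itertools

import numpy as np
import pytest

import vinespec as vs
from vinespec.bandsearch import (
    BudgetExceededError,
    correlogram_2d,
    correlogram_3d,
    fit_simple_regression,
    select_top_indices,
)
from vinespec.indices import IndexForm

from conftest import make_toy_spectra, make_toy_traits


class TestSimpleRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_simple_regression(x, 2 * x + 1)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.pvalue < 1e-10

    def test_constant_target_degenerate(self):
        fit = fit_simple_regression(np.arange(5.0), np.full(5, 3.0))
        assert fit.r2 == 0.0
        assert fit.degenerate

    def test_hand_computed_ols(self):
        # x=(1..4), y=(1.1,1.9,3.2,3.8): Sxx=5, Sxy=4.7, TSS=4.5
        fit = fit_simple_regression(np.array([1, 2, 3, 4.0]),
                                    np.array([1.1, 1.9, 3.2, 3.8]))
        assert fit.slope == pytest.approx(4.7 / 5)
        assert fit.intercept == pytest.approx(2.5 - (4.7 / 5) * 2.5)
        assert fit.r2 == pytest.approx((4.7 ** 2 / 5) / 4.5)

    def test_pairwise_deletion_and_minimum_n(self):
        x = np.array([1.0, 2, np.nan, 4, 5])
        y = np.array([2.0, 4, 6, np.nan, 10])
        fit = fit_simple_regression(x, y)
        assert fit.n == 3
        with pytest.raises(ValueError, match=">= 3"):
            fit_simple_regression(np.array([1.0, 2]), np.array([1.0, 2]))


def _naive_matrix(sset, traits, trait, form):
    """Brute-force double loop over band pairs via the scalar OLS path."""
    wl = sset.wavelengths
    y = traits[trait]
    m = len(wl)
    out = np.full((m, m), np.nan)
    for i, j in itertools.product(range(m), range(m)):
        if i == j:
            continue
        a, b = sset.reflectance[:, i], sset.reflectance[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            if form is IndexForm.RSI2:
                x = np.where(b == 0, np.nan, a / b)
            else:
                den = a + b
                x = np.where(den == 0, np.nan, (a - b) / den)
        fit = fit_simple_regression(x, y)
        out[i, j] = np.nan if fit.degenerate else fit.r2
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("form", [IndexForm.RSI2, IndexForm.NDI2])
    def test_2d_matches_naive_loop(self, form):
        sset = make_toy_spectra(n_samples=25, n_bands=20, seed=4)
        traits = make_toy_traits(sset, seed=5)
        got = correlogram_2d(sset, traits, "An", form, stride=10).matrix
        want = _naive_matrix(sset, traits, "An", form)
        assert np.allclose(got, want, equal_nan=True, atol=1e-10)

    def test_3d_top1_matches_naive_triple_loop(self):
        sset = make_toy_spectra(n_samples=20, n_bands=12, seed=6)
        traits = make_toy_traits(sset, seed=7)
        wl = sset.wavelengths
        best = (None, -1.0)
        for a in wl:
            for b, c in itertools.combinations_with_replacement(wl, 2):
                d = vs.IndexDefinition("t", IndexForm.NDI3, (a, b, c))
                fit = fit_simple_regression(vs.evaluate_index(sset, d),
                                            traits["An"])
                r2 = np.nan if fit.degenerate else fit.r2
                if np.isfinite(r2) and r2 > best[1]:
                    best = ((a, b, c), r2)
        cg = correlogram_3d(sset, traits, "An", stride=10, top_k=1)
        (trip, r2) = cg.triplets[0]
        assert trip == tuple(map(float, best[0]))
        assert r2 == pytest.approx(best[1], abs=1e-10)

    def test_pair_counts(self):
        sset = make_toy_spectra(n_bands=15, seed=8)
        traits = make_toy_traits(sset, seed=9)
        n = 15
        rsi = correlogram_2d(sset, traits, "An", IndexForm.RSI2, stride=10)
        assert np.isfinite(rsi.matrix).sum() == n * (n - 1)
        ndi = correlogram_2d(sset, traits, "An", IndexForm.NDI2, stride=10)
        iu = np.triu_indices(n, 1)
        assert np.isfinite(ndi.matrix[iu]).sum() == n * (n - 1) // 2


class TestCorrelogramProperties:
    def test_ndi2_matrix_symmetric_with_nan_diagonal(self):
        sset = make_toy_spectra(n_bands=10, seed=10)
        traits = make_toy_traits(sset, seed=11)
        cg = correlogram_2d(sset, traits, "TSS", IndexForm.NDI2, stride=10)
        assert np.all(np.isnan(np.diag(cg.matrix)))
        assert np.allclose(cg.matrix, cg.matrix.T, equal_nan=True)

    def test_all_r2_within_unit_interval(self, dataset):
        cg = correlogram_2d(dataset.spectra, dataset.traits, "An",
                            IndexForm.NDI2, stride=32)
        vals = cg.matrix[np.isfinite(cg.matrix)]
        assert np.all((vals >= 0) & (vals <= 1))

    def test_planted_ndi3_recovered_exactly(self):
        sset = make_toy_spectra(n_samples=40, n_bands=12, seed=12)
        target = (sset.wavelengths[2], sset.wavelengths[5], sset.wavelengths[9])
        d = vs.IndexDefinition("p", IndexForm.NDI3, target)
        y = 3.0 * vs.evaluate_index(sset, d) + 1.0
        import pandas as pd

        traits = vs.TraitTable(list(sset.sample_ids),
                               pd.DataFrame({"An": y, "TSS": y, "TA": np.ones_like(y)}),
                               groups=list(sset.groups))
        cg = correlogram_3d(sset, traits, "An", stride=10, top_k=1)
        trip, r2 = cg.triplets[0]
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert trip[0] == target[0] and set(trip[1:]) == set(target[1:])

    def test_coarser_stride_is_nested_subset(self):
        sset = make_toy_spectra(n_bands=16, seed=13)
        traits = make_toy_traits(sset, seed=14)
        fine = correlogram_2d(sset, traits, "An", IndexForm.NDI2, stride=10)
        coarse = correlogram_2d(sset, traits, "An", IndexForm.NDI2, stride=20)
        idx = np.searchsorted(fine.wavelengths, coarse.wavelengths)
        assert np.allclose(coarse.matrix, fine.matrix[np.ix_(idx, idx)],
                           equal_nan=True)

    def test_invalid_stride_rejected(self):
        sset = make_toy_spectra(n_bands=10, seed=1)
        traits = make_toy_traits(sset, seed=1)
        with pytest.raises(ValueError, match="stride"):
            correlogram_2d(sset, traits, "An", IndexForm.NDI2, stride=15)

    def test_triplet_budget_exceeded_names_stride(self):
        sset = make_toy_spectra(n_bands=20, seed=2)
        traits = make_toy_traits(sset, seed=2)
        with pytest.raises(BudgetExceededError, match="stride"):
            correlogram_3d(sset, traits, "An", stride=10, budget=100)


class TestSelection:
    def test_k_zero_empty_and_k_large_returns_all(self):
        sset = make_toy_spectra(n_bands=6, seed=15)
        traits = make_toy_traits(sset, seed=16)
        cg = correlogram_2d(sset, traits, "An", IndexForm.NDI2, stride=10)
        assert select_top_indices([cg], 0, sset, traits).ranked == []
        sel = select_top_indices([cg], 10_000, sset, traits)
        assert len(sel.ranked) <= 6 * 5 // 2

    def test_ranking_non_increasing_and_refit_matches(self):
        sset = make_toy_spectra(n_bands=10, seed=17)
        traits = make_toy_traits(sset, seed=18)
        res = vs.BandSearch(sset, traits, "TSS", forms=(IndexForm.RSI2,
                                                        IndexForm.NDI2),
                            stride=10).fit()
        sel = res.select_top(8)
        r2s = [r.r2 for r in sel.ranked]
        assert all(a >= b - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_tie_prefers_fewer_bands(self):
        # duplicate a 2-band winner as a degenerate-free 3-band candidate
        from vinespec.bandsearch import Correlogram

        sset = make_toy_spectra(n_bands=6, seed=19)
        traits = make_toy_traits(sset, seed=20)
        cg2 = correlogram_2d(sset, traits, "An", IndexForm.NDI2, stride=10)
        (pair, r2) = cg2.top(1)[0]
        fake3 = Correlogram(trait="An", form=IndexForm.NDI3,
                            wavelengths=sset.wavelengths, stride=10,
                            triplets=[((pair[0], pair[1], pair[1]), r2)])
        sel = select_top_indices([cg2, fake3], 1, sset, traits)
        assert len(sel.ranked[0].definition.wavelengths) == 2
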