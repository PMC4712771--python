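"""Size factors, normalization, dispersion estimation and BH adjustment."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hypoxsig as h
from hypoxsig.deseq import _gamma_irls
from hypoxsig.errors import EstimationError, ValidationError
from oracles import bh_stepup


def _cm(array, conditions=None):
    array = np.asarray(array, dtype=np.int64)
    genes = [f"g{i}" for i in range(array.shape[0])]
    samples = [f"s{j}" for j in range(array.shape[1])]
    cond = conditions or {s: "A" for s in samples}
    return h.CountMatrix(
        counts=pd.DataFrame(array, index=genes, columns=samples),
        condition_of=cond,
    )


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = _cm([[10, 10], [5, 5], [100, 100]])
        sf = h.estimate_size_factors(cm)
        np.testing.assert_allclose(sf.factors.to_numpy(), [1.0, 1.0])

    def test_doubled_sample_gives_symmetric_factors(self):
        cm = _cm([[10, 20], [4, 8], [100, 200]])
        sf = h.estimate_size_factors(cm)
        np.testing.assert_allclose(
            sf.factors.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_hand_computed_median_of_ratios(self):
        # geometric means: sqrt(200), 5, sqrt(5000); per-column ratio
        # medians are both exactly 1
        cm = _cm([[10, 20], [5, 5], [100, 50]])
        sf = h.estimate_size_factors(cm)
        np.testing.assert_allclose(sf.factors.to_numpy(), [1.0, 1.0], rtol=1e-12)

    def test_zero_in_every_gene_is_estimation_error(self):
        cm = _cm([[0, 5], [3, 0]])
        with pytest.raises(EstimationError, match="filter"):
            h.estimate_size_factors(cm)

    def test_global_scaling_leaves_factors_invariant(self):
        # the geometric-mean pseudo-reference scales with the data, so
        # scaling every sample by c cancels exactly
        rng = np.random.default_rng(3)
        base = rng.integers(1, 200, (30, 4))
        sf1 = h.estimate_size_factors(_cm(base)).factors.to_numpy()
        sf3 = h.estimate_size_factors(_cm(base * 3)).factors.to_numpy()
        np.testing.assert_allclose(sf3, sf1, rtol=1e-10)

    def test_single_sample_scaling_is_exact(self):
        # scaling sample j by c multiplies each gene's ratio in j by
        # c^((m-1)/m) and every other sample's by c^(-1/m); the medians
        # inherit the exact factors
        rng = np.random.default_rng(13)
        base = rng.integers(1, 200, (30, 4))
        c, m = 5.0, 4
        scaled = base.astype(float).copy()
        scaled[:, 0] *= c
        # keep counts integral: c * int stays integral for c = 5
        sf1 = h.estimate_size_factors(_cm(base)).factors.to_numpy()
        sf2 = h.estimate_size_factors(_cm(scaled.astype(np.int64))).factors.to_numpy()
        expect = sf1 * c ** (-1 / m)
        expect[0] = sf1[0] * c ** ((m - 1) / m)
        np.testing.assert_allclose(sf2, expect, rtol=1e-10)

    def test_gene_permutation_leaves_factors_unchanged(self):
        rng = np.random.default_rng(4)
        base = rng.integers(1, 500, (40, 5))
        perm = rng.permutation(40)
        sf1 = h.estimate_size_factors(_cm(base)).factors.to_numpy()
        sf2 = h.estimate_size_factors(_cm(base[perm])).factors.to_numpy()
        np.testing.assert_allclose(sf1, sf2, rtol=1e-12)


class TestNormalize:
    def test_unit_factors_are_identity(self, tiny_counts):
        sf = h.SizeFactors(pd.Series(1.0, index=tiny_counts.sample_ids))
        em = h.normalize(tiny_counts, sf)
        np.testing.assert_allclose(
            em.values.to_numpy(), tiny_counts.counts.to_numpy()
        )

    def test_doubling_a_factor_halves_the_column(self, tiny_counts):
        ones = pd.Series(1.0, index=tiny_counts.sample_ids)
        doubled = ones.copy()
        doubled["a1"] = 2.0
        em1 = h.normalize(tiny_counts, h.SizeFactors(ones))
        em2 = h.normalize(tiny_counts, h.SizeFactors(doubled))
        np.testing.assert_allclose(
            em2.values["a1"], em1.values["a1"] / 2.0
        )
        np.testing.assert_allclose(em2.values["b1"], em1.values["b1"])

    def test_column_ratio_medians_against_reference_are_one(self):
        rng = np.random.default_rng(8)
        cm = _cm(rng.integers(1, 300, (51, 4)))
        sf = h.estimate_size_factors(cm)
        norm = h.normalize(cm, sf).values.to_numpy()
        geo = np.exp(np.log(cm.counts.to_numpy()).mean(axis=1))
        # after normalization the median ratio to the geometric-mean
        # pseudo-reference is 1 in every sample
        ratios = norm / geo[:, None]
        np.testing.assert_allclose(np.median(ratios, axis=0), 1.0, rtol=1e-9)


class TestDispersions:
    def test_poisson_counts_have_near_zero_raw_dispersion(self):
        rng = np.random.default_rng(12)
        mu = 200.0
        counts = rng.poisson(mu, (50, 6))
        cond = {f"s{j}": ("A" if j < 3 else "B") for j in range(6)}
        cm = _cm(counts, cond)
        sf = h.SizeFactors(pd.Series(1.0, index=cm.sample_ids))
        model = h.estimate_dispersions(cm, sf)
        # true alpha = 0; MoM raw dispersions average ~0 within MC error
        assert abs(model.per_gene_raw.mean()) < 0.01

    def test_constant_dispersion_recovered(self):
        rng = np.random.default_rng(101)
        alpha, mu, n_genes = 0.2, 500.0, 500
        lam = rng.gamma(1 / alpha, mu * alpha, (n_genes, 6))
        counts = rng.poisson(lam)
        cond = {f"s{j}": ("A" if j < 3 else "B") for j in range(6)}
        cm = _cm(counts, cond)
        sf = h.SizeFactors(pd.Series(1.0, index=cm.sample_ids))
        model = h.estimate_dispersions(cm, sf)
        med = float(model.per_gene_final.median())
        assert 0.1 <= med <= 0.4

    def test_all_zero_gene_gets_zero_and_is_excluded_from_fit(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 100, (20, 4))
        counts[5] = 0
        cond = {f"s{j}": "A" for j in range(4)}
        cm = _cm(counts, cond)
        sf = h.SizeFactors(pd.Series(1.0, index=cm.sample_ids))
        model = h.estimate_dispersions(cm, sf)
        assert model.per_gene_raw.iloc[5] == 0.0
        assert model.per_gene_final.iloc[5] == 0.0

    def test_final_is_max_of_raw_and_curve(self, study_run):
        model = study_run["dispersions"]
        a0, a1 = model.fit_coeffs
        mu = study_run["truth"].genes["baseline_mean"]  # not used for check
        base = model.base_means.to_numpy()
        fitted = np.where(base > 0, a0 + a1 / np.where(base > 0, base, 1), 0.0)
        np.testing.assert_allclose(
            model.per_gene_final.to_numpy(),
            np.maximum(model.per_gene_raw.to_numpy(), fitted),
            rtol=1e-12,
        )

    def test_no_replicates_anywhere_is_an_error(self):
        cm = _cm([[5, 8], [7, 9]], {"s0": "A", "s1": "B"})
        sf = h.SizeFactors(pd.Series(1.0, index=cm.sample_ids))
        with pytest.raises(EstimationError, match="replicates"):
            h.estimate_dispersions(cm, sf)

    def test_gamma_irls_recovers_clean_curve(self):
        rng = np.random.default_rng(2)
        mu = rng.uniform(10, 1000, 300)
        disp = 0.02 + 1.5 / mu
        (a0, a1), converged = _gamma_irls(mu, disp)
        assert converged
        assert a0 == pytest.approx(0.02, rel=1e-6)
        assert a1 == pytest.approx(1.5, rel=1e-6)


class TestBH:
    def test_textbook_stepup_vector(self):
        np.testing.assert_allclose(
            h.adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(h.adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(h.adjust_bh([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            h.adjust_bh([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_literal_stepup_oracle(self, pvals):
        np.testing.assert_allclose(h.adjust_bh(pvals), bh_stepup(pvals),
                                   atol=1e-12)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 200)
        ref = statsmodels.multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(h.adjust_bh(p), ref, atol=1e-12)

    def test_padj_never_below_p(self, study_run):
        t = study_run["de_hypoxia"]
        assert (t["padj"] >= t["pval"] - 1e-15).all()
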