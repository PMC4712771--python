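import numpy as np
import pandas as pd
import pytest

import hypoxsig as h
from hypoxsig.errors import ValidationError


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return h.ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples))


class TestFitPCA:
    def test_rank1_toy_recovers_principal_axis(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 10, 40)
        x = t + rng.normal(0, 1e-3, 40)
        y = 2 * t + rng.normal(0, 1e-3, 40)
        em = _expr(np.vstack([x, y]))
        model, _ = h.fit_pca(em, transform="identity", n_components=1)
        axis = model.loadings[:, 0]
        np.testing.assert_allclose(np.abs(axis),
                                   np.array([1, 2]) / np.sqrt(5), atol=1e-3)
        assert model.explained_variance_ratio[0] > 0.999

    def test_self_projection_reproduces_fitted_coordinates(self):
        rng = np.random.default_rng(1)
        em = _expr(rng.uniform(0, 100, (30, 12)))
        model, coords = h.fit_pca(em)
        projected = h.project_samples(model, em)
        np.testing.assert_allclose(projected.to_numpy(), coords.to_numpy(),
                                   atol=1e-8)

    def test_loadings_orthonormal_and_variance_sums_to_one(self):
        rng = np.random.default_rng(2)
        em = _expr(rng.uniform(0, 50, (25, 10)))
        model, _ = h.fit_pca(em)  # all min(n-1, p) components
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-8)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(model.explained_variance_ratio) <= 1e-12).all()

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(3)
        em = _expr(rng.uniform(0, 50, (15, 8)))
        m1, c1 = h.fit_pca(em)
        m2, c2 = h.fit_pca(em)
        np.testing.assert_array_equal(m1.loadings, m2.loadings)
        for j in range(m1.n_components):
            i = np.argmax(np.abs(m1.loadings[:, j]))
            assert m1.loadings[i, j] > 0

    def test_constant_matrix_rejected(self):
        em = _expr(np.full((5, 4), 7.0))
        with pytest.raises(ValidationError, match="constant"):
            h.fit_pca(em)

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(4)
        em = _expr(rng.uniform(0, 1, (10, 4)))
        with pytest.raises(ValidationError, match="n_components"):
            h.fit_pca(em, n_components=5)

    def test_reconstruction_error_nonincreasing_in_k(self):
        rng = np.random.default_rng(5)
        em = _expr(rng.uniform(0, 100, (20, 9)))
        X = np.log2(em.values.to_numpy() + 1).T
        Xc = X - X.mean(axis=0)
        errs = []
        for k in range(1, 9):
            model, coords = h.fit_pca(em, n_components=k)
            recon = coords.to_numpy() @ model.loadings.T
            errs.append(((Xc - recon) ** 2).sum())
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_tumour_normal_shift_separates_on_pc1(self, study_run):
        sig = h.build_signature(study_run["de_hypoxia"])
        design = h.CohortDesign(n_tumour=60, n_normal=30, n_genes=800,
                                tumour_program_fraction=0.3, seed=9)
        expr, clinical, _ = h.simulate_cohort(design, sig)
        model, coords = h.fit_pca(expr, n_components=2)
        pc1 = coords["PC1"]
        tum = pc1[clinical.table["tissue"] == "tumour"]
        nor = pc1[clinical.table["tissue"] == "normal"]
        # group means on PC1 separate (opposite signs of the common mean)
        assert np.sign(tum.mean() - pc1.mean()) != np.sign(nor.mean() - pc1.mean())
        gap = abs(tum.mean() - nor.mean())
        spread = pc1.std()
        assert gap > spread  # clear separation


class TestProjectSamples:
    def test_center_sample_maps_to_origin(self):
        rng = np.random.default_rng(6)
        em = _expr(rng.uniform(0, 100, (12, 7)))
        model, _ = h.fit_pca(em)
        center_raw = 2 ** model.centers - 1  # invert the log2(x+1) transform
        probe = h.ExpressionMatrix(values=pd.DataFrame(
            {"probe": center_raw}, index=em.values.index))
        coords = h.project_samples(model, probe)
        np.testing.assert_allclose(coords.to_numpy(), 0.0, atol=1e-8)

    def test_extra_genes_in_new_samples_are_ignored(self):
        rng = np.random.default_rng(7)
        em = _expr(rng.uniform(0, 100, (12, 7)))
        model, _ = h.fit_pca(em)
        new_vals = em.values.iloc[:, :2].copy()
        with_extra = pd.concat([
            new_vals,
            pd.DataFrame(rng.uniform(0, 100, (3, 2)),
                         index=["x1", "x2", "x3"], columns=new_vals.columns),
        ])
        c1 = h.project_samples(model, h.ExpressionMatrix(values=new_vals))
        c2 = h.project_samples(model, h.ExpressionMatrix(values=with_extra))
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-10)

    def test_low_overlap_rejected_with_fraction(self):
        rng = np.random.default_rng(8)
        em = _expr(rng.uniform(0, 100, (20, 6)))
        model, _ = h.fit_pca(em)
        few = h.ExpressionMatrix(values=em.values.iloc[:5, :1])
        with pytest.raises(ValidationError, match="%"):
            h.project_samples(model, few)

    def test_missing_model_genes_imputed_at_center(self):
        rng = np.random.default_rng(9)
        em = _expr(rng.uniform(1, 100, (10, 6)))
        model, _ = h.fit_pca(em)
        # drop 3 genes from a cohort sample; imputation at center means
        # the projection equals using center values for those genes
        sample = em.values.iloc[:, [0]].copy()
        partial = h.ExpressionMatrix(values=sample.iloc[3:])
        filled = sample.copy()
        filled.iloc[:3, 0] = 2 ** model.centers[:3] - 1
        c_partial = h.project_samples(model, partial)
        c_filled = h.project_samples(model, h.ExpressionMatrix(values=filled))
        np.testing.assert_allclose(c_partial.to_numpy(), c_filled.to_numpy(),
                                   atol=1e-8)

    def test_coupled_programs_align_displacements(self, study_run):
        """With tumour and hypoxia programs coupled in the generator, the
        untreated->hypoxia displacement in PC space points with the
        normal->tumour displacement."""
        sig = h.build_signature(study_run["de_hypoxia"])
        design = h.CohortDesign(n_tumour=60, n_normal=30, n_genes=800,
                                signature_coupling=0.7, seed=10)
        expr, clinical, truth = h.simulate_cohort(design, sig)
        model, coords = h.fit_pca(expr, n_components=3)
        tum = coords[(clinical.table["tissue"] == "tumour").to_numpy()]
        nor = coords[(clinical.table["tissue"] == "normal").to_numpy()]
        tumour_dir = tum.mean() - nor.mean()

        # synthetic cell lines on the cohort scale: baseline vs baseline
        # shifted along the hypoxia signature
        rng = np.random.default_rng(99)
        base_log2 = truth["baseline_log2"].to_numpy()
        shift = np.zeros(len(base_log2))
        shift[: len(sig)] = sig.weights.to_numpy()
        cells = {}
        for r in range(3):
            noise = rng.normal(0, 0.3, len(base_log2))
            cells[f"untr_{r}"] = 2 ** (base_log2 + noise)
            noise = rng.normal(0, 0.3, len(base_log2))
            cells[f"hyp_{r}"] = 2 ** (base_log2 + shift + noise)
        cell_em = h.ExpressionMatrix(values=pd.DataFrame(
            cells, index=truth.index))
        cc = h.project_samples(model, cell_em)
        hyp_dir = cc.iloc[3:].mean() - cc.iloc[:3].mean()
        assert float(np.dot(tumour_dir, hyp_dir)) > 0
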