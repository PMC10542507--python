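"""NB-GLM machinery: TMM, dispersion, LRT calibration, BH FDR.

Independent oracles: a loop-based trimmed-mean TMM, edgeR via Rscript on a
small fixture, statsmodels Poisson GLM for the zero-dispersion limit, and a
brute-force BH step-up.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from oefit import count_stats as cs


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------


def bh_oracle(p):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * n / j for j in range(rank_i, n + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            cs.bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_p_is_identity(self):
        assert cs.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(cs.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.bh_fdr([0.5, 1.5])

    def test_nan_passthrough(self):
        out = cs.bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(cs.bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.random(50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(cs.bh_fdr(p)[perm], cs.bh_fdr(p[perm]))


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def tmm_pair_oracle(y, yr, m_trim=0.3, a_trim=0.05):
    """Loop-based trimmed weighted mean of M values for one sample vs ref."""
    n, nr = y.sum(), yr.sum()
    rows = []
    for yi, yri in zip(y, yr):
        if yi > 0 and yri > 0:
            M = np.log2((yi / n) / (yri / nr))
            A = 0.5 * np.log2((yi / n) * (yri / nr))
            w = 1.0 / ((n - yi) / (n * yi) + (nr - yri) / (nr * yri))
            rows.append((M, A, w))
    M = np.array([r[0] for r in rows])
    A = np.array([r[1] for r in rows])
    w = np.array([r[2] for r in rows])
    G = len(M)
    rM, rA = rankdata(M), rankdata(A)
    loM = np.floor(G * m_trim) + 1
    loA = np.floor(G * a_trim) + 1
    keep = (
        (rM >= loM) & (rM <= G + 1 - loM) & (rA >= loA) & (rA <= G + 1 - loA)
    )
    return float(np.sum(w[keep] * M[keep]) / np.sum(w[keep]))


class TestTMM:
    def test_identical_libraries(self, rng):
        y = rng.integers(1, 500, 100)
        df = pd.DataFrame({"a": y, "b": y})
        np.testing.assert_allclose(cs.tmm_factors(df), 1.0)

    def test_pure_depth_difference(self, rng):
        y = rng.integers(1, 500, 100)
        df = pd.DataFrame({"a": y, "b": y * 2})
        np.testing.assert_allclose(cs.tmm_factors(df), 1.0, atol=1e-12)

    def test_composition_matches_brute_force(self, rng):
        base = rng.integers(50, 500, 200)
        pert = base.copy()
        up = rng.choice(200, 20, replace=False)
        pert[up] = pert[up] * 8
        df = pd.DataFrame({"a": base, "b": pert})
        factors = cs.tmm_factors(df, ref_sample="a")
        f_oracle = tmm_pair_oracle(pert.astype(float), base.astype(float))
        # factors are normalized to geometric mean 1
        expected = 2.0 ** np.array([-f_oracle / 2, f_oracle / 2])
        np.testing.assert_allclose(factors.to_numpy(), expected, atol=1e-10)
        assert factors["b"] < 1.0  # composition bias compensated downward

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_edger_reference(self, tmp_path, rng):
        base = rng.gamma(2, 100, size=300)
        A = rng.poisson(base)
        B = rng.poisson(base * 2)
        C = rng.poisson(base)
        up = rng.choice(300, 30, replace=False)
        C[up] = rng.poisson(base[up] * 8)
        df = pd.DataFrame({"A": A + 1, "B": B + 1, "C": C + 1})
        fixture = tmp_path / "counts.tsv"
        df.to_csv(fixture, sep="\t", index=False)
        script = (
            "suppressMessages(library(edgeR));"
            f"x <- as.matrix(read.delim('{fixture}'));"
            "d <- calcNormFactors(DGEList(counts=x), method='TMM');"
            "cat(sprintf('%.10f', d$samples$norm.factors), sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(cs.tmm_factors(df).to_numpy(), ref, atol=1e-6)

    def test_no_shared_nonzero_genes_error(self):
        df = pd.DataFrame({"a": [5, 0, 3], "b": [0, 7, 0]})
        with pytest.raises(ValueError, match="no nonzero"):
            cs.tmm_factors(df, ref_sample="a")


# ---------------------------------------------------------------------------
# NB GLM
# ---------------------------------------------------------------------------


def two_group_design(n_per=3):
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(2 * n_per)],
         "group": ["a"] * n_per + ["b"] * n_per}
    )
    return samples


class TestNBGLM:
    def test_zero_dispersion_matches_statsmodels_poisson(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        samples = two_group_design()
        design = cs.build_design(samples, ["group"])
        Y = rng.poisson([200, 210, 190, 400, 380, 420], size=(20, 6))
        fit = cs.fit_nb_glm(pd.DataFrame(Y), design, dispersions=0.0)
        for g in range(5):
            ref = sm.GLM(Y[g], design.matrix, family=sm.families.Poisson()).fit()
            np.testing.assert_allclose(
                fit.coefficients[g] * np.log(2), ref.params, atol=1e-6
            )

    def test_two_group_fitted_means_are_group_means(self, rng):
        samples = two_group_design()
        design = cs.build_design(samples, ["group"])
        Y = rng.poisson(300, size=(10, 6))
        fit = cs.fit_nb_glm(pd.DataFrame(Y), design, dispersions=0.3)
        np.testing.assert_allclose(
            fit.fitted[:, :3].mean(axis=1), Y[:, :3].mean(axis=1), rtol=1e-5
        )
        np.testing.assert_allclose(
            fit.fitted[:, 3:].mean(axis=1), Y[:, 3:].mean(axis=1), rtol=1e-5
        )

    def test_intercept_only_closed_form(self, rng):
        samples = pd.DataFrame({"sample_id": list("abcd")})
        design = cs.build_design(samples, [])
        Y = rng.poisson(100, size=(8, 4))
        off = np.log(np.array([1.0, 2.0, 1.0, 2.0]))
        fit = cs.fit_nb_glm(pd.DataFrame(Y), design, offsets=off, dispersions=0.0)
        # Poisson intercept-only with offsets: mu_hat = sum(y) / sum(exp(off))
        expect = np.log2(Y.sum(axis=1) / np.exp(off).sum())
        np.testing.assert_allclose(fit.coefficients[:, 0], expect, atol=1e-6)

    def test_offsets_must_be_finite(self, rng):
        samples = two_group_design()
        design = cs.build_design(samples, ["group"])
        with pytest.raises(ValueError):
            cs.fit_nb_glm(
                pd.DataFrame(rng.poisson(10, size=(3, 6))), design,
                offsets=np.array([0, 0, 0, 0, 0, np.inf]),
            )


class TestDispersion:
    def test_poisson_data_near_zero(self, rng):
        samples = two_group_design()
        design = cs.build_design(samples, ["group"])
        Y = rng.poisson(500, size=(2000, 6))
        est = cs.estimate_dispersion(pd.DataFrame(Y), design, offsets=np.zeros(6))
        assert est.common <= 0.01

    def test_nb_dispersion_recovered(self, rng):
        samples = two_group_design()
        design = cs.build_design(samples, ["group"])
        lam = rng.gamma(1 / 0.4, 500 * 0.4, size=(2000, 6))
        Y = rng.poisson(lam)
        est = cs.estimate_dispersion(pd.DataFrame(Y), design, offsets=np.zeros(6))
        assert 0.3 <= est.common <= 0.5

    def test_large_prior_df_collapses_to_common(self, rng):
        samples = two_group_design()
        design = cs.build_design(samples, ["group"])
        lam = rng.gamma(1 / 0.2, 300 * 0.2, size=(100, 6))
        Y = rng.poisson(lam)
        est = cs.estimate_dispersion(
            pd.DataFrame(Y), design, offsets=np.zeros(6), prior_df=1e6
        )
        ok = np.isfinite(est.per_gene)
        np.testing.assert_allclose(est.per_gene[ok], est.common, rtol=0.05)

    def test_shrunken_between_raw_and_common(self, rng):
        samples = two_group_design()
        design = cs.build_design(samples, ["group"])
        lam = rng.gamma(1 / 0.2, 300 * 0.2, size=(200, 6))
        Y = rng.poisson(lam)
        est = cs.estimate_dispersion(pd.DataFrame(Y), design, offsets=np.zeros(6))
        ok = np.isfinite(est.per_gene)
        lo = np.minimum(est.raw_per_gene[ok], est.common)
        hi = np.maximum(est.raw_per_gene[ok], est.common)
        assert ((est.per_gene[ok] >= lo - 1e-12)
                & (est.per_gene[ok] <= hi + 1e-12)).all()

    def test_all_zero_gene_excluded(self, rng):
        samples = two_group_design()
        design = cs.build_design(samples, ["group"])
        Y = rng.poisson(100, size=(50, 6))
        Y[0] = 0
        est = cs.estimate_dispersion(pd.DataFrame(Y), design, offsets=np.zeros(6))
        assert np.isnan(est.per_gene[0])


class TestLRT:
    @staticmethod
    def _fits(Y, effect=False):
        samples = two_group_design()
        full = cs.build_design(samples, ["group"])
        red = cs.build_design(samples, [])
        disp = cs.estimate_dispersion(pd.DataFrame(Y), full, offsets=np.zeros(6))
        ff = cs.fit_nb_glm(pd.DataFrame(Y), full, dispersions=disp.for_testing())
        fr = cs.fit_nb_glm(pd.DataFrame(Y), red, dispersions=disp.for_testing())
        return ff, fr

    def test_identical_designs_degenerate(self, rng):
        samples = two_group_design()
        d = cs.build_design(samples, ["group"])
        Y = pd.DataFrame(rng.poisson(100, size=(5, 6)))
        f1 = cs.fit_nb_glm(Y, d, dispersions=0.1)
        f2 = cs.fit_nb_glm(Y, d, dispersions=0.1)
        res = cs.lrt(f1, f2)
        np.testing.assert_allclose(res.table["stat"], 0.0, atol=1e-9)
        np.testing.assert_allclose(res.table["pvalue"], 1.0)

    def test_non_nested_rejected(self, rng):
        samples = two_group_design()
        samples["other"] = ["x", "y", "x", "y", "x", "y"]
        d1 = cs.build_design(samples, ["group"])
        d2 = cs.build_design(samples, ["other"])
        Y = pd.DataFrame(rng.poisson(100, size=(3, 6)))
        with pytest.raises(ValueError, match="nested"):
            cs.lrt(cs.fit_nb_glm(Y, d1), cs.fit_nb_glm(Y, d2))

    def test_null_type_one_error_calibrated(self, rng):
        lam = rng.gamma(1 / 0.2, 500 * 0.2, size=(2000, 6))
        Y = rng.poisson(lam)
        ff, fr = self._fits(Y)
        res = cs.lrt(ff, fr)
        frac = float((res.table["pvalue"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07
        n_fdr = float((res.table["fdr"] < 0.05).mean())
        assert n_fdr <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_strong_effects_detected(self, rng):
        # deep, low-dispersion data: every spiked gene decisively detected
        mu = np.tile([500.0] * 3 + [2000.0] * 3, (50, 1))  # lfc = 2
        Y = rng.poisson(rng.gamma(1 / 0.01, mu * 0.01))
        ff, fr = self._fits(Y)
        res = cs.lrt(ff, fr)
        assert (res.table["pvalue"] < 1e-6).all()


class TestCoefficientRecovery:
    def test_lfc_grid_recovered(self, rng):
        # spec-grade recovery: lfc in {-2,-1,0,1,2} at mean 500, 3 vs 3
        lfcs = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        reps = 40
        mu_a = np.full((len(lfcs) * reps, 3), 500.0)
        mu_b = (500.0 * 2.0 ** np.repeat(lfcs, reps))[:, None] * np.ones(3)
        Y = rng.poisson(np.hstack([mu_a, mu_b]))
        samples = two_group_design()
        design = cs.build_design(samples, ["group"])
        fit = cs.fit_nb_glm(pd.DataFrame(Y), design, dispersions=0.0)
        est = fit.coefficients[:, 1].reshape(len(lfcs), reps).mean(axis=1)
        assert np.abs(est - lfcs).max() < 0.05
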