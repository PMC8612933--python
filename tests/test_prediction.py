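import numpy as np
import pandas as pd
import pytest

from cicerscan.prediction import (
    CVScheme,
    accuracy_summary,
    build_kernels,
    compute_grm,
    cross_validate,
    fit_multikernel,
    fit_rrblup,
    fitted_blups,
    gblup_predictions,
    make_cv_partitions,
    predict_multikernel,
)
from cicerscan.simulate import PopulationSpec, SimConfig, TraitSpec, simulate_genotypes, simulate_phenotypes
from conftest import make_gm


class TestGrm:
    def test_duplicated_samples(self, rng):
        d = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        d = np.vstack([d, d[0]])  # sample 4 duplicates sample 0
        g = compute_grm(make_gm(d))
        assert g.matrix[0, 0] == pytest.approx(g.matrix[4, 4], abs=1e-12)
        assert g.matrix[0, 4] == pytest.approx(g.matrix[0, 0], abs=1e-12)

    def test_rows_sum_to_zero(self, rng):
        d = rng.integers(0, 3, size=(8, 50)).astype(np.int8)
        g = compute_grm(make_gm(d))
        np.testing.assert_allclose(g.matrix.sum(axis=1), 0.0, atol=1e-9)

    def test_hand_computed_fixture(self):
        d = np.array(
            [
                [0, 1, 2, 0, 1, 2],
                [1, 1, 0, 2, 0, 1],
                [2, 0, 1, 1, 2, 0],
                [0, 2, 1, 1, 1, 1],
            ],
            dtype=np.int8,
        )
        X = d.astype(float)
        p = X.mean(axis=0) / 2
        Z = X - 2 * p
        expected = Z @ Z.T / (2 * np.sum(p * (1 - p)))
        g = compute_grm(make_gm(d))
        np.testing.assert_allclose(g.matrix, expected, atol=1e-12)

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(make_gm(np.zeros((3, 5), dtype=np.int8)))

    def test_mean_imputation_of_missing(self, rng):
        d = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        g1 = compute_grm(make_gm(d))
        d2 = d.copy()
        d2[0, 0] = -1
        g2 = compute_grm(make_gm(d2))
        assert np.abs(g1.matrix - g2.matrix).max() < 0.5  # still finite/close

    def test_kinship_accessor(self, rng):
        d = rng.integers(0, 3, size=(5, 30)).astype(np.int8)
        g = compute_grm(make_gm(d))
        assert g.kinship(1, 2) == pytest.approx(g.matrix[1, 2] / 2)
        with pytest.raises(IndexError):
            g.kinship(0, 99)


def _sim_gp(seed=1, n=500, m=2000, h2=0.5):
    cfg = SimConfig(
        seed=seed,
        populations=[PopulationSpec("p", n, 0.2)],
        chrom_lengths={"Ca1": max(m * 10, 100_000)},
        n_variants_per_chrom=m,
        traits=[TraitSpec("t", n_qtl=min(200, m // 4), h2=h2)],
    )
    g, truth = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(g, truth, cfg)
    merged = pheno.merge(truth.tbv, on=["accession", "trait", "environment"])
    return g, merged["value"].to_numpy(), merged["tbv"].to_numpy()


class TestRrblup:
    def test_infinite_lambda_all_zero(self, rng):
        d = rng.integers(0, 3, size=(20, 30)).astype(np.int8)
        y = rng.normal(size=20)
        eff = fit_rrblup(y, make_gm(d), lambda_=np.inf)
        np.testing.assert_array_equal(eff.beta, 0.0)
        np.testing.assert_allclose(eff.gebv(make_gm(d)), 0.0)

    def test_lambda_zero_single_marker_ols(self, rng):
        x = rng.integers(0, 3, 30).astype(np.int8).reshape(-1, 1)
        y = 0.7 * x[:, 0] + rng.normal(0, 0.1, 30)
        eff = fit_rrblup(y, make_gm(x), lambda_=0.0)
        xc = x[:, 0] - x[:, 0].mean()
        yc = y - y.mean()
        ols = float(xc @ yc / (xc @ xc))
        assert eff.beta[0] == pytest.approx(ols, abs=1e-8)

    def test_gebv_accuracy_simulation(self):
        cors = []
        for seed in (1, 2, 3):
            g, y, tbv = _sim_gp(seed=seed, n=500, m=2000)
            eff = fit_rrblup(y, g)
            gebv = eff.gebv(g)
            cors.append(np.corrcoef(gebv, tbv)[0, 1])
        assert min(cors) >= 0.6

    def test_rrblup_equals_gblup(self, rng):
        for seed in (11, 12):
            g, y, _ = _sim_gp(seed=seed, n=60, m=300)
            eff = fit_rrblup(y, g)
            marker_side = eff.gebv(g)
            relationship_side = gblup_predictions(y, g, eff)
            np.testing.assert_allclose(marker_side, relationship_side, atol=1e-8)

    def test_zero_variance_errors(self, rng):
        d = rng.integers(0, 3, size=(15, 10)).astype(np.int8)
        with pytest.raises(ValueError, match="variance"):
            fit_rrblup(np.ones(15), make_gm(d))

    def test_missing_phenotypes_dropped(self, rng):
        g, y, _ = _sim_gp(seed=31, n=50, m=100)
        y2 = y.copy()
        y2[:5] = np.nan
        eff = fit_rrblup(y2, g)
        assert np.isfinite(eff.beta).all()


def _records_from_sim(seed=5, n=80, m=300, n_env=3, rho=0.6, h2=0.5, env_sd=2.0):
    # two drifted populations give the GRM block structure that makes the
    # G / GE / residual split identifiable
    cfg = SimConfig(
        seed=seed,
        populations=[PopulationSpec("pa", n // 2, 0.35), PopulationSpec("pb", n - n // 2, 0.35)],
        chrom_lengths={"Ca1": m * 20},
        n_variants_per_chrom=m,
        traits=[TraitSpec("t", n_qtl=60, h2=h2)],
        environments=[f"E{i}" for i in range(n_env)],
        rho_ge=rho,
        env_effect_sd=env_sd,
    )
    g, truth = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(g, truth, cfg)
    records = pheno.rename(columns={"accession": "line"})[["line", "environment", "value"]]
    return g, records.reset_index(drop=True), truth


class TestMultikernel:
    def test_loglik_monotone(self):
        g, records, _ = _records_from_sim(seed=7, n=50, m=200, n_env=3)
        grm = compute_grm(g)
        kernels = build_kernels(records, grm, "E+L+G+GE")
        fit = fit_multikernel(records["value"].to_numpy(), kernels, max_iter=60)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-6 * np.abs(fit.loglik_trace[:-1])).all()

    def test_ge_variance_small_when_rho_one(self):
        g, records, _ = _records_from_sim(seed=9, n=60, m=250, n_env=3, rho=1.0)
        grm = compute_grm(g)
        kernels = build_kernels(records, grm, "E+L+G+GE")
        fit = fit_multikernel(records["value"].to_numpy(), kernels, max_iter=200)
        assert fit.varcomps["GE"] / max(fit.varcomps["G"], 1e-9) < 0.1

    def test_el_recovers_env_shifts(self, rng):
        lines = [f"l{i}" for i in range(40)]
        shifts = {"E0": -3.0, "E1": 0.0, "E2": 4.0}
        rows = []
        for l in lines:
            u = rng.normal()
            for e, s in shifts.items():
                rows.append((l, e, s + u + rng.normal(0, 0.3)))
        records = pd.DataFrame(rows, columns=["line", "environment", "value"])
        d = rng.integers(0, 3, size=(40, 50)).astype(np.int8)
        grm = compute_grm(make_gm(d, sample_ids=lines))
        kernels = build_kernels(records, grm, "E+L")
        y = records["value"].to_numpy()
        fit = fit_multikernel(y, kernels, max_iter=200)
        blups = fitted_blups(y, kernels, fit)
        env_blup = pd.DataFrame({"environment": records["environment"], "u": blups["E"]})
        est = env_blup.groupby("environment")["u"].mean()
        truth = pd.Series(shifts)
        assert np.corrcoef(est[truth.index], truth)[0, 1] >= 0.95

    def test_non_psd_kernel_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="positive semi-definite"):
            fit_multikernel(np.array([0.1, 0.2]), {"X": bad})

    def test_variance_component_recovery(self, rng):
        # simulate directly from the E+L+G+GE model and recover each
        # component within 25% relative error
        n_lines, n_env = 300, 4
        cfg = SimConfig(
            seed=17,
            populations=[PopulationSpec("pa", 150, 0.35), PopulationSpec("pb", 150, 0.35)],
            chrom_lengths={"Ca1": 20_000},
            n_variants_per_chrom=600,
        )
        g, _ = simulate_genotypes(cfg)
        grm = compute_grm(g)
        lines = list(g.samples["id"])
        records = pd.DataFrame(
            [(l, f"E{e}") for e in range(n_env) for l in lines],
            columns=["line", "environment"],
        ).assign(value=0.0)
        kernels = build_kernels(records, grm, "E+L+G+GE")
        true_vc = {"E": 2.0, "L": 1.0, "G": 3.0, "GE": 1.5}
        ve = 1.0
        n = len(records)
        y = np.zeros(n)
        local = np.random.default_rng(99)
        for name, sigma2 in true_vc.items():
            k = kernels[name]
            evals, evecs = np.linalg.eigh((k + k.T) / 2)
            evals = np.clip(evals, 0, None)
            y += evecs @ (np.sqrt(sigma2 * evals) * local.normal(size=n))
        y += local.normal(0, np.sqrt(ve), n)
        fit = fit_multikernel(y, kernels, max_iter=300, tol=1e-6)
        for name, sigma2 in true_vc.items():
            assert fit.varcomps[name] == pytest.approx(sigma2, rel=0.25), name
        assert fit.varcomps["residual"] == pytest.approx(ve, rel=0.25)


class TestCrossValidation:
    def test_perfect_predictions_r_one(self):
        obs = np.arange(10, dtype=float)
        from scipy.stats import pearsonr

        assert pearsonr(obs, obs).statistic == pytest.approx(1.0)

    def test_cv1_partition_audit(self):
        _, records, _ = _records_from_sim(seed=19, n=40, m=100, n_env=3)
        for part in make_cv_partitions(records, CVScheme("CV1", folds=5, seed=3)):
            test_lines = set(records.loc[part["test"], "line"])
            train_lines = set(records.loc[part["train"], "line"])
            assert not (test_lines & train_lines)

    def test_cv2_lines_seen_elsewhere(self):
        _, records, _ = _records_from_sim(seed=21, n=40, m=100, n_env=4)
        parts = make_cv_partitions(records, CVScheme("CV2", folds=5, seed=3))
        overlap = 0
        for part in parts:
            test_lines = set(records.loc[part["test"], "line"])
            train_lines = set(records.loc[part["train"], "line"])
            overlap += len(test_lines & train_lines)
        assert overlap > 0

    def test_cv0_each_env_once(self):
        _, records, _ = _records_from_sim(seed=23, n=30, m=80, n_env=4)
        parts = make_cv_partitions(records, CVScheme("CV0", repeats=2))
        envs = records["environment"].unique()
        for rep in (0, 1):
            held = [p["fold"] for p in parts if p["repeat"] == rep]
            assert sorted(held) == sorted(envs)
            for p in parts:
                assert set(records.loc[p["test"], "environment"]) == {p["fold"]}

    def test_partitions_cover_all_records(self):
        _, records, _ = _records_from_sim(seed=25, n=25, m=150, n_env=3)
        for scheme in ("CV0", "CV1", "CV2"):
            parts = make_cv_partitions(records, CVScheme(scheme, folds=5, seed=1))
            reps = {p["repeat"] for p in parts}
            for rep in reps:
                test_union = np.concatenate([p["test"] for p in parts if p["repeat"] == rep])
                assert sorted(test_union.tolist()) == list(range(len(records)))

    def test_elg_beats_el_cv1(self):
        # compare on pooled fold accuracy: E+L predictions are constant
        # within an environment, so per-environment r is undefined for it
        g, records, _ = _records_from_sim(seed=27, n=70, m=300, n_env=3, h2=0.7)
        grm = compute_grm(g)
        scheme = CVScheme("CV1", folds=5, repeats=2, seed=5)
        cv_el = cross_validate(records, grm, "E+L", scheme, max_iter=100)
        cv_elg = cross_validate(records, grm, "E+L+G", scheme, max_iter=100)
        acc_el = cv_el[cv_el["environment"] == "POOLED"]["accuracy"].mean()
        acc_elg = cv_elg[cv_elg["environment"] == "POOLED"]["accuracy"].mean()
        assert acc_elg > acc_el

    def test_cv2_at_least_cv1_on_average(self):
        g, records, _ = _records_from_sim(seed=29, n=60, m=250, n_env=3, h2=0.6)
        grm = compute_grm(g)
        acc1 = cross_validate(records, grm, "E+L+G", CVScheme("CV1", repeats=4, seed=2), max_iter=80)
        acc2 = cross_validate(records, grm, "E+L+G", CVScheme("CV2", repeats=4, seed=2), max_iter=80)
        m1 = acc1[acc1["environment"] != "POOLED"]["accuracy"].mean()
        m2 = acc2[acc2["environment"] != "POOLED"]["accuracy"].mean()
        assert m2 >= m1 - 0.02

    def test_accuracy_summary_shape(self):
        g, records, _ = _records_from_sim(seed=31, n=30, m=80, n_env=3)
        grm = compute_grm(g)
        cv = cross_validate(records, grm, "E+L+G", CVScheme("CV0"), max_iter=50)
        summary = accuracy_summary(cv)
        assert "ALL" in set(summary["environment"])
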