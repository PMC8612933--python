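"""Genomic prediction: VanRaden GRM, RR-BLUP marker effects with REML
shrinkage, multi-kernel environment/line/marker/GxE mixed models fitted by
EM-REML, and CV0/CV1/CV2 cross-validation accuracy.

Estimation notes: the single-component (RR-BLUP/GBLUP) model profiles the
restricted likelihood over the variance ratio on the spectral decomposition
of ZZ' (exact, deterministic). The multi-kernel model uses EM-REML updates,
which increase the restricted likelihood monotonically; model structure
(E + L, E + L + G, E + L + G + GE) is expressed through record-level
covariance kernels, with the GxE kernel the Hadamard product of the genomic
and environment kernels (PSD-preserving).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from cicerscan.core_io import MISSING, GenotypeMatrix

logger = logging.getLogger("cicerscan.prediction")

MODEL_TAGS = ("E+L", "E+L+G", "E+L+G+GE")


@dataclass
class GRM:
    """VanRaden method-1 genomic relationship matrix."""

    matrix: np.ndarray
    freqs: np.ndarray
    scale: float  # 2 * sum p_j (1 - p_j)
    ids: list[str]

    def kinship(self, i: int, j: int) -> float:
        """Co-ancestry f_ij = G_ij / 2 (= progeny inbreeding of mating i x j)."""
        n = self.matrix.shape[0]
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError("sample index out of range")
        return float(self.matrix[i, j] / 2.0)


def _imputed_dosages(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    d = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g)
    X = d.astype(float)
    miss = X == MISSING
    if miss.any():
        X[miss] = np.nan
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        inds = np.where(miss)
        X[inds] = col_mean[inds[1]]
    return X


def compute_grm(g: GenotypeMatrix | np.ndarray, ids: list[str] | None = None) -> GRM:
    """VanRaden method 1: Z = X - 2p, G = ZZ' / (2 sum p(1-p)).

    Missing dosages are mean-imputed; allele frequencies are sample
    frequencies of the (imputed) panel.
    """
    X = _imputed_dosages(g)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    p = X.mean(axis=0) / 2.0
    scale = float(2.0 * np.sum(p * (1.0 - p)))
    if scale == 0.0:
        raise ValueError("all markers monomorphic: GRM scaling constant is zero")
    Z = X - 2.0 * p
    G = Z @ Z.T / scale
    if ids is None:
        ids = (
            list(g.samples["id"]) if isinstance(g, GenotypeMatrix) else [str(i) for i in range(X.shape[0])]
        )
    return GRM(matrix=G, freqs=p, scale=scale, ids=ids)


# ---------------------------------------------------------------------------
# RR-BLUP


@dataclass
class MarkerEffects:
    mu: float
    beta: np.ndarray
    lambda_: float  # sigma_e^2 / sigma_beta^2
    sigma_g2: float
    sigma_e2: float
    freqs: np.ndarray
    trait: str = ""

    def gebv(self, g: GenotypeMatrix | np.ndarray, centered: bool = True) -> np.ndarray:
        """Sum of marker effects; ``centered`` uses the training 2p offsets."""
        X = _imputed_dosages(g)
        Z = X - 2.0 * self.freqs if centered else X
        return Z @ self.beta


def fit_rrblup(
    y: np.ndarray,
    X: np.ndarray | GenotypeMatrix,
    lambda_: float | None = None,
    trait: str = "",
) -> MarkerEffects:
    """Ridge-regression BLUP of marker effects.

    Variance components come from exact REML on the equivalent GBLUP model
    (spectral decomposition of ZZ'); then beta = Z'(ZZ' + lambda I)^-1 (y -
    mu). Passing ``lambda_`` skips REML (0 = no shrinkage, inf = total
    shrinkage).
    """
    y = np.asarray(y, dtype=float)
    Xd = _imputed_dosages(X)
    ok = np.isfinite(y)
    y, Xd = y[ok], Xd[ok]
    n = y.size
    if n < 10 and lambda_ is None:
        raise ValueError("need at least 10 records for REML")
    if np.var(y) == 0:
        raise ValueError("zero phenotypic variance")
    p = Xd.mean(axis=0) / 2.0
    Z = Xd - 2.0 * p

    if lambda_ is not None and np.isinf(lambda_):
        return MarkerEffects(float(y.mean()), np.zeros(Z.shape[1]), np.inf, 0.0, float(np.var(y, ddof=1)), p, trait)
    if lambda_ == 0.0:
        H = Z @ Z.T
        mu = float(y.mean())
        beta = Z.T @ np.linalg.pinv(H) @ (y - mu)
        return MarkerEffects(mu, beta, 0.0, float(np.var(y, ddof=1)), 0.0, p, trait)

    H = Z @ Z.T
    evals, U = np.linalg.eigh(H)
    evals = np.maximum(evals, 0.0)
    ys = U.T @ y
    xs = U.T @ np.ones(n)

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = evals + delta
        sxx = np.sum(xs**2 / w)
        mu = np.sum(xs * ys / w) / sxx
        r = ys - xs * mu
        sigma_g2 = np.sum(r**2 / w) / (n - 1)
        ll = -0.5 * (
            (n - 1) * np.log(sigma_g2)
            + np.sum(np.log(w))
            + np.log(sxx)
            + (n - 1)
        )
        return -ll

    if lambda_ is None:
        res = minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded")
        delta = float(np.exp(res.x))
    else:
        delta = float(lambda_)
    w = evals + delta
    sxx = np.sum(xs**2 / w)
    mu = float(np.sum(xs * ys / w) / sxx)
    r = ys - xs * mu
    sigma_g2 = float(np.sum(r**2 / w) / (n - 1))
    sigma_e2 = sigma_g2 * delta
    beta = Z.T @ (U @ (r / w))
    return MarkerEffects(mu, beta, delta, sigma_g2, sigma_e2, p, trait)


def gblup_predictions(y: np.ndarray, X: np.ndarray | GenotypeMatrix, effects: MarkerEffects) -> np.ndarray:
    """Relationship-side BLUP g_hat = H (H + lambda I)^-1 (y - mu); used to
    verify RR-BLUP/GBLUP equivalence through an independent matrix route."""
    Xd = _imputed_dosages(X)
    Z = Xd - 2.0 * effects.freqs
    H = Z @ Z.T
    n = H.shape[0]
    return H @ np.linalg.solve(H + effects.lambda_ * np.eye(n), np.asarray(y, float) - effects.mu)


# ---------------------------------------------------------------------------
# Multi-kernel E + L (+ G) (+ GE) model


def build_kernels(
    records: pd.DataFrame,
    grm: GRM,
    model: str = "E+L+G+GE",
) -> dict[str, np.ndarray]:
    """Record-level covariance kernels for the requested model tag.

    ``records`` needs columns line, environment. K_E and K_L are block
    identity-by-factor kernels, K_G expands the GRM to records, and
    K_GE = K_G o K_E elementwise.
    """
    if model not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model!r}")
    env = records["environment"].to_numpy()
    line = records["line"].to_numpy()
    ke = (env[:, None] == env[None, :]).astype(float)
    kl = (line[:, None] == line[None, :]).astype(float)
    kernels = {"E": ke, "L": kl}
    if "G" in model:
        pos = {s: i for i, s in enumerate(grm.ids)}
        missing = set(line) - set(pos)
        if missing:
            raise ValueError(f"lines without GRM entry: {sorted(missing)[:5]}")
        li = np.array([pos[s] for s in line])
        kg = grm.matrix[np.ix_(li, li)]
        kernels["G"] = kg
        if model.endswith("GE"):
            kernels["GE"] = kg * ke
    return kernels


def _check_psd(k: np.ndarray, name: str, tol: float = -1e-8) -> None:
    ev = np.linalg.eigvalsh((k + k.T) / 2.0)
    if ev.min() < tol * max(1.0, abs(ev.max())):
        raise ValueError(f"kernel {name} is not positive semi-definite (min eig {ev.min():.3g})")


@dataclass
class KernelFit:
    mu: float
    varcomps: dict[str, float]
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int


def _reml_loglik(y, V, X):
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    sign, logdet_v = np.linalg.slogdet(V)
    _, logdet_x = np.linalg.slogdet(XtVX)
    return -0.5 * (logdet_v + logdet_x + r @ Vinv @ r), Vinv, float(beta[0])


def fit_multikernel(
    y: np.ndarray,
    kernels: dict[str, np.ndarray],
    max_iter: int = 500,
    tol: float = 1e-6,
    check_psd: bool = True,
) -> KernelFit:
    """EM-REML for y = mu + sum_k u_k + e with u_k ~ N(0, sigma_k^2 K_k).

    The restricted log-likelihood is tracked each iteration (monotone
    non-decreasing by the EM property); non-convergence in ``max_iter``
    iterations warns and returns the last iterate.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if check_psd:
        for name, k in kernels.items():
            _check_psd(k, name)
    X = np.ones((n, 1))
    vc = {name: float(np.var(y)) / (len(kernels) + 1) for name in kernels}
    ve = float(np.var(y)) / (len(kernels) + 1)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = ve * np.eye(n)
        for name, k in kernels.items():
            V = V + vc[name] * k
        ll, Vinv, mu = _reml_loglik(y, V, X)
        trace.append(ll)
        P = Vinv - (Vinv @ X) @ np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv)
        Py = P @ y
        new_vc = {}
        for name, k in kernels.items():
            # tr(PK) = sum(P o K) for symmetric P, K
            grad = Py @ (k @ Py) - np.sum(P * k)
            new_vc[name] = max(vc[name] + (vc[name] ** 2 / n) * grad, 1e-10)
        grad_e = Py @ Py - np.trace(P)
        new_ve = max(ve + (ve**2 / n) * grad_e, 1e-10)
        rel = max(
            max(abs(new_vc[k2] - vc[k2]) / max(vc[k2], 1e-10) for k2 in vc),
            abs(new_ve - ve) / max(ve, 1e-10),
        )
        vc, ve = new_vc, new_ve
        if rel < tol:
            converged = True
            break
    if not converged:
        logger.warning("fit_multikernel: EM-REML did not converge in %d iterations", max_iter)
    V = ve * np.eye(n)
    for name, k in kernels.items():
        V = V + vc[name] * k
    ll, Vinv, mu = _reml_loglik(y, V, X)
    trace.append(ll)
    varcomps = dict(vc)
    varcomps["residual"] = ve
    return KernelFit(mu=mu, varcomps=varcomps, loglik_trace=np.array(trace), converged=converged, n_iter=it)


def predict_multikernel(
    y_train: np.ndarray,
    kernels: dict[str, np.ndarray],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    fit: KernelFit,
) -> np.ndarray:
    """Conditional-mean prediction of held-out records from a fitted model."""
    tr, te = np.asarray(train_idx), np.asarray(test_idx)
    n_tr = tr.size
    V = fit.varcomps["residual"] * np.eye(n_tr)
    C = np.zeros((te.size, n_tr))
    for name, k in kernels.items():
        if name == "residual":
            continue
        V = V + fit.varcomps[name] * k[np.ix_(tr, tr)]
        C = C + fit.varcomps[name] * k[np.ix_(te, tr)]
    resid = np.asarray(y_train, float) - fit.mu
    return fit.mu + C @ np.linalg.solve(V, resid)


def fitted_blups(y: np.ndarray, kernels: dict[str, np.ndarray], fit: KernelFit) -> dict[str, np.ndarray]:
    """BLUPs of each random term at the training records."""
    n = y.size
    V = fit.varcomps["residual"] * np.eye(n)
    for name, k in kernels.items():
        V = V + fit.varcomps[name] * k
    resid = np.linalg.solve(V, np.asarray(y, float) - fit.mu)
    return {name: fit.varcomps[name] * (k @ resid) for name, k in kernels.items()}


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVScheme:
    scheme: str  # CV0 | CV1 | CV2
    folds: int = 5
    repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("CV0", "CV1", "CV2"):
            raise ValueError(f"unknown CV scheme {self.scheme!r}")


def make_cv_partitions(records: pd.DataFrame, scheme: CVScheme) -> list[dict]:
    """Seeded train/test partitions honouring each scheme's constraint.

    CV0 holds out one whole environment per fold; CV1 holds out all records
    of a line fold (test lines unseen in any environment); CV2 holds out a
    random record fold (test lines typically observed elsewhere).
    """
    rng = np.random.default_rng(scheme.seed)
    env = records["environment"].to_numpy()
    line = records["line"].to_numpy()
    n = len(records)
    parts = []
    for rep in range(scheme.repeats):
        if scheme.scheme == "CV0":
            for e in pd.unique(env):
                test = np.flatnonzero(env == e)
                train = np.flatnonzero(env != e)
                parts.append({"repeat": rep, "fold": str(e), "train": train, "test": test})
        elif scheme.scheme == "CV1":
            lines = pd.unique(line)
            perm = rng.permutation(len(lines))
            fold_of = {lines[perm[i]]: i % scheme.folds for i in range(len(lines))}
            assign = np.array([fold_of[l] for l in line])
            for f in range(scheme.folds):
                test = np.flatnonzero(assign == f)
                train = np.flatnonzero(assign != f)
                parts.append({"repeat": rep, "fold": f, "train": train, "test": test})
        else:  # CV2
            assign = rng.permutation(n) % scheme.folds
            for f in range(scheme.folds):
                test = np.flatnonzero(assign == f)
                train = np.flatnonzero(assign != f)
                parts.append({"repeat": rep, "fold": f, "train": train, "test": test})
    return parts


def cross_validate(
    records: pd.DataFrame,
    grm: GRM,
    model: str,
    scheme: CVScheme,
    max_iter: int = 200,
    min_test_records: int = 3,
) -> pd.DataFrame:
    """Per-environment Pearson-r accuracy under a CV scheme.

    Kernels are built once over all records; variance components are
    re-estimated on each training partition. Folds with fewer than
    ``min_test_records`` usable test records are skipped with a warning.
    """
    records = records.reset_index(drop=True)
    y = records["value"].to_numpy(dtype=float)
    kernels = build_kernels(records, grm, model)
    for name in kernels:
        _check_psd(kernels[name], name)
    env = records["environment"].to_numpy()
    rows = []
    for part in make_cv_partitions(records, scheme):
        tr, te = part["train"], part["test"]
        sub_kernels = {k: v[np.ix_(tr, tr)] for k, v in kernels.items()}
        fit = fit_multikernel(y[tr], sub_kernels, max_iter=max_iter, check_psd=False)
        pred = predict_multikernel(y[tr], kernels, tr, te, fit)
        # pooled accuracy over the whole test fold (defined even for models
        # whose predictions are constant within an environment)
        if te.size >= min_test_records and np.std(y[te]) > 1e-12 and np.std(pred) > 1e-12:
            with np.errstate(invalid="ignore"):
                r_pool = float(np.corrcoef(y[te], pred)[0, 1])
            if np.isfinite(r_pool):
                rows.append((scheme.scheme, model, part["repeat"], part["fold"],
                             "POOLED", r_pool, int(te.size)))
        for e in pd.unique(env[te]):
            m = env[te] == e
            if m.sum() < min_test_records:
                logger.warning("cross_validate: fold %s env %s has <%d records, skipped",
                               part["fold"], e, min_test_records)
                continue
            if np.std(y[te][m]) < 1e-12 or np.std(pred[m]) < 1e-12:
                continue
            with np.errstate(invalid="ignore"):
                r = float(np.corrcoef(y[te][m], pred[m])[0, 1])
            if not np.isfinite(r):
                continue
            rows.append((scheme.scheme, model, part["repeat"], part["fold"], e, r, int(m.sum())))
    return pd.DataFrame(
        rows, columns=["scheme", "model", "repeat", "fold", "environment", "accuracy", "n_test"]
    )


def accuracy_summary(cv_table: pd.DataFrame) -> pd.DataFrame:
    """Average accuracy per environment and overall (per-environment mean)."""
    per_env = (
        cv_table.groupby(["scheme", "model", "environment"], as_index=False)["accuracy"].mean()
    )
    overall = (
        per_env[per_env["environment"] != "POOLED"]
        .groupby(["scheme", "model"], as_index=False)["accuracy"].mean()
        .assign(environment="ALL")
    )
    return pd.concat([per_env, overall], ignore_index=True)
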