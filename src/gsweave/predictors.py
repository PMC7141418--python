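"""The fifteen GEBV prediction methods behind one fit/score contract.

Method tags
-----------
GBLUP    kinship mixed model, REML by spectral decomposition
EGBLUP   GBLUP + epistatic kernel (elementwise square of the scaled kinship)
RR/LASSO/EN   penalized regression (elastic-net family), lambda by inner 5-fold CV
BRR/BL/BA/BB/BC   Bayesian whole-genome regression, Gibbs sampling
RKHS/MRKHS    Gaussian-kernel (multi-)kernel Bayesian mixed model
RF/SVM/BRNN   random forest, support-vector and Bayesian-regularized
              neural-network regression

Every ``fit_*`` returns a :class:`FittedModel` scoreable on new genotypes
with :func:`predict_gebv`.  GEBV are reported as mu + genetic value;
prediction error variances (hence reliabilities) are exposed for the
methods with an explicit Gaussian model (GBLUP, EGBLUP, the Bayes
family, RKHS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import GenotypeMatrix, PhenotypeVector, PSD_JITTER, vanraden_design
from ._gibbs import PRIOR_CODES, marker_gibbs
from ._kernels import gaussian_kernel, kernel_gibbs, mean_offdiag, squared_distances
from ._brnn import BRNNRegressor

__all__ = [
    "METHODS",
    "FittedModel",
    "fit",
    "fit_gblup",
    "fit_egblup",
    "fit_penalized",
    "fit_bayes",
    "fit_rkhs",
    "fit_rf",
    "fit_svm",
    "fit_brnn",
    "predict_gebv",
]

METHODS = (
    "GBLUP", "EGBLUP", "RR", "LASSO", "EN",
    "BRR", "BL", "BA", "BB", "BC",
    "RKHS", "MRKHS", "RF", "SVM", "BRNN",
)

#: markers above which the RBF support-vector machine is known to struggle
SVM_MARKER_WARN = 20_000


@dataclass
class FittedModel:
    """A fitted genomic prediction model plus everything needed to score.

    Exactly one of the three representations is populated:

    * effect-based: ``beta`` (marker effects), with per-column ``centers``
      and ``scales`` applied to dosages before the dot product;
    * kernel-based: ``kernel_components``, each holding the training
      kernel, its BLUP/posterior-mean effect and a recipe for the
      training-vs-target cross kernel;
    * estimator-based: a fitted scikit-learn-style ``estimator``.
    """

    method: str
    line_ids: np.ndarray
    marker_ids: np.ndarray
    mu: float
    fitted_gebv: np.ndarray
    sigma2_g: float | None = None
    sigma2_e: float | None = None
    pev: np.ndarray | None = None
    beta: np.ndarray | None = None
    centers: np.ndarray | None = None
    scales: np.ndarray | None = None
    kernel_components: list | None = None
    estimator: object | None = None
    mcmc: dict | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose one of {METHODS}")
        if self.pev is not None and np.any(self.pev < 0):
            raise ValueError("negative prediction error variance")

    @property
    def reliability(self) -> np.ndarray | None:
        """REL = 1 - PEV/sigma2_g for training lines, clipped to [0, 1]."""
        if self.pev is None or not self.sigma2_g or self.sigma2_g <= 0:
            return None
        return np.clip(1.0 - self.pev / self.sigma2_g, 0.0, 1.0)


# ----------------------------------------------------------------------
# shared plumbing


def _design(geno: GenotypeMatrix, pheno: PhenotypeVector):
    if np.isnan(geno.dosage).any():
        raise ValueError("genotypes contain missing values; impute first")
    if geno.n_lines < 3:
        raise ValueError("need at least 3 training lines")
    y = pheno.aligned_to(geno.line_ids)
    return geno.dosage, y


def _check_variance(y):
    if np.var(y) == 0:
        raise ValueError("zero phenotypic variance")


def _standardize(X):
    centers = X.mean(axis=0)
    sd = X.std(axis=0)
    scales = np.where(sd > 0, sd, 1.0)
    return (X - centers) / scales, centers, scales


# ----------------------------------------------------------------------
# GBLUP (REML via spectral decomposition)


def _reml_gblup(G: np.ndarray, y: np.ndarray):
    """REML of y = 1*mu + g + e, g ~ (0, G*sg2): profile likelihood in the
    ratio delta = se2/sg2 maximized on the eigenbasis of G."""
    n = y.size
    d, U = np.linalg.eigh(G)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_restricted_ll(log_delta):
        delta = np.exp(log_delta)
        h = d + delta
        xhx = np.sum(xt**2 / h)
        mu = np.sum(xt * yt / h) / xhx
        r = yt - xt * mu
        ypy = np.sum(r**2 / h)
        return 0.5 * ((n - 1) * np.log(ypy) + np.sum(np.log(h)) + np.log(xhx))

    # coarse grid then local refinement (profile is usually unimodal)
    grid = np.linspace(np.log(1e-6), np.log(1e6), 61)
    vals = [neg_restricted_ll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(neg_restricted_ll, bounds=(lo, hi), method="bounded")
    delta = float(np.exp(res.x))

    h = d + delta
    xhx = np.sum(xt**2 / h)
    mu = float(np.sum(xt * yt / h) / xhx)
    r = yt - xt * mu
    sg2 = float(np.sum(r**2 / h) / (n - 1))
    se2 = delta * sg2
    ghat = U @ (d / h * r)
    return mu, ghat, sg2, se2, delta


def fit_gblup(geno: GenotypeMatrix, pheno: PhenotypeVector) -> FittedModel:
    """GBLUP: mixed model with the VanRaden relationship matrix.

    Variance components by REML (spectral decomposition); returns
    back-solved marker effects, so the model is also directly scoreable
    on new genotypes, and PEV from the inverse coefficient matrix of the
    mixed-model equations.
    """
    X, y = _design(geno, pheno)
    _check_variance(y)
    W, p, c = vanraden_design(X)
    if c <= 0:
        raise ValueError("all markers monomorphic")
    n = X.shape[0]
    G = W @ W.T / c + PSD_JITTER * np.eye(n)
    mu, ghat, sg2, se2, delta = _reml_gblup(G, y)

    # PEV from the inverse coefficient matrix of the MME
    Ginv = np.linalg.inv(G)
    C = np.empty((n + 1, n + 1))
    C[0, 0] = n
    C[0, 1:] = 1.0
    C[1:, 0] = 1.0
    C[1:, 1:] = np.eye(n) + delta * Ginv
    Cinv = np.linalg.inv(C)
    pev = np.maximum(se2 * np.diag(Cinv)[1:], 0.0)

    beta = W.T @ (Ginv @ ghat) / c
    return FittedModel(
        method="GBLUP", line_ids=geno.line_ids.copy(),
        marker_ids=geno.marker_ids.copy(),
        mu=mu, fitted_gebv=mu + ghat,
        sigma2_g=sg2, sigma2_e=se2, pev=pev,
        beta=beta, centers=2.0 * p, scales=np.ones_like(p),
        extra={"delta": delta},
    )


# ----------------------------------------------------------------------
# kernel-based fits (EGBLUP, RKHS, MRKHS)


def _scaled_vanraden(X):
    W, p, c = vanraden_design(X)
    A = W @ W.T / c
    d = np.sqrt(np.maximum(np.diag(A), 1e-12))
    return A / np.outer(d, d), W, p, c, d


def fit_egblup(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    n_iter: int = 5000,
    burn_in: int = 1000,
    thin: int = 5,
    seed: int = 0,
) -> FittedModel:
    """Epistatic GBLUP: additive kernel G plus its elementwise square
    (modelling pairwise interactions), both sampled as variance
    components of a Bayesian mixed model."""
    X, y = _design(geno, pheno)
    _check_variance(y)
    A, W, p, c, diag = _scaled_vanraden(X)
    H = A * A
    res = kernel_gibbs([A, H], y, n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)
    comps = [
        {"type": "vanraden_scaled", "u": res["u"][0], "K": A,
         "p": p, "c": c, "diag": diag, "train_dosage": X,
         "sigma2": res["sigma2_k"][0]},
        {"type": "vanraden_scaled_sq", "u": res["u"][1], "K": H,
         "p": p, "c": c, "diag": diag, "train_dosage": X,
         "sigma2": res["sigma2_k"][1]},
    ]
    return FittedModel(
        method="EGBLUP", line_ids=geno.line_ids.copy(),
        marker_ids=geno.marker_ids.copy(),
        mu=res["mu"], fitted_gebv=res["mu"] + res["g"],
        sigma2_g=res["sigma2_g"], sigma2_e=res["sigma2_e"], pev=res["pev"],
        kernel_components=comps,
        mcmc={"n_iter": n_iter, "burn_in": burn_in, "thin": thin,
              "seed": seed, "n_samples": res["n_samples"],
              "sigma2_k": res["sigma2_k"].tolist()},
    )


def fit_rkhs(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    bandwidths=(1.0,),
    n_iter: int = 5000,
    burn_in: int = 1000,
    thin: int = 5,
    seed: int = 0,
) -> FittedModel:
    """(Multi-)kernel RKHS regression with Gaussian kernels
    K_h = exp(-h * d^2 / mean(d^2)) on squared Euclidean genotype
    distances; one variance component per bandwidth."""
    bandwidths = list(bandwidths)
    if not bandwidths:
        raise ValueError("empty bandwidth list")
    X, y = _design(geno, pheno)
    _check_variance(y)
    D2 = squared_distances(X)
    md2 = mean_offdiag(D2)
    kernels = [gaussian_kernel(D2, h, md2) for h in bandwidths]
    res = kernel_gibbs(kernels, y, n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)
    comps = [
        {"type": "gauss", "u": res["u"][k], "K": kernels[k],
         "h": bandwidths[k], "mean_d2": md2, "train_dosage": X,
         "sigma2": res["sigma2_k"][k]}
        for k in range(len(bandwidths))
    ]
    method = "MRKHS" if len(bandwidths) > 1 else "RKHS"
    return FittedModel(
        method=method, line_ids=geno.line_ids.copy(),
        marker_ids=geno.marker_ids.copy(),
        mu=res["mu"], fitted_gebv=res["mu"] + res["g"],
        sigma2_g=res["sigma2_g"], sigma2_e=res["sigma2_e"], pev=res["pev"],
        kernel_components=comps,
        mcmc={"n_iter": n_iter, "burn_in": burn_in, "thin": thin,
              "seed": seed, "n_samples": res["n_samples"],
              "bandwidths": bandwidths},
    )


#: default bandwidth ladder for the multi-kernel fit
MRKHS_BANDWIDTHS = (0.1, 0.5, 2.5)


# ----------------------------------------------------------------------
# penalized regression (RR / LASSO / EN)


def fit_penalized(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    penalty: str = "RR",
    alpha_mix: float = 0.5,
    lambda_grid=None,
    cv_folds: int = 5,
) -> FittedModel:
    """Elastic-net family on standardized dosages.

    ``penalty`` selects the mixing parameter: RR (ridge, alpha=0), LASSO
    (alpha=1) or EN (``alpha_mix``).  The penalty weight lambda is chosen
    by ``cv_folds``-fold cross-validation *inside the training data* over
    ``lambda_grid`` (an automatic grid if None).
    """
    from sklearn.linear_model import ElasticNetCV, Ridge, RidgeCV

    if penalty not in ("RR", "LASSO", "EN"):
        raise ValueError("penalty must be RR, LASSO or EN")
    if lambda_grid is not None:
        lambda_grid = np.asarray(list(lambda_grid), dtype=float)
        if lambda_grid.size == 0:
            raise ValueError("empty lambda grid")
    X, y = _design(geno, pheno)
    _check_variance(y)
    Xs, centers, scales = _standardize(X)

    chosen_lambda: float
    if penalty == "RR":
        grid = lambda_grid if lambda_grid is not None else np.logspace(-3, 5, 41)
        if grid.size == 1:
            est = Ridge(alpha=float(grid[0]), solver="cholesky").fit(Xs, y)
            chosen_lambda = float(grid[0])
        else:
            est = RidgeCV(alphas=grid, cv=cv_folds).fit(Xs, y)
            chosen_lambda = float(est.alpha_)
        beta_std = est.coef_
        mu = float(est.intercept_)
    else:
        l1_ratio = 1.0 if penalty == "LASSO" else float(alpha_mix)
        est = ElasticNetCV(
            l1_ratio=l1_ratio,
            alphas=100 if lambda_grid is None else lambda_grid,
            cv=cv_folds, max_iter=5000,
        ).fit(Xs, y)
        beta_std = est.coef_
        mu = float(est.intercept_)
        chosen_lambda = float(est.alpha_)

    beta = beta_std / scales
    g = (X - centers) @ beta
    return FittedModel(
        method=penalty, line_ids=geno.line_ids.copy(),
        marker_ids=geno.marker_ids.copy(),
        mu=mu, fitted_gebv=mu + g,
        beta=beta, centers=centers, scales=np.ones_like(scales),
        extra={"lambda": chosen_lambda,
               "alpha_mix": 0.0 if penalty == "RR" else (1.0 if penalty == "LASSO" else alpha_mix)},
    )


# ----------------------------------------------------------------------
# Bayesian whole-genome regression (BRR / BL / BA / BB / BC)


def fit_bayes(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    prior: str = "BRR",
    n_iter: int = 5000,
    burn_in: int = 1000,
    thin: int = 5,
    seed: int = 0,
    R2: float = 0.5,
    df_prior: float = 5.0,
    pi0: float = 0.5,
    pi_counts: float = 10.0,
) -> FittedModel:
    """Gibbs sampler for y = 1*mu + X*beta + e with the named prior.

    Hyperparameters follow the variance-partition rule: prior scales are
    set so the markers are expected to explain ``R2`` of the phenotypic
    variance a priori.  Chains are seeded and reproducible; PEV comes
    from the posterior variance of each line's genetic value.
    """
    if prior not in PRIOR_CODES:
        raise ValueError(f"prior must be one of {tuple(PRIOR_CODES)}")
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    X, y = _design(geno, pheno)
    _check_variance(y)
    centers = X.mean(axis=0)
    Xc = np.ascontiguousarray(X - centers)
    out = marker_gibbs(
        Xc, np.ascontiguousarray(y, dtype=float), PRIOR_CODES[prior],
        int(n_iter), int(burn_in), int(thin), int(seed) % (2**31 - 1),
        float(R2), float(df_prior), float(df_prior), float(pi0), float(pi_counts),
    )
    mu, beta, g, pev, s2e, s2g, pi, n_samples = out
    if not np.isfinite(beta).all():
        bad = int(np.flatnonzero(~np.isfinite(beta))[0])
        raise FloatingPointError(f"non-finite posterior mean at marker index {bad}")
    return FittedModel(
        method=prior, line_ids=geno.line_ids.copy(),
        marker_ids=geno.marker_ids.copy(),
        mu=float(mu), fitted_gebv=float(mu) + Xc @ beta,
        sigma2_g=float(s2g), sigma2_e=float(s2e), pev=pev,
        beta=beta, centers=centers, scales=np.ones_like(centers),
        mcmc={"n_iter": n_iter, "burn_in": burn_in, "thin": thin,
              "seed": seed, "n_samples": int(n_samples),
              "pi": float(pi) if prior in ("BB", "BC") else None},
    )


# ----------------------------------------------------------------------
# machine-learning fits (RF / SVM / BRNN)


def _canonical_features(geno: GenotypeMatrix):
    """Columns sorted by marker id so predictions do not depend on the
    incoming column order."""
    order = np.argsort(geno.marker_ids)
    return geno.dosage[:, order], geno.marker_ids[order]


def fit_rf(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    n_trees: int = 500,
    seed: int = 0,
) -> FittedModel:
    """Random forest regression on dosage features (seeded)."""
    from sklearn.ensemble import RandomForestRegressor

    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X, y = _design(geno, pheno)
    _check_variance(y)
    feats, ids = _canonical_features(geno)
    est = RandomForestRegressor(
        n_estimators=n_trees, random_state=int(seed) % (2**31 - 1), n_jobs=1
    ).fit(feats, y)
    fitted = est.predict(feats)
    return FittedModel(
        method="RF", line_ids=geno.line_ids.copy(), marker_ids=ids,
        mu=float(y.mean()), fitted_gebv=fitted, estimator=est,
        centers=np.zeros(ids.size), scales=np.ones(ids.size),
    )


def fit_svm(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    cost: float = 1.0,
    epsilon: float = 0.1,
    gamma="scale",
) -> FittedModel:
    """Epsilon-insensitive support-vector regression, RBF kernel, on
    standardized dosages.  Warns on very large marker panels, where this
    method is known to degrade."""
    from sklearn.svm import SVR

    if cost <= 0:
        raise ValueError("cost must be positive")
    X, y = _design(geno, pheno)
    _check_variance(y)
    if geno.n_markers > SVM_MARKER_WARN:
        warnings.warn(
            f"SVM with {geno.n_markers} markers: RBF support-vector "
            "regression degrades on very large panels; consider marker "
            "reduction first",
            UserWarning,
        )
    feats, ids = _canonical_features(geno)
    fs, centers, scales = _standardize(feats)
    est = SVR(C=cost, epsilon=epsilon, gamma=gamma).fit(fs, y)
    return FittedModel(
        method="SVM", line_ids=geno.line_ids.copy(), marker_ids=ids,
        mu=float(y.mean()), fitted_gebv=est.predict(fs), estimator=est,
        centers=centers, scales=scales,
    )


def fit_brnn(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    neurons: int = 2,
    epochs: int = 20,
    seed: int = 0,
) -> FittedModel:
    """Single-hidden-layer tanh network with Bayesian-regularized
    (evidence-weighted) least squares; defaults neurons=2, epochs=20."""
    X, y = _design(geno, pheno)
    _check_variance(y)
    feats, ids = _canonical_features(geno)
    est = BRNNRegressor(neurons=neurons, epochs=epochs, seed=int(seed) % (2**31 - 1))
    est.fit(feats, y)
    return FittedModel(
        method="BRNN", line_ids=geno.line_ids.copy(), marker_ids=ids,
        mu=float(y.mean()), fitted_gebv=est.predict(feats), estimator=est,
        centers=np.zeros(ids.size), scales=np.ones(ids.size),
    )


# ----------------------------------------------------------------------
# dispatch and scoring


def fit(method: str, geno: GenotypeMatrix, pheno: PhenotypeVector, **params) -> FittedModel:
    """Fit any of the fifteen methods by tag."""
    method = method.upper()
    if method == "GBLUP":
        return fit_gblup(geno, pheno, **params)
    if method == "EGBLUP":
        return fit_egblup(geno, pheno, **params)
    if method in ("RR", "LASSO", "EN"):
        return fit_penalized(geno, pheno, penalty=method, **params)
    if method in PRIOR_CODES:
        return fit_bayes(geno, pheno, prior=method, **params)
    if method == "RKHS":
        params.setdefault("bandwidths", (1.0,))
        return fit_rkhs(geno, pheno, **params)
    if method == "MRKHS":
        params.setdefault("bandwidths", MRKHS_BANDWIDTHS)
        return fit_rkhs(geno, pheno, **params)
    if method == "RF":
        return fit_rf(geno, pheno, **params)
    if method == "SVM":
        return fit_svm(geno, pheno, **params)
    if method == "BRNN":
        return fit_brnn(geno, pheno, **params)
    raise ValueError(f"unknown method {method!r}; choose one of {METHODS}")


def _cross_genetic_value(comp: dict, X_target: np.ndarray) -> np.ndarray:
    """Project a kernel component's effect onto target lines:
    u_target = K_cross (K_train + jitter)^{-1} u_train."""
    Xt = comp["train_dosage"]
    if comp["type"] in ("vanraden_scaled", "vanraden_scaled_sq"):
        p, c, diag = comp["p"], comp["c"], comp["diag"]
        Wt = X_target - 2.0 * p
        W = Xt - 2.0 * p
        Kc = (Wt @ W.T) / c
        d_t = np.sqrt(np.maximum(np.einsum("ij,ij->i", Wt, Wt) / c, 1e-12))
        Kc = Kc / np.outer(d_t, diag)
        if comp["type"] == "vanraden_scaled_sq":
            Kc = Kc * Kc
    elif comp["type"] == "gauss":
        D2 = squared_distances(X_target, Xt)
        Kc = gaussian_kernel(D2, comp["h"], comp["mean_d2"])
    else:  # pragma: no cover
        raise ValueError(f"unknown kernel component {comp['type']!r}")
    K = comp["K"] + PSD_JITTER * np.eye(comp["K"].shape[0])
    return Kc @ np.linalg.solve(K, comp["u"])


def predict_gebv(model: FittedModel, target_geno: GenotypeMatrix) -> pd.DataFrame:
    """Score a fitted model on target genotypes.

    The target must carry exactly the training marker panel (any column
    order); rows are aligned by line id.  Returns a DataFrame with
    columns (line_id, gebv, sd, reliability); sd/reliability are filled
    where the model exposes prediction error variances for those lines.
    """
    if np.isnan(target_geno.dosage).any():
        raise ValueError("target genotypes contain missing values; impute first")
    train_set = set(model.marker_ids)
    target_set = set(target_geno.marker_ids)
    if train_set != target_set:
        missing = sorted(train_set - target_set)[:5]
        extra = sorted(target_set - train_set)[:5]
        raise ValueError(
            f"marker panel mismatch: missing from target {missing}, "
            f"extra in target {extra}"
        )
    aligned = target_geno.subset_markers(model.marker_ids)
    X = aligned.dosage

    if model.beta is not None:
        g = ((X - model.centers) / model.scales) @ model.beta
        gebv = model.mu + g
    elif model.kernel_components is not None:
        g = np.zeros(X.shape[0])
        for comp in model.kernel_components:
            g += _cross_genetic_value(comp, X)
        gebv = model.mu + g
    elif model.estimator is not None:
        feats = (X - model.centers) / model.scales
        gebv = model.estimator.predict(feats)
    else:  # pragma: no cover
        raise ValueError("model has no scoreable representation")

    out = pd.DataFrame({"line_id": aligned.line_ids, "gebv": gebv})
    out["sd"] = np.nan
    out["reliability"] = np.nan
    if model.pev is not None:
        pev_by_id = pd.Series(model.pev, index=model.line_ids)
        shared = out["line_id"].isin(pev_by_id.index)
        pevs = pev_by_id.reindex(out.loc[shared, "line_id"]).to_numpy()
        out.loc[shared, "sd"] = np.sqrt(pevs)
        if model.sigma2_g and model.sigma2_g > 0:
            out.loc[shared, "reliability"] = np.clip(
                1.0 - pevs / model.sigma2_g, 0.0, 1.0
            )
    return out
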