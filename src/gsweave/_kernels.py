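"""Kernel construction and the Gibbs sampler for kernel mixed models.

Used by the kernel-regression methods: RKHS / multi-kernel RKHS
(Gaussian kernels on genotype distances) and the epistatic extension of
GBLUP (additive kernel plus its elementwise square).  The model is

    y = 1*mu + sum_k u_k + e,   u_k ~ N(0, K_k * sigma2_k)

sampled in the eigenbasis of each kernel where the conditionals are
independent Gaussians.
"""

from __future__ import annotations

import numpy as np

#: eigenvalues below this fraction of the largest are dropped
EIG_TOL = 1e-10


def gaussian_kernel(D2: np.ndarray, h: float, mean_d2: float) -> np.ndarray:
    """K = exp(-h * d2 / mean_d2) on squared Euclidean genotype distances."""
    return np.exp(-h * D2 / mean_d2)


def squared_distances(X: np.ndarray, Z: np.ndarray | None = None) -> np.ndarray:
    """Pairwise squared Euclidean distances between rows of X (and Z)."""
    if Z is None:
        Z = X
    xx = (X * X).sum(axis=1)
    zz = (Z * Z).sum(axis=1)
    D2 = xx[:, None] + zz[None, :] - 2.0 * (X @ Z.T)
    return np.maximum(D2, 0.0)


def mean_offdiag(D2: np.ndarray) -> float:
    n = D2.shape[0]
    if n < 2:
        return 1.0
    total = D2.sum() - np.trace(D2)
    return float(total / (n * (n - 1)))


def kernel_gibbs(
    kernels: list[np.ndarray],
    y: np.ndarray,
    n_iter: int = 5000,
    burn_in: int = 1000,
    thin: int = 5,
    seed: int = 0,
    R2: float = 0.5,
    df: float = 5.0,
):
    """Gibbs sampler for the multi-kernel Gaussian mixed model.

    Returns a dict with posterior means: mu, per-kernel genetic values
    ``u`` (list), total genetic value ``g``, its posterior variance
    ``pev``, variance components ``sigma2_k`` / ``sigma2_e``, and
    ``sigma2_g`` (posterior mean of var(g) across lines).
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    n = y.size
    nk = len(kernels)
    if nk == 0:
        raise ValueError("need at least one kernel")
    Vs, ds = [], []
    for K in kernels:
        d, V = np.linalg.eigh(0.5 * (K + K.T))
        keep = d > EIG_TOL * max(d.max(), 1.0)
        Vs.append(V[:, keep])
        ds.append(d[keep])

    vy = y.var()
    vy = vy if vy > 0 else 1e-8
    s2e = vy * (1.0 - R2)
    Se = vy * (1.0 - R2) * (df + 2.0)
    s2k = np.empty(nk)
    Sk = np.empty(nk)
    for k, K in enumerate(kernels):
        md = float(np.mean(np.diag(K)))
        md = md if md > 0 else 1.0
        s2k[k] = vy * R2 / (nk * md)
        Sk[k] = s2k[k] * (df + 2.0)

    mu = y.mean()
    a = [np.zeros(d.size) for d in ds]
    u = [np.zeros(n) for _ in range(nk)]
    e = y - mu

    n_samples = 0
    mu_s = 0.0
    u_s = [np.zeros(n) for _ in range(nk)]
    g_s = np.zeros(n)
    g2_s = np.zeros(n)
    s2k_s = np.zeros(nk)
    s2e_s = 0.0
    varg_s = 0.0

    for it in range(n_iter):
        off = e.mean()
        mu_new = mu + off + rng.standard_normal() * np.sqrt(s2e / n)
        e -= (mu_new - mu)
        mu = mu_new

        for k in range(nk):
            V, d = Vs[k], ds[k]
            e += u[k]
            z = V.T @ e
            prec = d * s2k[k]
            post_var = prec * s2e / (prec + s2e)
            post_mean = z * prec / (prec + s2e)
            a[k] = post_mean + rng.standard_normal(d.size) * np.sqrt(post_var)
            u[k] = V @ a[k]
            e -= u[k]
            ss = float(np.sum(a[k] ** 2 / d))
            s2k[k] = (Sk[k] + ss) / rng.chisquare(df + d.size)

        s2e = (Se + float(e @ e)) / rng.chisquare(df + n)
        s2e = max(s2e, 1e-12)

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_samples += 1
            mu_s += mu
            g = np.zeros(n)
            for k in range(nk):
                u_s[k] += u[k]
                g += u[k]
            g_s += g
            g2_s += g * g
            varg_s += g.var(ddof=1) if n > 1 else 0.0
            s2k_s += s2k
            s2e_s += s2e

    inv = 1.0 / max(n_samples, 1)
    g_mean = g_s * inv
    pev = np.maximum(g2_s * inv - g_mean**2, 0.0)
    return {
        "mu": mu_s * inv,
        "u": [uk * inv for uk in u_s],
        "g": g_mean,
        "pev": pev,
        "sigma2_k": s2k_s * inv,
        "sigma2_e": s2e_s * inv,
        "sigma2_g": varg_s * inv,
        "n_samples": n_samples,
    }
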