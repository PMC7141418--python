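"""Missing-genotype imputation.

Two strategies:

* MNI — each missing call is replaced by the mean of the observed dosages
  of its marker (real-valued, not rounded).  Adequate for sparse
  missingness such as SNP-chip data.
* EMI — expectation-maximization under the additive-relationship model.
  Missing entries of each marker are re-imputed by their conditional
  expectation given the current kinship structure among lines (E-step),
  and the kinship matrix is recomputed from the completed matrix
  (M-step), until the kinship stops changing.  Designed for heavily
  missing, randomly distributed data such as genotyping-by-sequencing.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import GenotypeMatrix, PSD_JITTER

__all__ = ["ImputationReport", "impute_mni", "impute_emi"]


@dataclass
class ImputationReport:
    method: str                 # "MNI" or "EMI"
    n_imputed: int
    iterations: int = 0        # EMI only
    final_change: float = 0.0  # max-norm of last kinship update (EMI only)
    converged: bool = True


def impute_mni(geno: GenotypeMatrix):
    """Mean-frequency imputation: missing calls -> observed column mean.

    Returns (imputed GenotypeMatrix, ImputationReport).  Observed cells
    are untouched; imputed values are real numbers in [0, 2].
    """
    mask = geno.missing_mask
    fully_missing = mask.all(axis=0)
    if fully_missing.any():
        bad = geno.marker_ids[fully_missing][:5].tolist()
        raise ValueError(f"markers with no observed calls: {bad}")
    col_means = np.nanmean(geno.dosage, axis=0)
    filled = np.where(mask, col_means[None, :], geno.dosage)
    out = dataclasses.replace(geno, dosage=filled, validate_integer=False)
    return out, ImputationReport(method="MNI", n_imputed=int(mask.sum()))


@njit(cache=True)
def _em_estep(W, mask, A, Ainv):
    """E-step on the centred matrix W, column by column.

    For a column with observed block o and missing block m, the
    conditional mean is E[w_m | w_o] = A_mo A_oo^{-1} w_o.  Two
    algebraically identical routes are used depending on which block is
    smaller: invert A_oo directly, or solve Ainv_mm w_m = -Ainv_mo w_o
    on the missing block of the precomputed full inverse.
    """
    n, m = W.shape
    for j in range(m):
        n_mis = 0
        for i in range(n):
            if mask[i, j]:
                n_mis += 1
        if n_mis == 0:
            continue
        mis = np.empty(n_mis, dtype=np.int64)
        obs = np.empty(n - n_mis, dtype=np.int64)
        a = 0
        b = 0
        for i in range(n):
            if mask[i, j]:
                mis[a] = i
                a += 1
            else:
                obs[b] = i
                b += 1
        w = W[:, j]
        if obs.size <= n_mis:
            Aoo = A[obs, :][:, obs].copy()
            Wm = A[mis, :][:, obs] @ np.linalg.solve(Aoo, w[obs].copy())
        else:
            Amm = Ainv[mis, :][:, mis].copy()
            rhs = -(Ainv[mis, :][:, obs] @ w[obs].copy())
            Wm = np.linalg.solve(Amm, rhs)
        for k in range(n_mis):
            W[mis[k], j] = Wm[k]


def _cauchy_schwarz_clip(A: np.ndarray) -> np.ndarray:
    """Bound |A_ik| by sqrt(A_ii * A_kk); guards pairwise estimates whose
    denominators are tiny."""
    d = np.diag(A).copy()
    s = np.sqrt(np.maximum(d, 1e-12))
    bound = np.outer(s, s)
    A = np.clip(A, -bound, bound)
    np.fill_diagonal(A, d)
    return A


def _observed_kinship(W: np.ndarray, mask: np.ndarray, p: np.ndarray,
                      shrink_markers: float) -> np.ndarray:
    """Pairwise-complete VanRaden estimate from the observed calls only.

    Each entry is normalised by the expected variance of the markers the
    pair actually shares, so it is unbiased under random missingness,
    then shrunk toward zero by overlap/(overlap + shrink_markers) to
    damp the sampling noise of sparsely shared pairs.  On dense panels
    the shrinkage vanishes and the estimate coincides with the plug-in
    VanRaden matrix.
    """
    M = (~mask).astype(float)
    var = 2.0 * p * (1.0 - p)
    num = W @ W.T
    den = (M * var) @ M.T
    overlap = M @ M.T
    A = num / np.maximum(den, 1e-12)
    A *= overlap / (overlap + shrink_markers)
    np.fill_diagonal(A, np.diag(num) / np.maximum(np.diag(den), 1e-12))
    return _cauchy_schwarz_clip(A)


def impute_emi(
    geno: GenotypeMatrix,
    tol: float = 0.02,
    max_iter: int = 100,
    block_size: int | None = None,
    ridge: float = 0.05,
    shrink_markers: float = 100.0,
):
    """EM imputation under the additive-relationship model.

    Starting from a pairwise-complete (observed-calls-only) estimate of
    the additive relationship matrix, the algorithm alternates (E)
    conditional re-imputation of each missing cell given the current
    relationship structure among lines with (M) re-estimation of the
    relationship matrix.  Because imputed cells carry no information
    about relatedness beyond the current matrix, the M-step blends the
    plug-in estimate from the completed data with the fixed
    observed-data estimate, weighting the latter by the missing
    fraction; as missingness goes to zero this reduces to the classical
    plug-in EM.  Iteration stops when the max-norm change of the matrix
    falls below ``tol``, when the change stalls, or at ``max_iter``.

    Parameters
    ----------
    block_size : optional chunk of markers processed per E-step pass;
        columns are conditionally independent so results do not depend
        on it (it only bounds transient memory).
    ridge : fraction of the mean kinship diagonal added to the
        conditioning covariance in the E-step.  Plays the role of
        per-marker residual variance around the kinship model;
        stabilises the conditional solves when related lines are
        near-clones and shrinks imputations slightly toward the marker
        mean.
    shrink_markers : overlap scale (in markers) of the shrinkage applied
        to the observed-data kinship estimate; pairs sharing many more
        observed markers than this are taken at face value.

    Returns (imputed GenotypeMatrix, ImputationReport).
    """
    if geno.n_lines < 2:
        raise ValueError("EM imputation needs at least 2 lines")
    mask = geno.missing_mask
    n_missing = int(mask.sum())
    if n_missing == 0:
        rep = ImputationReport(method="EMI", n_imputed=0, iterations=1, final_change=0.0)
        return dataclasses.replace(geno, validate_integer=False), rep
    if mask.all(axis=0).any():
        bad = geno.marker_ids[mask.all(axis=0)][:5].tolist()
        raise ValueError(f"markers with no observed calls: {bad}")
    if mask.all(axis=1).any():
        bad = geno.line_ids[mask.all(axis=1)][:5].tolist()
        raise ValueError(f"lines with no observed calls: {bad}")

    n, m = geno.dosage.shape
    # centring by observed allele frequencies; MNI start = zeros in W space
    p = np.nanmean(geno.dosage, axis=0) / 2.0
    W = geno.dosage - 2.0 * p[None, :]
    W[mask] = 0.0
    W_obs = W[~mask]
    c = 2.0 * np.sum(p * (1.0 - p))
    if c <= 0:
        raise ValueError("all markers monomorphic; cannot build relationship matrix")
    blocks = [np.arange(m)] if not block_size else [
        np.arange(s, min(s + block_size, m)) for s in range(0, m, block_size)
    ]
    # feasible dosage range in centred coordinates
    lo = -2.0 * p[None, :]
    hi = 2.0 - 2.0 * p[None, :]

    A_obs = _observed_kinship(W, mask, p, shrink_markers)
    w_obs_weight = n_missing / mask.size
    A_prev = A_obs
    change = np.inf
    best_change = np.inf
    stall = 0
    it = 0
    converged = False
    while it < max_iter:
        it += 1
        delta = max(ridge * np.trace(A_prev) / n, PSD_JITTER)
        A = A_prev + delta * np.eye(n)
        Ainv = np.linalg.inv(A)
        for idx in blocks:
            Wb = np.ascontiguousarray(W[:, idx])
            _em_estep(Wb, np.ascontiguousarray(mask[:, idx]), A, Ainv)
            W[:, idx] = Wb
        np.clip(W, lo, hi, out=W)
        W[~mask] = W_obs
        A_new = _cauchy_schwarz_clip(
            w_obs_weight * A_obs + (1.0 - w_obs_weight) * (W @ W.T) / c
        )
        change = float(np.max(np.abs(A_new - A_prev)))
        A_prev = A_new
        if change < tol:
            converged = True
            break
        # stall detection: the max-norm settles into a bounded oscillation
        # of a few clipped entries long before max_iter
        if change < best_change * 0.99:
            best_change = change
            stall = 0
        else:
            stall += 1
            if stall >= 3:
                converged = True
                break
    if not converged:
        warnings.warn(
            f"EM imputation did not converge in {max_iter} iterations "
            f"(last change {change:.4g}); returning current estimate",
            RuntimeWarning,
        )
    filled = W + 2.0 * p[None, :]
    filled = np.clip(filled, 0.0, 2.0)
    filled[~mask] = geno.dosage[~mask]          # observed cells bitwise untouched
    out = dataclasses.replace(geno, dosage=filled, validate_integer=False)
    rep = ImputationReport(
        method="EMI", n_imputed=n_missing, iterations=it,
        final_change=change, converged=converged,
    )
    return out, rep
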