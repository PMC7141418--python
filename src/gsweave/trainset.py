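"""Training-set selection: random sampling or CDmean exchange optimization.

The CDmean criterion measures, under the kinship-based mixed model, how
precisely the training set determines the genetic values of the
unphenotyped (validation) lines.  For a contrast c between an
unphenotyped line and the validation-set mean, the coefficient of
determination is

    CD(c) = c' (G - lambda * (Z'MZ + lambda * G^{-1})^{-1}) c / (c' G c)

with G the additive relationship matrix, Z the incidence of phenotyped
lines, M the within-training-set centring projector and
lambda = sigma2_e / sigma2_g.  The optimizer greedily exchanges one
selected line against one unselected line, accepting swaps that strictly
increase the mean CD over validation lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RelationshipMatrix, PSD_JITTER

__all__ = ["TrainingSelection", "sample_random_training", "cd_mean", "optimize_cdmean"]


@dataclass
class TrainingSelection:
    selected_ids: np.ndarray
    method: str                       # RANDOM | OPTI
    validation_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=str))
    cdmean: float | None = None
    lam: float | None = None
    n_swaps_accepted: int = 0

    def __post_init__(self):
        self.selected_ids = np.asarray(self.selected_ids, dtype=str)
        self.validation_ids = np.asarray(self.validation_ids, dtype=str)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected_ids": self.selected_ids.tolist(),
            "validation_ids": self.validation_ids.tolist(),
            "cdmean": self.cdmean,
            "lambda": self.lam,
            "n_swaps_accepted": self.n_swaps_accepted,
        }


def sample_random_training(ids, size: int, seed: int) -> TrainingSelection:
    """Uniform random training subset; the complement is the validation set."""
    ids = np.asarray(ids, dtype=str)
    n = ids.size
    if not 1 < size < n:
        raise ValueError(f"training size must be in (1, {n}), got {size}")
    rng = np.random.default_rng(seed)
    sel = rng.choice(n, size=size, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[sel] = True
    return TrainingSelection(ids[mask], "RANDOM", validation_ids=ids[~mask])


def _cd_values(G: np.ndarray, Ginv: np.ndarray, sel_mask: np.ndarray, lam: float) -> np.ndarray:
    """CD of each unselected line's contrast against the unselected mean."""
    n = G.shape[0]
    s = int(sel_mask.sum())
    unsel = np.flatnonzero(~sel_mask)
    # coefficient matrix C = Z'MZ + lam * Ginv  (Z'MZ: centring projector
    # on the selected block, zero elsewhere)
    C = lam * Ginv
    sel = np.flatnonzero(sel_mask)
    C[np.ix_(sel, sel)] += -1.0 / s
    C[sel, sel] += 1.0
    # contrasts: e_i - mean over unselected
    n_u = unsel.size
    Ct = np.zeros((n, n_u))
    Ct[unsel, :] = -1.0 / n_u
    Ct[unsel, np.arange(n_u)] += 1.0
    X = np.linalg.solve(C, Ct)
    num = np.einsum("ij,ij->j", Ct, G @ Ct - lam * X)
    den = np.einsum("ij,ij->j", Ct, G @ Ct)
    cd = np.where(den > 0, num / den, 0.0)
    return np.clip(cd, 0.0, 1.0)


def cd_mean(A: RelationshipMatrix, selected_ids, lam: float = 1.0) -> float:
    """Mean coefficient of determination over unselected lines.

    ``lam`` is the variance ratio sigma2_e / sigma2_g; the default 1
    corresponds to an assumed heritability of 0.5.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    selected_ids = np.asarray(selected_ids, dtype=str)
    if selected_ids.size == 0:
        raise ValueError("selected set is empty")
    sel_mask = np.isin(A.line_ids, selected_ids)
    if sel_mask.sum() != selected_ids.size:
        raise KeyError("selected ids not all present in relationship matrix")
    if sel_mask.all():
        raise ValueError("no unselected lines left to validate on")
    G = A.A + PSD_JITTER * np.eye(A.n_lines)
    Ginv = np.linalg.inv(G)
    return float(np.mean(_cd_values(G, Ginv, sel_mask, lam)))


def optimize_cdmean(
    A: RelationshipMatrix,
    size: int,
    lam: float = 1.0,
    n_iter: int = 3000,
    n_stall: int = 500,
    seed: int = 0,
) -> TrainingSelection:
    """Exchange (drop-replacement) search maximizing the mean CD.

    Starts from a seeded random subset of the requested size; each
    iteration proposes swapping one selected line with one unselected
    line and accepts the swap iff the mean CD strictly increases.  After
    ``n_stall`` consecutive rejections the current subset is a local
    optimum of the single-swap neighbourhood; the search then restarts
    from a fresh random subset (keeping the best subset seen) until the
    ``n_iter`` proposal budget is spent.
    """
    n = A.n_lines
    if not 1 < size < n:
        raise ValueError(f"training size must be in (1, {n}), got {size}")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    rng = np.random.default_rng(seed)
    G = A.A + PSD_JITTER * np.eye(n)
    Ginv = np.linalg.inv(G)

    def random_start():
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=size, replace=False)] = True
        return mask, float(np.mean(_cd_values(G, Ginv, mask, lam)))

    sel_mask, current = random_start()
    best_mask, best = sel_mask.copy(), current
    accepted = 0
    stall = 0
    for _ in range(n_iter):
        if stall >= n_stall:
            sel_mask, current = random_start()
            stall = 0
            if current > best:
                best_mask, best = sel_mask.copy(), current
        sel = np.flatnonzero(sel_mask)
        unsel = np.flatnonzero(~sel_mask)
        out_i = sel[rng.integers(sel.size)]
        in_i = unsel[rng.integers(unsel.size)]
        sel_mask[out_i] = False
        sel_mask[in_i] = True
        cand = float(np.mean(_cd_values(G, Ginv, sel_mask, lam)))
        if cand > current:
            current = cand
            accepted += 1
            stall = 0
            if cand > best:
                best_mask, best = sel_mask.copy(), cand
        else:
            sel_mask[out_i] = True
            sel_mask[in_i] = False
            stall += 1
    return TrainingSelection(
        A.line_ids[best_mask], "OPTI",
        validation_ids=A.line_ids[~best_mask],
        cdmean=best, lam=lam, n_swaps_accepted=accepted,
    )
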