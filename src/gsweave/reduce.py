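"""Marker-set reduction: random sampling, LD pruning, ANOVA screening.

Reduction can speed up model fitting on dense panels and, for the
association screen, concentrate the panel on trait-linked markers.  The
ANOVA screen is leakage-prone: selecting markers on the full population
and then cross-validating overstates predictive ability, so the
cross-validation engine re-runs the screen inside each training fold by
default ("fold-honest" mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix, MarkerMap, PhenotypeVector

__all__ = [
    "ReductionResult",
    "select_random_markers",
    "prune_ld",
    "select_anova",
    "select_anova_ld",
    "pairwise_r2",
    "anova_pvalues",
]

#: pairs sharing fewer observed lines than this are treated as unlinked
MIN_SHARED_OBS = 10


@dataclass
class ReductionResult:
    method: str                       # RMR | LD | ANO | ANO_LD
    kept_marker_ids: np.ndarray
    params: dict = field(default_factory=dict)
    per_marker_stats: pd.DataFrame | None = None

    def __post_init__(self):
        self.kept_marker_ids = np.asarray(self.kept_marker_ids, dtype=str)
        if len(np.unique(self.kept_marker_ids)) != self.kept_marker_ids.size:
            raise ValueError("duplicate markers in reduction result")

    @property
    def n_kept(self) -> int:
        return self.kept_marker_ids.size

    def to_table(self, all_marker_ids=None) -> pd.DataFrame:
        """Per-marker kept flag merged with any per-marker statistics."""
        ids = np.asarray(all_marker_ids, dtype=str) if all_marker_ids is not None \
            else self.kept_marker_ids
        t = pd.DataFrame({"marker_id": ids})
        t["kept"] = t["marker_id"].isin(self.kept_marker_ids)
        if self.per_marker_stats is not None:
            t = t.merge(self.per_marker_stats, on="marker_id", how="left")
        return t


def select_random_markers(geno: GenotypeMatrix, k: int, seed: int) -> ReductionResult:
    """Uniform sample of k markers without replacement (RMR)."""
    m = geno.n_markers
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(m, size=k, replace=False))
    return ReductionResult("RMR", geno.marker_ids[idx], params={"k": k, "seed": seed})


def pairwise_r2(dosage: np.ndarray, min_shared: int = MIN_SHARED_OBS) -> np.ndarray:
    """Squared Pearson correlation between marker columns, pairwise-complete.

    Pairs with fewer than ``min_shared`` jointly observed lines, or with
    zero variance on the shared lines, get r2 = 0.
    """
    X = np.asarray(dosage, dtype=float)
    M = (~np.isnan(X)).astype(float)
    V = np.where(np.isnan(X), 0.0, X)
    n = M.T @ M                       # shared observation counts
    sx = V.T @ M                      # sum of x over shared rows (per pair)
    sxx = (V * V).T @ M
    sxy = V.T @ V
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx**2
        denom = varx * varx.T
        r2 = np.where(denom > 0, cov**2 / denom, 0.0)
    r2[n < min_shared] = 0.0
    np.fill_diagonal(r2, 1.0)
    return r2


def prune_ld(
    geno: GenotypeMatrix,
    marker_map: MarkerMap,
    r2_threshold: float,
    seed: int | None = None,
) -> ReductionResult:
    """LD pruning: within each chromosome, drop one member of every marker
    pair with r2 above the threshold.

    Markers are scanned in map-position order; for each pair in LD the
    member with more missing calls is removed (ties broken at random,
    seeded).  Markers on different chromosomes are never compared; a
    chromosome with a single marker is kept unconditionally.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must be in (0, 1]")
    chrom = marker_map.chromosome_of()
    missing_from_map = set(geno.marker_ids) - set(chrom.index)
    if missing_from_map:
        raise KeyError(f"markers absent from map: {sorted(missing_from_map)[:5]}")
    rng = np.random.default_rng(seed)
    pos = marker_map.position_of()
    col_of = {mid: j for j, mid in enumerate(geno.marker_ids)}
    n_missing = np.isnan(geno.dosage).sum(axis=0)

    kept: list[str] = []
    order = pd.DataFrame({
        "marker_id": geno.marker_ids,
        "chromosome": chrom.loc[geno.marker_ids].to_numpy(),
        "position": pos.loc[geno.marker_ids].to_numpy(),
    }).sort_values(["chromosome", "position"], kind="stable")

    for _, grp in order.groupby("chromosome", sort=False):
        ids = grp["marker_id"].to_numpy()
        if ids.size == 1:
            kept.append(ids[0])
            continue
        cols = np.array([col_of[i] for i in ids])
        r2 = pairwise_r2(geno.dosage[:, cols])
        miss = n_missing[cols]
        alive = np.ones(ids.size, dtype=bool)
        for a in range(ids.size):
            if not alive[a]:
                continue
            for b in range(a + 1, ids.size):
                if not alive[b]:
                    continue
                if r2[a, b] > r2_threshold:
                    # keep the member with fewer missing calls
                    if miss[a] > miss[b]:
                        alive[a] = False
                        break
                    elif miss[b] > miss[a]:
                        alive[b] = False
                    else:
                        if rng.random() < 0.5:
                            alive[b] = False
                        else:
                            alive[a] = False
                            break
        kept.extend(ids[alive])

    keep_set = set(kept)
    kept_in_input_order = [m for m in geno.marker_ids if m in keep_set]
    return ReductionResult(
        "LD", np.asarray(kept_in_input_order, dtype=str),
        params={"r2_threshold": r2_threshold, "seed": seed},
    )


def anova_pvalues(dosage: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Single-marker regression F-test p-value per marker.

    Fits phenotype ~ dosage for each marker (1 df slope test) and returns
    the p-value of the F statistic.  Zero-variance markers get p = 1.
    """
    X = np.asarray(dosage, dtype=float)
    if np.isnan(X).any():
        raise ValueError("ANOVA screen requires imputed genotypes")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 lines for the F test")
    y = np.asarray(y, dtype=float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        ssr = np.where(sxx > 0, sxy**2 / sxx, 0.0)
        sse = np.maximum(syy - ssr, 0.0)
        F = ssr / (sse / (n - 2))
    pvals = np.where(sxx > 0, stats.f.sf(F, 1, n - 2), 1.0)
    # perfect fits: sse == 0 with signal -> p = 0
    pvals = np.where((sxx > 0) & (sse == 0) & (ssr > 0), 0.0, pvals)
    return pvals


def select_anova(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    pval: float,
) -> ReductionResult:
    """Keep markers whose single-marker regression p-value is < pval."""
    if not 0 < pval <= 1:
        raise ValueError("pval must be in (0, 1]")
    y = pheno.aligned_to(geno.line_ids)
    p = anova_pvalues(geno.dosage, y)
    keep = p < pval
    if pval == 1.0:
        keep = np.ones_like(keep)  # threshold 1 retains the full set
    stats_table = pd.DataFrame({"marker_id": geno.marker_ids, "p_value": p,
                                "zero_variance": np.nanstd(geno.dosage, axis=0) == 0})
    return ReductionResult(
        "ANO", geno.marker_ids[keep], params={"pval": pval},
        per_marker_stats=stats_table,
    )


def select_anova_ld(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    marker_map: MarkerMap,
    pval: float,
    r2_threshold: float,
    seed: int | None = None,
) -> ReductionResult:
    """ANOVA screen followed by LD pruning of the selected markers."""
    ano = select_anova(geno, pheno, pval)
    sub = geno.subset_markers(ano.kept_marker_ids)
    if sub.n_markers == 1:
        kept = sub.marker_ids
    else:
        kept = prune_ld(sub, marker_map, r2_threshold, seed=seed).kept_marker_ids
    return ReductionResult(
        "ANO_LD", kept,
        params={"pval": pval, "r2_threshold": r2_threshold, "seed": seed},
        per_marker_stats=ano.per_marker_stats,
    )
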