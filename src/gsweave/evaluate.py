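"""Replicated random k-fold cross-validation and quality metrics.

Predictive ability is the Pearson correlation between merged GEBV and
observed (adjusted) phenotypes across the whole data set — the "hold
accuracy", computed over the union of the folds rather than averaged
fold by fold.  RMSEP is the root mean squared error of prediction, and
per-individual reliability is REL = 1 - PEV / sigma2_g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PhenotypeVector
from .impute import impute_emi, impute_mni
from .predictors import METHODS, fit, predict_gebv
from .reduce import prune_ld, select_anova, select_anova_ld, select_random_markers

__all__ = [
    "CVResult",
    "run_cross_validation",
    "predictive_ability",
    "rmsep",
    "reliability",
    "make_folds",
]


def predictive_ability(gebv_merged, observed) -> float:
    """Pearson correlation between merged GEBV and observed phenotypes."""
    g = np.asarray(gebv_merged, dtype=float)
    y = np.asarray(observed, dtype=float)
    if g.size != y.size:
        raise ValueError("length mismatch")
    if g.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(g) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in GEBV or phenotype")
    return float(np.corrcoef(g, y)[0, 1])


def rmsep(gebv_merged, observed) -> float:
    """Root mean squared error of prediction, in trait units."""
    g = np.asarray(gebv_merged, dtype=float)
    y = np.asarray(observed, dtype=float)
    if g.size != y.size:
        raise ValueError("length mismatch")
    if g.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((g - y) ** 2)))


def reliability(pev, sigma2_g: float, return_n_clipped: bool = False):
    """REL = 1 - PEV/sigma2_g per individual, clipped to [0, 1]."""
    pev = np.asarray(pev, dtype=float)
    if (pev < 0).any():
        raise ValueError("PEV must be non-negative")
    if sigma2_g <= 0:
        raise ValueError("sigma2_g must be positive")
    raw = 1.0 - pev / sigma2_g
    clipped = np.clip(raw, 0.0, 1.0)
    if return_n_clipped:
        return clipped, int(np.sum((raw < 0) | (raw > 1)))
    return clipped


def make_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of range(n) into n_folds near-equal folds."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n < n_folds:
        raise ValueError("more folds than lines")
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


@dataclass
class CVResult:
    n_folds: int
    n_times: int
    per_replicate: pd.DataFrame       # columns: replicate, pa, rmsep
    gebv_table: pd.DataFrame          # line_id, observed, gebv_mean, gebv_sd, reliability
    summary: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.per_replicate) != self.n_times:
            raise ValueError("one metric row per replicate required")
        if not self.summary:
            self.summary = {
                "pa_mean": float(self.per_replicate["pa"].mean()),
                "pa_sd": float(self.per_replicate["pa"].std(ddof=1)) if self.n_times > 1 else 0.0,
                "rmsep_mean": float(self.per_replicate["rmsep"].mean()),
                "rmsep_sd": float(self.per_replicate["rmsep"].std(ddof=1)) if self.n_times > 1 else 0.0,
            }


def _apply_reduction(geno, pheno, marker_map, reduction: dict, seed: int):
    method = reduction["method"].upper()
    if method == "RMR":
        res = select_random_markers(geno, reduction["k"], seed=seed)
    elif method == "LD":
        res = prune_ld(geno, marker_map, reduction["r2_threshold"], seed=seed)
    elif method == "ANO":
        res = select_anova(geno, pheno, reduction["pval"])
    elif method == "ANO_LD":
        res = select_anova_ld(geno, pheno, marker_map,
                              reduction["pval"], reduction["r2_threshold"], seed=seed)
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    return res.kept_marker_ids


def run_cross_validation(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector,
    method: str = "GBLUP",
    method_params: dict | None = None,
    n_folds: int = 10,
    n_times: int = 100,
    reduction: dict | None = None,
    marker_map=None,
    imputation: str | None = None,
    seed: int = 0,
) -> CVResult:
    """Replicated random k-fold cross-validation of one prediction method.

    Each replicate partitions the lines into ``n_folds`` near-equal
    random folds; each fold is predicted from a model trained on the
    others, the fold GEBV are merged, and predictive ability / RMSEP are
    computed on the merged vector.

    ``reduction`` is a dict such as ``{"method": "ANO", "pval": 1e-3}``
    (optionally ``"honest": False`` to run the leakage-prone variant that
    selects markers once on the full data).  Phenotype-free reductions
    (RMR, LD) are always applied once up front.  ``imputation`` ("MNI" or
    "EMI") is applied up front when the matrix has missing calls.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose one of {METHODS}")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if geno.n_lines < n_folds:
        raise ValueError("more folds than lines")
    method_params = dict(method_params or {})
    y_all = pheno.aligned_to(geno.line_ids)

    if geno.n_missing > 0:
        if imputation is None:
            imputation = "MNI"
        if imputation.upper() == "EMI":
            geno, _ = impute_emi(geno)
        else:
            geno, _ = impute_mni(geno)

    honest = True
    if reduction is not None:
        reduction = dict(reduction)
        honest = bool(reduction.pop("honest", True))
        uses_pheno = reduction["method"].upper() in ("ANO", "ANO_LD")
        if not uses_pheno or not honest:
            kept = _apply_reduction(geno, pheno, marker_map, reduction, seed=seed)
            geno = geno.subset_markers(kept)
            reduction_in_fold = None
        else:
            reduction_in_fold = reduction
    else:
        reduction_in_fold = None

    n = geno.n_lines
    rows = []
    gebv_rep = np.empty((n_times, n))
    rng = np.random.default_rng(seed)
    for rep in range(n_times):
        folds = make_folds(n, n_folds, rng)
        merged = np.empty(n)
        for fold in folds:
            if fold.size < 1 or n - fold.size < 2:
                raise ValueError("fold sizes leave too few training lines")
            train_mask = np.ones(n, dtype=bool)
            train_mask[fold] = False
            train_geno = geno.subset_lines(geno.line_ids[train_mask])
            if reduction_in_fold is not None:
                kept = _apply_reduction(
                    train_geno, pheno, marker_map, reduction_in_fold,
                    seed=int(rng.integers(2**31 - 1)),
                )
                train_geno = train_geno.subset_markers(kept)
            model = fit(method, train_geno, pheno, **method_params)
            target = geno.subset_lines(geno.line_ids[fold])
            if reduction_in_fold is not None:
                target = target.subset_markers(train_geno.marker_ids)
            pred = predict_gebv(model, target)
            merged[fold] = pred["gebv"].to_numpy()
        gebv_rep[rep] = merged
        rows.append({
            "replicate": rep,
            "pa": predictive_ability(merged, y_all),
            "rmsep": rmsep(merged, y_all),
        })

    per_rep = pd.DataFrame(rows)
    gebv_table = pd.DataFrame({
        "line_id": geno.line_ids,
        "observed": y_all,
        "gebv_mean": gebv_rep.mean(axis=0),
        "gebv_sd": gebv_rep.std(axis=0, ddof=1) if n_times > 1 else np.zeros(n),
    })
    # reliability from a final full-data fit, for methods exposing PEV
    rel = np.full(n, np.nan)
    if method in ("GBLUP", "EGBLUP", "BRR", "BL", "BA", "BB", "BC", "RKHS", "MRKHS"):
        try:
            full_model = fit(method, geno, pheno, **method_params)
            if full_model.pev is not None and full_model.sigma2_g and full_model.sigma2_g > 0:
                rel = reliability(full_model.pev, full_model.sigma2_g)
        except (ValueError, FloatingPointError):
            pass
    gebv_table["reliability"] = rel
    return CVResult(n_folds=n_folds, n_times=n_times,
                    per_replicate=per_rep, gebv_table=gebv_table)
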