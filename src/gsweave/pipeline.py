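"""Top-level entry points: cross-validation and target prediction runs.

``run_cv`` mirrors the classical genomic-selection workflow on a
training population (QC -> imputation -> optional marker/training-set
reduction -> replicated cross-validation); ``run_predict`` calibrates
the chosen model on the full training set and scores a target set of
genotyped-only candidates, ranked by GEBV.  Every run writes a
provenance record sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import GenotypeMatrix, PhenotypeVector, qc_filter
from .evaluate import CVResult, run_cross_validation, reliability
from .impute import impute_emi, impute_mni
from .io import read_genotypes, read_map, read_phenotypes
from .predictors import METHODS, fit, predict_gebv
from .reduce import prune_ld, select_anova, select_anova_ld, select_random_markers
from .trainset import optimize_cdmean, sample_random_training
from .core import compute_relationship

__all__ = ["RunConfig", "run_cv", "run_predict"]


@dataclass
class RunConfig:
    """Configuration of a pipeline run; defaults follow the
    fixed-parameter philosophy: MAF 0.05, maxNA 0.20, MNI imputation, no
    reduction, GBLUP, 10-fold x 100-replicate cross-validation."""

    geno: str | None = None
    pheno: str | None = None
    map: str | None = None
    target_geno: str | None = None
    outdir: str | None = None
    maf_min: float = 0.05
    max_missing: float = 0.20
    imputation: str = "MNI"               # MNI | EMI
    reduction: str | None = None          # None | RMR | LD | ANO | ANO_LD
    reduction_params: dict = field(default_factory=dict)
    sampling: str | None = None           # None | RANDOM | OPTI
    sampling_size: int | None = None
    sampling_lambda: float = 1.0
    method: str = "GBLUP"
    method_params: dict = field(default_factory=dict)
    n_folds: int = 10
    n_times: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.method.upper() not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose one of {METHODS}")
        self.method = self.method.upper()
        if self.imputation.upper() not in ("MNI", "EMI"):
            raise ValueError("imputation must be MNI or EMI")
        self.imputation = self.imputation.upper()
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0 <= self.max_missing <= 1:
            raise ValueError("max_missing must be in [0, 1]")
        if self.reduction is not None:
            self.reduction = self.reduction.upper()
            if self.reduction not in ("RMR", "LD", "ANO", "ANO_LD"):
                raise ValueError("reduction must be RMR, LD, ANO or ANO_LD")
        if self.sampling is not None:
            self.sampling = self.sampling.upper()
            if self.sampling not in ("RANDOM", "OPTI"):
                raise ValueError("sampling must be RANDOM or OPTI")
            if self.sampling_size is None:
                raise ValueError("sampling requires sampling_size")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_inputs(config: RunConfig):
    geno = read_genotypes(config.geno)
    pheno = read_phenotypes(config.pheno)
    marker_map = read_map(config.map) if config.map else None
    return geno, pheno, marker_map


def _prepare_training(geno: GenotypeMatrix, pheno: PhenotypeVector, config: RunConfig):
    """QC + imputation + optional training-set sampling; returns the
    prepared matrix, matching phenotypes, and stage-by-stage counts."""
    stages = {"markers_input": geno.n_markers, "lines_input": geno.n_lines}
    shared = np.intersect1d(geno.line_ids, pheno.line_ids)
    if shared.size < geno.n_lines:
        geno = geno.subset_lines(shared)
    stages["lines_phenotyped"] = geno.n_lines

    geno, qc_report = qc_filter(geno, config.maf_min, config.max_missing, return_report=True)
    stages["markers_after_qc"] = geno.n_markers
    stages["markers_dropped_maf"] = qc_report.n_dropped_maf
    stages["markers_dropped_missing"] = qc_report.n_dropped_missing

    if geno.n_missing > 0:
        if config.imputation == "EMI":
            geno, imp = impute_emi(geno)
        else:
            geno, imp = impute_mni(geno)
        stages["imputation"] = dataclasses.asdict(imp)

    if config.sampling is not None:
        if config.sampling == "RANDOM":
            sel = sample_random_training(geno.line_ids, config.sampling_size, seed=config.seed)
        else:
            A = compute_relationship(geno, scaled=False)
            sel = optimize_cdmean(A, config.sampling_size,
                                  lam=config.sampling_lambda, seed=config.seed)
        geno = geno.subset_lines(sel.selected_ids)
        stages["sampling"] = {"method": config.sampling,
                              "size": int(config.sampling_size),
                              "cdmean": sel.cdmean}
    return geno, pheno, stages


def _reduction_spec(config: RunConfig) -> dict | None:
    if config.reduction is None:
        return None
    return {"method": config.reduction, **config.reduction_params}


def _provenance(config: RunConfig, stages: dict) -> dict:
    return {
        "package": "gsweave",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": stages,
    }


def run_cv(
    config: RunConfig,
    geno: GenotypeMatrix | None = None,
    pheno: PhenotypeVector | None = None,
    marker_map=None,
):
    """Cross-validation entry point (QC -> imputation -> reduction ->
    replicated k-fold CV).  Inputs may be passed in memory or read from
    the paths in the config.  Returns (CVResult, provenance dict); when
    ``config.outdir`` is set, metrics, the per-individual GEBV table and
    the provenance JSON are written there.
    """
    if geno is None:
        geno, pheno, marker_map = _load_inputs(config)
    try:
        geno, pheno, stages = _prepare_training(geno, pheno, config)
    except ValueError as err:
        raise ValueError(f"[prepare] {err}") from err
    try:
        result = run_cross_validation(
            geno, pheno,
            method=config.method, method_params=config.method_params,
            n_folds=config.n_folds, n_times=config.n_times,
            reduction=_reduction_spec(config), marker_map=marker_map,
            seed=config.seed,
        )
    except ValueError as err:
        raise ValueError(f"[cross-validation] {err}") from err
    prov = _provenance(config, stages)
    prov["summary"] = result.summary
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        result.per_replicate.to_csv(out / "cv_metrics.csv", index=False)
        result.gebv_table.to_csv(out / "cv_gebv.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
    return result, prov


def run_predict(
    config: RunConfig,
    geno: GenotypeMatrix | None = None,
    pheno: PhenotypeVector | None = None,
    target: GenotypeMatrix | None = None,
    marker_map=None,
):
    """Calibrate on the full training set, score the target set, rank by GEBV.

    QC and marker reduction are computed on the training panel only and
    the surviving marker list is imposed on the targets, so targets
    never influence marker choice.  Returns (ranked GEBV DataFrame,
    provenance dict).
    """
    if geno is None:
        geno, pheno, marker_map = _load_inputs(config)
        if config.target_geno is None:
            raise ValueError("[load] run_predict requires target genotypes")
        target = read_genotypes(config.target_geno)
    if target is None:
        raise ValueError("[load] run_predict requires target genotypes")
    try:
        geno, pheno, stages = _prepare_training(geno, pheno, config)
    except ValueError as err:
        raise ValueError(f"[prepare] {err}") from err

    red = _reduction_spec(config)
    if red is not None:
        red.pop("honest", None)
        method = red.pop("method")
        try:
            if method == "RMR":
                kept = select_random_markers(geno, red["k"], seed=config.seed).kept_marker_ids
            elif method == "LD":
                kept = prune_ld(geno, marker_map, red["r2_threshold"],
                                seed=config.seed).kept_marker_ids
            elif method == "ANO":
                kept = select_anova(geno, pheno, red["pval"]).kept_marker_ids
            else:
                kept = select_anova_ld(geno, pheno, marker_map, red["pval"],
                                       red["r2_threshold"], seed=config.seed).kept_marker_ids
        except (ValueError, KeyError) as err:
            raise ValueError(f"[reduction] {err}") from err
        geno = geno.subset_markers(kept)
        stages["markers_after_reduction"] = geno.n_markers

    missing = sorted(set(geno.marker_ids) - set(target.marker_ids))
    if missing:
        raise ValueError(
            f"[target] target lacks {len(missing)} training markers "
            f"(e.g. {missing[:5]}); panels must match"
        )
    target = target.subset_markers(geno.marker_ids)
    if target.n_missing > 0:
        target = (impute_emi(target)[0] if config.imputation == "EMI"
                  else impute_mni(target)[0])

    try:
        model = fit(config.method, geno, pheno,
                    **{**config.method_params,
                       **({"seed": config.seed}
                          if config.method in ("EGBLUP", "BRR", "BL", "BA", "BB", "BC",
                                               "RKHS", "MRKHS", "RF", "BRNN")
                          and "seed" not in config.method_params else {})})
        table = predict_gebv(model, target)
    except ValueError as err:
        raise ValueError(f"[fit/predict] {err}") from err
    table = table.sort_values("gebv", ascending=False).reset_index(drop=True)
    prov = _provenance(config, stages)
    prov["n_targets"] = int(len(table))
    prov["kept_markers"] = geno.marker_ids.tolist()
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "gebv_ranked.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
    return table, prov

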