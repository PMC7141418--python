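"""Core domain types: genotype matrices, marker maps, phenotypes, kinship.

The package works on biallelic SNP dosages coded 0/1/2 (count of the
non-reference allele).  Missing calls are carried as NaN in the dosage
array together with a boolean mask.  All downstream stages (imputation,
marker reduction, prediction) consume these containers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "MarkerMap",
    "PhenotypeVector",
    "RelationshipMatrix",
    "VarianceComponents",
    "QCReport",
    "qc_filter",
    "compute_relationship",
    "broad_sense_heritability",
]

#: ridge added to kinship diagonals before any inversion downstream
PSD_JITTER = 1e-8


def _as_str_array(ids, name: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=str)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if len(np.unique(arr)) != arr.size:
        dupes = pd.Index(arr)[pd.Index(arr).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {name}: {dupes[:5]}")
    return arr


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage table with a missing-value mask.

    Parameters
    ----------
    line_ids : array-like of str
        Unique identifiers of the individuals (rows).
    marker_ids : array-like of str
        Unique identifiers of the markers (columns).
    dosage : ndarray of shape (n_lines, n_markers)
        Alt-allele dosages; observed entries must be 0, 1 or 2 and
        missing entries are NaN.  Imputed matrices may hold real-valued
        dosages in [0, 2]; set ``validate_integer=False`` for those.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    dosage: np.ndarray
    validate_integer: bool = True

    def __post_init__(self):
        self.line_ids = _as_str_array(self.line_ids, "line_ids")
        self.marker_ids = _as_str_array(self.marker_ids, "marker_ids")
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D array")
        n, m = self.dosage.shape
        if n != self.line_ids.size or m != self.marker_ids.size:
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{self.line_ids.size} lines x {self.marker_ids.size} markers"
            )
        if n < 2:
            raise ValueError("need at least 2 lines")
        if m < 1:
            raise ValueError("need at least 1 marker")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if self.validate_integer and obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))]
            raise ValueError(f"non-integer dosage values present (e.g. {bad[:3]}); expected 0/1/2")

    # -- basic geometry -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_lines, n_markers) array, True where the call is missing."""
        return np.isnan(self.dosage)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    # -- per-marker statistics ------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency p_j = mean(observed dosage)/2 per marker."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency min(p, 1-p) per marker, observed calls only."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    # -- subsetting ------------------------------------------------------
    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        idx = pd.Index(self.marker_ids).get_indexer(np.asarray(marker_ids, dtype=str))
        if (idx < 0).any():
            missing = np.asarray(marker_ids)[idx < 0][:5].tolist()
            raise KeyError(f"markers not present: {missing}")
        return dataclasses.replace(
            self, marker_ids=self.marker_ids[idx], dosage=self.dosage[:, idx]
        )

    def subset_lines(self, line_ids) -> "GenotypeMatrix":
        idx = pd.Index(self.line_ids).get_indexer(np.asarray(line_ids, dtype=str))
        if (idx < 0).any():
            missing = np.asarray(line_ids)[idx < 0][:5].tolist()
            raise KeyError(f"lines not present: {missing}")
        return dataclasses.replace(self, line_ids=self.line_ids[idx], dosage=self.dosage[idx, :])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.line_ids, columns=self.marker_ids)


@dataclass
class MarkerMap:
    """Marker positions: (marker_id, chromosome, position), sorted within chromosome.

    Positions (genetic or physical) are used only as a sorting key for
    chromosome-wise operations such as LD pruning.
    """

    table: pd.DataFrame  # columns: marker_id, chromosome, position

    def __post_init__(self):
        required = ["marker_id", "chromosome", "position"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        t = self.table[required].copy()
        t["marker_id"] = t["marker_id"].astype(str)
        t["chromosome"] = t["chromosome"].astype(str)
        t["position"] = pd.to_numeric(t["position"], errors="raise")
        if t["marker_id"].duplicated().any():
            dupes = t.loc[t["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValueError(f"duplicate marker ids in map: {dupes[:5]}")
        if (t["position"] < 0).any():
            raise ValueError("map positions must be non-negative")
        self.table = t.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    def chromosome_of(self) -> pd.Series:
        return self.table.set_index("marker_id")["chromosome"]

    def position_of(self) -> pd.Series:
        return self.table.set_index("marker_id")["position"]


@dataclass
class PhenotypeVector:
    """Adjusted phenotypic value (BLUE) per line; must be complete (no NA)."""

    values: pd.Series  # index = line_id, float values

    def __post_init__(self):
        s = self.values.copy()
        s.index = s.index.astype(str)
        if s.index.duplicated().any():
            raise ValueError(f"duplicate line ids in phenotypes: "
                             f"{s.index[s.index.duplicated()].tolist()[:5]}")
        s = s.astype(float)
        if s.isna().any():
            raise ValueError("phenotypes must be complete (no NA); "
                             "cross-validation needs an observed value per line")
        if s.empty:
            raise ValueError("empty phenotype vector")
        self.values = s

    @property
    def line_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def aligned_to(self, line_ids) -> np.ndarray:
        """Values reordered to ``line_ids``; raises if any line lacks a phenotype."""
        line_ids = np.asarray(line_ids, dtype=str)
        missing = set(line_ids) - set(self.values.index)
        if missing:
            raise KeyError(f"no phenotype for lines: {sorted(missing)[:5]}")
        return self.values.loc[line_ids].to_numpy()


@dataclass
class RelationshipMatrix:
    """Additive (VanRaden) relationship matrix among lines.

    ``scaled=True`` means each entry was divided by sqrt(A_ii * A_kk), so
    the diagonal is one and off-diagonals read as coancestry coefficients.
    """

    line_ids: np.ndarray
    A: np.ndarray
    scaled: bool = False

    def __post_init__(self):
        self.line_ids = _as_str_array(self.line_ids, "line_ids")
        self.A = np.asarray(self.A, dtype=float)
        n = self.line_ids.size
        if self.A.shape != (n, n):
            raise ValueError(f"A must be {n}x{n}")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric (tol 1e-10)")
        if self.scaled and not np.allclose(np.diag(self.A), 1.0, atol=1e-8):
            raise ValueError("scaled relationship matrix must have unit diagonal")

    @property
    def n_lines(self) -> int:
        return self.line_ids.size

    def subset(self, line_ids) -> "RelationshipMatrix":
        idx = pd.Index(self.line_ids).get_indexer(np.asarray(line_ids, dtype=str))
        if (idx < 0).any():
            raise KeyError("lines not present in relationship matrix")
        return RelationshipMatrix(self.line_ids[idx], self.A[np.ix_(idx, idx)], self.scaled)


@dataclass
class VarianceComponents:
    """Variance components of a multi-environment trial analysis.

    sigma2_g : genotypic variance; sigma2_ge : genotype-by-environment
    variance; sigma2_e : residual (plot) variance; n_env / n_plot :
    average numbers of environments and plots per genotype.
    """

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    n_env: float = 1.0
    n_plot: float = 1.0

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_ge", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_env < 1 or self.n_plot < 1:
            raise ValueError("n_env and n_plot must be >= 1")


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    n_dropped_maf: int
    n_dropped_missing: int


def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.20,
    return_report: bool = False,
):
    """Drop markers with low minor-allele frequency or too many missing calls.

    A marker is removed when its MAF (computed on observed dosages) is
    below ``maf_min`` or when its missing fraction exceeds ``max_missing``.
    Survivor order is preserved.  Applied before imputation.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    maf = geno.maf()
    missf = geno.missing_fraction()
    fail_maf = np.isnan(maf) | (maf < maf_min)
    fail_missing = missf > max_missing
    keep = ~(fail_maf | fail_missing)
    if not keep.any():
        raise ValueError("QC removed every marker; relax maf_min/max_missing")
    out = geno.subset_markers(geno.marker_ids[keep])
    report = QCReport(
        n_input=geno.n_markers,
        n_kept=int(keep.sum()),
        n_dropped_maf=int(fail_maf.sum()),
        n_dropped_missing=int(fail_missing.sum()),
    )
    return (out, report) if return_report else out


def vanraden_design(dosage: np.ndarray):
    """Centred marker matrix W = X - 2p and the VanRaden denominator.

    Returns (W, p, c) with c = 2 * sum_j p_j (1 - p_j).  Frequencies are
    recomputed from the supplied (imputed) matrix at call time.
    """
    p = dosage.mean(axis=0) / 2.0
    W = dosage - 2.0 * p
    c = 2.0 * np.sum(p * (1.0 - p))
    return W, p, c


def compute_relationship(geno: GenotypeMatrix, scaled: bool = False) -> RelationshipMatrix:
    """VanRaden additive relationship matrix A = W W' / (2 sum p(1-p)).

    W centres each marker by twice its allele frequency.  With
    ``scaled=True`` the entry (i, k) is divided by sqrt(A_ii * A_kk),
    putting the matrix on a 0-1 scale with ones on the diagonal.
    """
    if np.isnan(geno.dosage).any():
        raise ValueError("genotypes contain missing values; impute first "
                         "(impute_mni or impute_emi)")
    W, p, c = vanraden_design(geno.dosage)
    if c <= 0:
        raise ValueError("all markers are monomorphic; VanRaden denominator is zero")
    A = (W @ W.T) / c
    A = 0.5 * (A + A.T)
    if scaled:
        d = np.sqrt(np.diag(A))
        if (d <= 0).any():
            raise ValueError("zero diagonal in relationship matrix; cannot scale")
        A = A / np.outer(d, d)
        np.fill_diagonal(A, 1.0)
    return RelationshipMatrix(geno.line_ids.copy(), A, scaled=scaled)


def broad_sense_heritability(vc: VarianceComponents):
    """Broad-sense heritability on a genotype-mean basis and its accuracy bound.

    h2 = sigma2_g / (sigma2_g + sigma2_ge/n_env + sigma2_e/n_plot).  The
    square root of h2 is the theoretical upper limit of the correlation
    between predictions and phenotype (the prediction-accuracy bound).

    Returns
    -------
    (h2, accuracy_bound)
    """
    denom = vc.sigma2_g + vc.sigma2_ge / vc.n_env + vc.sigma2_e / vc.n_plot
    if denom <= 0:
        raise ValueError("total variance must be positive")
    h2 = vc.sigma2_g / denom
    return h2, float(np.sqrt(h2))
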