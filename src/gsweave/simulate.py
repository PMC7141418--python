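"""Synthetic wheat-like inbred populations with LD, QTL and missingness.

The generator uses a founder-mosaic model: a pool of founder haplotypes
is drawn per chromosome, and each inbred line is a Markov mosaic of
founders (switching between founders with a per-marker probability that
plays the role of recombination), doubled to homozygosity so dosages
concentrate on {0, 2}.  Shared founder segments between lines create
both family relatedness and chromosome-level linkage disequilibrium —
the two features genomic prediction feeds on.  A quantitative trait is
built from additive (and optionally pairwise-epistatic) QTL effects with
noise calibrated to a target heritability.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MarkerMap, PhenotypeVector

__all__ = ["SimConfig", "SimTruth", "simulate_population", "mask_genotypes"]


@dataclass
class SimConfig:
    """Configuration of the founder-mosaic simulator.

    Defaults emulate a breeding population of a few hundred related
    inbred lines genotyped on a dense mapped SNP panel: 300 lines, 2000
    markers on 21 chromosomes (bread wheat's count), organised into many
    small biparental families whose parents are drawn from a shared
    elite founder pool — so full sibs are strongly related, half-sib
    families moderately so, and the rest loosely connected through the
    pool.  The trait is moderately polygenic (100 QTL) with heritability
    0.6 on a line-mean basis.
    """

    n_lines: int = 300
    n_markers: int = 2000
    n_chromosomes: int = 21
    n_founders: int = 16
    family_size: int = 4
    recomb_rate: float = 0.02
    n_qtl: int = 100
    h2_target: float = 0.6
    epistasis_fraction: float = 0.0
    residual_het: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if not 0 < self.h2_target <= 1:
            raise ValueError("h2_target must be in (0, 1]")
        if not 0 <= self.epistasis_fraction < 1:
            raise ValueError("epistasis_fraction must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.recomb_rate <= 1:
            raise ValueError("recomb_rate must be in [0, 1]")
        if self.n_chromosomes < 1 or self.n_founders < 2:
            raise ValueError("need >= 1 chromosome and >= 2 founders")
        if self.n_lines < 2 or self.n_markers < 1:
            raise ValueError("need >= 2 lines and >= 1 marker")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")


@dataclass
class SimTruth:
    """Ground truth of a simulated population: QTL architecture, true
    breeding values and the realized heritability."""

    qtl_marker_ids: np.ndarray
    additive_effects: np.ndarray
    epistatic_pairs: np.ndarray       # (k, 2) marker ids
    epistatic_effects: np.ndarray
    tbv: pd.Series                    # true breeding value per line
    realized_h2: float
    noise_sd: float


def _chromosome_sizes(m: int, n_chrom: int) -> np.ndarray:
    sizes = np.full(n_chrom, m // n_chrom)
    sizes[: m % n_chrom] += 1
    return sizes


def simulate_population(config: SimConfig):
    """Generate (GenotypeMatrix, MarkerMap, PhenotypeVector, SimTruth).

    Founder haplotypes are drawn with per-marker allele frequencies
    uniform on (0.1, 0.9).  Lines come in biparental families of
    ``family_size``: each family is assigned a random pair of founders,
    and each inbred line is a two-parent mosaic (Markov switching at
    ``recomb_rate`` per marker step, restarting on each chromosome)
    doubled to homozygosity, up to an optional residual heterozygosity —
    the genome of a recombinant inbred line.  Noise variance is set from
    the realized TBV variance so the phenotype heritability matches
    ``h2_target``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_lines, cfg.n_markers
    sizes = _chromosome_sizes(m, cfg.n_chromosomes)

    marker_ids = np.array([f"M{j + 1:05d}" for j in range(m)])
    line_ids = np.array([f"L{i + 1:04d}" for i in range(n)])
    chroms = np.repeat([f"chr{c + 1}" for c in range(cfg.n_chromosomes)], sizes)
    positions = np.concatenate([np.arange(s, dtype=float) for s in sizes])

    # founder haplotypes, per-chromosome blocks
    freqs = rng.uniform(0.1, 0.9, size=m)
    founders = (rng.random((cfg.n_founders, m)) < freqs).astype(np.int8)

    # biparental families: each line is a mosaic of its two parents
    n_families = int(np.ceil(n / cfg.family_size))
    fam_parents = np.empty((n_families, 2), dtype=np.int64)
    for f in range(n_families):
        fam_parents[f] = rng.choice(cfg.n_founders, size=2, replace=False)
    family_of = np.repeat(np.arange(n_families), cfg.family_size)[:n]

    dosage = np.empty((n, m), dtype=float)
    starts = np.concatenate([[0], np.cumsum(sizes)])
    for c in range(cfg.n_chromosomes):
        lo, hi = starts[c], starts[c + 1]
        width = hi - lo
        switch = rng.random((n, width)) < cfg.recomb_rate
        switch[:, 0] = True
        draws = rng.integers(0, 2, size=(n, width))    # which parent
        idx = np.where(switch, np.arange(width), 0)
        idx = np.maximum.accumulate(idx, axis=1)       # last switch position
        parent_slot = np.take_along_axis(draws, idx, axis=1)
        founder_of = fam_parents[family_of[:, None], parent_slot]
        hap = founders[founder_of, np.arange(lo, hi)[None, :]]
        dosage[:, lo:hi] = 2.0 * hap
    if cfg.residual_het > 0:
        het = rng.random((n, m)) < cfg.residual_het
        dosage[het] = 1.0

    # trait architecture
    qtl_idx = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    add_effects = rng.normal(0.0, 1.0, size=cfg.n_qtl)
    centred = dosage - dosage.mean(axis=0)
    tbv = centred[:, qtl_idx] @ add_effects

    n_epi = int(round(cfg.epistasis_fraction * cfg.n_qtl))
    if n_epi > 0:
        pairs_idx = rng.choice(m, size=(n_epi, 2), replace=True)
        epi_effects = rng.normal(0.0, 1.0, size=n_epi)
        prod = centred[:, pairs_idx[:, 0]] * centred[:, pairs_idx[:, 1]]
        # scale interaction contribution to match the additive variance share
        epi_part = prod @ epi_effects
        sd_add = tbv.std()
        if epi_part.std() > 0 and sd_add > 0:
            target_sd = sd_add * np.sqrt(
                cfg.epistasis_fraction / (1.0 - cfg.epistasis_fraction)
            )
            epi_part *= target_sd / epi_part.std()
        tbv = tbv + epi_part
        epi_pairs = marker_ids[pairs_idx]
    else:
        epi_pairs = np.empty((0, 2), dtype=str)
        epi_effects = np.empty(0)

    var_g = tbv.var()
    if var_g == 0:
        raise ValueError("degenerate trait: zero genetic variance; "
                         "increase n_qtl or marker diversity")
    noise_sd = float(np.sqrt(var_g * (1.0 - cfg.h2_target) / cfg.h2_target))
    pheno_vals = tbv + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else tbv.copy()
    # realized h2: regression R^2 of phenotype on TBV
    r = np.corrcoef(pheno_vals, tbv)[0, 1]
    realized_h2 = float(r**2)

    geno = GenotypeMatrix(line_ids, marker_ids, dosage)
    marker_map = MarkerMap(pd.DataFrame({
        "marker_id": marker_ids, "chromosome": chroms, "position": positions,
    }))
    pheno = PhenotypeVector(pd.Series(pheno_vals, index=line_ids))
    truth = SimTruth(
        qtl_marker_ids=marker_ids[qtl_idx],
        additive_effects=add_effects,
        epistatic_pairs=epi_pairs,
        epistatic_effects=epi_effects,
        tbv=pd.Series(tbv, index=line_ids),
        realized_h2=realized_h2,
        noise_sd=noise_sd,
    )
    if cfg.missing_rate > 0:
        geno = mask_genotypes(geno, cfg.missing_rate, seed=cfg.seed + 1)
    return geno, marker_map, pheno, truth


def mask_genotypes(geno: GenotypeMatrix, missing_rate: float, seed: int = 0) -> GenotypeMatrix:
    """Mask a uniform random fraction of cells (the original is untouched).

    Cells whose removal would leave a marker or a line with no observed
    call are re-drawn (with a warning), so downstream imputation always
    has something to work with.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if missing_rate == 0:
        return dataclasses.replace(geno, dosage=geno.dosage.copy())
    rng = np.random.default_rng(seed)
    n, m = geno.dosage.shape
    mask = rng.random((n, m)) < missing_rate
    mask &= ~geno.missing_mask  # only mask observed cells

    redraws = 0
    for axis, count in ((0, m), (1, n)):
        full = (mask | geno.missing_mask).all(axis=axis)
        if full.any():
            redraws += int(full.sum())
            if axis == 0:
                for j in np.flatnonzero(full):
                    obs = np.flatnonzero(~geno.missing_mask[:, j])
                    keep = obs[rng.integers(obs.size)]
                    mask[keep, j] = False
            else:
                for i in np.flatnonzero(full):
                    obs = np.flatnonzero(~geno.missing_mask[i, :])
                    keep = obs[rng.integers(obs.size)]
                    mask[i, keep] = False
    if redraws:
        warnings.warn(
            f"masking rate {missing_rate} would have emptied {redraws} "
            "marker(s)/line(s); one observed cell protected in each",
            UserWarning,
        )
    dosage = geno.dosage.copy()
    dosage[mask] = np.nan
    return dataclasses.replace(geno, dosage=dosage)
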