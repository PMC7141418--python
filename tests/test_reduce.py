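import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gsweave import (
    GenotypeMatrix,
    MarkerMap,
    PhenotypeVector,
    prune_ld,
    select_anova,
    select_anova_ld,
    select_random_markers,
)
from gsweave.reduce import anova_pvalues, pairwise_r2


def _geno(dosage, marker_ids=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        [f"l{i}" for i in range(n)],
        marker_ids or [f"m{j}" for j in range(m)],
        dosage,
    )


class TestRandomMarkers:
    def test_k_equals_m_keeps_all(self, toy_geno):
        res = select_random_markers(toy_geno, toy_geno.n_markers, seed=0)
        assert set(res.kept_marker_ids) == set(toy_geno.marker_ids)

    def test_seeded_reproducibility(self, toy_geno):
        a = select_random_markers(toy_geno, 1, seed=123)
        b = select_random_markers(toy_geno, 1, seed=123)
        assert list(a.kept_marker_ids) == list(b.kept_marker_ids)

    def test_uniform_inclusion_frequency(self):
        rng = np.random.default_rng(0)
        g = _geno(rng.integers(0, 3, size=(4, 5)))
        counts = {m: 0 for m in g.marker_ids}
        n_draws = 2000
        for s in range(n_draws):
            for m in select_random_markers(g, 2, seed=s).kept_marker_ids:
                counts[m] += 1
        freqs = np.array(list(counts.values())) / n_draws
        np.testing.assert_allclose(freqs, 0.4, atol=0.03)

    def test_k_out_of_range(self, toy_geno):
        with pytest.raises(ValueError):
            select_random_markers(toy_geno, toy_geno.n_markers + 1, seed=0)


def _ld_oracle(dosage, marker_ids, chrom, pos, thr, rng):
    """Exhaustive pairwise application of the pruning rule."""
    order = sorted(range(len(marker_ids)), key=lambda j: (chrom[j], pos[j]))
    alive = {j: True for j in order}
    n_missing = np.isnan(dosage).sum(axis=0)
    for a_i, a in enumerate(order):
        if not alive[a]:
            continue
        for b in order[a_i + 1:]:
            if not alive[b] or chrom[a] != chrom[b]:
                continue
            xa, xb = dosage[:, a], dosage[:, b]
            both = ~np.isnan(xa) & ~np.isnan(xb)
            if both.sum() < 10 or xa[both].std() == 0 or xb[both].std() == 0:
                r2 = 0.0
            else:
                r2 = np.corrcoef(xa[both], xb[both])[0, 1] ** 2
            if r2 > thr:
                if n_missing[a] > n_missing[b]:
                    alive[a] = False
                    break
                elif n_missing[b] > n_missing[a]:
                    alive[b] = False
                else:
                    if rng.random() < 0.5:
                        alive[b] = False
                    else:
                        alive[a] = False
                        break
    return [marker_ids[j] for j in range(len(marker_ids)) if alive[j]]


class TestPruneLD:
    def test_least_missing_member_kept(self):
        col = np.array([0, 2, 1, 0, 2, 1, 0, 2, 1, 0, 2, 1], dtype=float)
        a = col.copy()
        a[0] = np.nan          # marker A has one missing call
        dosage = np.column_stack([a, col])
        g = _geno(dosage, ["A", "B"])
        mp = MarkerMap(pd.DataFrame({
            "marker_id": ["A", "B"], "chromosome": ["1", "1"], "position": [1.0, 2.0],
        }))
        res = prune_ld(g, mp, r2_threshold=0.9)
        assert list(res.kept_marker_ids) == ["B"]

    def test_tied_missingness_keeps_exactly_one(self):
        col = np.array([0, 2, 1, 0, 2, 1, 0, 2, 1, 0], dtype=float)
        g = _geno(np.column_stack([col, col]), ["A", "B"])
        mp = MarkerMap(pd.DataFrame({
            "marker_id": ["A", "B"], "chromosome": ["1", "1"], "position": [1.0, 2.0],
        }))
        kept = {tuple(prune_ld(g, mp, 0.9, seed=s).kept_marker_ids) for s in range(20)}
        assert all(len(k) == 1 for k in kept)
        assert kept == {("A",), ("B",)}  # both outcomes occur across seeds

    def test_matches_exhaustive_oracle(self):
        rng_data = np.random.default_rng(8)
        base = rng_data.integers(0, 3, size=(30, 3)).astype(float)
        # 6 markers on 2 chromosomes, with correlated pairs
        dosage = np.column_stack([
            base[:, 0], base[:, 0], base[:, 1],
            base[:, 2], base[:, 2], rng_data.integers(0, 3, 30),
        ]).astype(float)
        dosage[0, 1] = np.nan
        ids = [f"m{j}" for j in range(6)]
        chrom = ["1", "1", "1", "2", "2", "2"]
        pos = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        g = _geno(dosage, ids)
        mp = MarkerMap(pd.DataFrame({
            "marker_id": ids, "chromosome": chrom, "position": pos,
        }))
        res = prune_ld(g, mp, r2_threshold=0.8, seed=5)
        oracle = _ld_oracle(dosage, ids, chrom, pos, 0.8,
                            np.random.default_rng(5))
        assert sorted(res.kept_marker_ids) == sorted(oracle)

    def test_no_surviving_pair_in_ld(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 3, size=(40, 5)).astype(float)
        dosage = np.column_stack([base, base[:, :3]])  # duplicates
        ids = [f"m{j}" for j in range(8)]
        g = _geno(dosage, ids)
        mp = MarkerMap(pd.DataFrame({
            "marker_id": ids, "chromosome": ["1"] * 8,
            "position": np.arange(8, dtype=float),
        }))
        res = prune_ld(g, mp, 0.5, seed=0)
        survivors = g.subset_markers(res.kept_marker_ids)
        r2 = pairwise_r2(survivors.dosage)
        off = r2[np.triu_indices_from(r2, 1)]
        assert np.all(off <= 0.5)

    def test_single_marker_chromosome_kept(self, toy_geno, toy_map):
        mp = MarkerMap(pd.DataFrame({
            "marker_id": toy_geno.marker_ids,
            "chromosome": ["1", "1", "1", "1", "2"],
            "position": [1.0, 2, 3, 4, 1],
        }))
        res = prune_ld(toy_geno, mp, 0.99)
        assert "M5" in res.kept_marker_ids

    def test_marker_absent_from_map_raises(self, toy_geno):
        mp = MarkerMap(pd.DataFrame({
            "marker_id": ["M1"], "chromosome": ["1"], "position": [1.0],
        }))
        with pytest.raises(KeyError, match="absent"):
            prune_ld(toy_geno, mp, 0.5)


class TestSelectAnova:
    def test_threshold_one_keeps_all(self, small_population):
        geno, _, pheno, _ = small_population
        res = select_anova(geno, pheno, pval=1.0)
        assert list(res.kept_marker_ids) == list(geno.marker_ids)

    def test_perfect_association_always_kept(self):
        dosage = np.tile([0.0, 1.0, 2.0], 4)[:10].reshape(-1, 1)
        dosage = np.column_stack([dosage, np.random.default_rng(0).integers(0, 3, 10)])
        g = _geno(dosage, ["causal", "noise"])
        pheno = PhenotypeVector(pd.Series(3.0 * dosage[:, 0] + 1.0,
                                          index=g.line_ids))
        res = select_anova(g, pheno, pval=1e-8)
        p = res.per_marker_stats.set_index("marker_id")["p_value"]
        assert p["causal"] < 1e-10
        assert "causal" in res.kept_marker_ids

    def test_pvalues_match_first_principles_f_test(self):
        rng = np.random.default_rng(17)
        dosage = rng.integers(0, 3, size=(30, 20)).astype(float)
        y = rng.normal(size=30) + 0.4 * dosage[:, 0]
        p = anova_pvalues(dosage, y)
        n = 30
        for j in range(20):
            x = dosage[:, j]
            # two-parameter least squares from scratch
            X = np.column_stack([np.ones(n), x])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            sse = resid @ resid
            sst = ((y - y.mean()) ** 2).sum()
            F = (sst - sse) / (sse / (n - 2))
            expected = stats.f.sf(F, 1, n - 2)
            assert p[j] == pytest.approx(expected, rel=1e-8)

    def test_zero_variance_marker_never_selected(self):
        dosage = np.column_stack([np.full(10, 2.0),
                                  np.arange(10) % 3]).astype(float)
        g = _geno(dosage, ["flat", "ok"])
        pheno = PhenotypeVector(pd.Series(np.random.default_rng(2).normal(size=10),
                                          index=g.line_ids))
        res = select_anova(g, pheno, pval=0.9999)
        assert "flat" not in res.kept_marker_ids
        stats_p = res.per_marker_stats.set_index("marker_id")
        assert stats_p.loc["flat", "p_value"] == 1.0
        assert bool(stats_p.loc["flat", "zero_variance"])

    def test_threshold_monotone(self, small_population):
        geno, _, pheno, _ = small_population
        kept_small = set(select_anova(geno, pheno, 0.01).kept_marker_ids)
        kept_big = set(select_anova(geno, pheno, 0.2).kept_marker_ids)
        assert kept_small <= kept_big


class TestSelectAnovaLD:
    def test_identity_when_thresholds_are_loose(self, small_population):
        geno, marker_map, pheno, _ = small_population
        res = select_anova_ld(geno, pheno, marker_map, pval=1.0, r2_threshold=1.0)
        assert set(res.kept_marker_ids) == set(geno.marker_ids)

    def test_equals_manual_two_step_composition(self, small_population):
        geno, marker_map, pheno, _ = small_population
        combo = select_anova_ld(geno, pheno, marker_map,
                                pval=0.3, r2_threshold=0.6, seed=9)
        step1 = select_anova(geno, pheno, pval=0.3)
        sub = geno.subset_markers(step1.kept_marker_ids)
        step2 = prune_ld(sub, marker_map, 0.6, seed=9)
        assert list(combo.kept_marker_ids) == list(step2.kept_marker_ids)
        assert set(combo.kept_marker_ids) <= set(step1.kept_marker_ids)

    def test_single_survivor_skips_pruning(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(20, 5)).astype(float)
        g = _geno(dosage)
        y = 5.0 * dosage[:, 2] + rng.normal(scale=0.01, size=20)
        pheno = PhenotypeVector(pd.Series(y, index=g.line_ids))
        mp = MarkerMap(pd.DataFrame({
            "marker_id": g.marker_ids, "chromosome": ["1"] * 5,
            "position": np.arange(5, dtype=float),
        }))
        res = select_anova_ld(g, pheno, mp, pval=1e-12, r2_threshold=0.5)
        assert list(res.kept_marker_ids) == ["m2"]
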