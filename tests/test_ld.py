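"""Two-locus EM, D/D'/r², pruning and LD summaries."""

import numpy as np
import pytest

from capripop.ld import (
    DECAY_BIN_EDGES_KB,
    HaplotypeFreqs,
    LDUndefinedError,
    em_haplotype_freqs,
    ld_decay_table,
    ld_from_freqs,
    ld_prune,
    pairwise_ld,
    per_chromosome_ld,
)
from capripop.simulate import simulate_structured

from conftest import make_dataset


def sample_genotypes_from_haplotypes(rng, hap_freqs, n):
    """Draw n diploids as random unions of two haplotypes; returns dosages."""
    haps = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])
    idx = rng.choice(4, size=(n, 2), p=hap_freqs)
    pair = haps[idx]  # (n, 2, 2)
    return pair[:, :, 0].sum(axis=1), pair[:, :, 1].sum(axis=1)


def grid_loglik_maximizer(g1, g2, step=1e-5):
    """Independent oracle: maximize the 9-cell multinomial likelihood over
    p_ab on a fine grid, margins fixed at the observed allele frequencies."""
    table = np.zeros((3, 3))
    np.add.at(table, (g1, g2), 1.0)
    n = table.sum()
    p_a = (table.sum(axis=1) @ np.arange(3)) / (2 * n)
    p_b = (table.sum(axis=0) @ np.arange(3)) / (2 * n)
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    grid = np.arange(lo, hi + step, step)
    grid = np.clip(grid, lo, hi)
    # haplotype freqs per grid point: (ab, aB, Ab, AB)
    h = np.stack([grid, p_a - grid, p_b - grid, 1.0 - p_a - p_b + grid], axis=1)
    h = np.clip(h, 1e-12, 1.0)
    probs9 = np.einsum("gi,gj->gij", h, h)
    haps = np.array([(1, 1), (1, 0), (0, 1), (0, 0)])  # dosage contribution
    cell = np.zeros((len(grid), 3, 3))
    for i in range(4):
        for j in range(4):
            cell[:, haps[i, 0] + haps[j, 0], haps[i, 1] + haps[j, 1]] += probs9[:, i, j]
    ll = (table[None, :, :] * np.log(np.clip(cell, 1e-300, None))).sum(axis=(1, 2))
    return float(grid[np.argmax(ll)])


class TestEMHaplotypeFreqs:
    def test_no_double_hets_equals_direct_counts(self):
        g1 = np.array([0, 0, 2, 2, 1, 0])
        g2 = np.array([0, 2, 2, 0, 0, 1])  # no sample is het at both loci
        f = em_haplotype_freqs(g1, g2)
        # haplotypes are fully determined; count minor-minor haplotypes by
        # hand: only s3 (2,2) carries them, two copies, out of 2n = 12
        direct_ab = 2 / 12
        assert f.p_ab == pytest.approx(direct_ab, abs=1e-9)
        assert f.p_a == pytest.approx(np.mean(g1) / 2)
        assert f.p_b == pytest.approx(np.mean(g2) / 2)

    def test_identical_columns_give_perfect_coupling(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1])
        f = em_haplotype_freqs(g, g)
        _, dprime, r2 = ld_from_freqs(f)
        assert r2 == pytest.approx(1.0, abs=1e-6)
        assert dprime == pytest.approx(1.0, abs=1e-6)

    def test_independent_loci_large_n(self):
        rng = np.random.default_rng(42)
        g1 = rng.binomial(2, 0.5, size=10_000)
        g2 = rng.binomial(2, 0.5, size=10_000)
        f = em_haplotype_freqs(g1, g2)
        assert f.p_ab == pytest.approx(0.25, abs=0.02)

    def test_too_few_samples_raises(self):
        with pytest.raises(LDUndefinedError):
            em_haplotype_freqs(np.array([1]), np.array([1]))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p_a, p_b = rng.uniform(0.15, 0.85, size=2)
        lo, hi = max(0, p_a + p_b - 1), min(p_a, p_b)
        p_ab = rng.uniform(lo, hi)
        h = np.clip([p_ab, p_a - p_ab, p_b - p_ab, 1 - p_a - p_b + p_ab], 0, 1)
        h = h / h.sum()
        g1, g2 = sample_genotypes_from_haplotypes(rng, h, 300)
        f = em_haplotype_freqs(g1, g2)
        oracle = grid_loglik_maximizer(g1, g2)
        assert f.p_ab == pytest.approx(oracle, abs=1e-4 + 2e-5)

    def test_em_r2_converges_to_haplotypic_r2(self):
        rng = np.random.default_rng(7)
        h = np.array([0.4, 0.1, 0.1, 0.4])  # strong coupling
        p_a = p_b = 0.5
        true_r2 = (h[0] - p_a * p_b) ** 2 / (p_a * (1 - p_a) * p_b * (1 - p_b))
        g1, g2 = sample_genotypes_from_haplotypes(rng, h, 2000)
        _, _, r2 = ld_from_freqs(em_haplotype_freqs(g1, g2))
        assert r2 == pytest.approx(true_r2, abs=0.02)


class TestLDFromFreqs:
    @pytest.mark.parametrize("p_ab,expected", [
        (0.25, (0.0, 0.0, 0.0)),       # independence
        (0.50, (0.25, 1.0, 1.0)),      # perfect coupling
        (0.35, (0.10, 0.4, 0.16)),     # hand-evaluated intermediate
    ])
    def test_symmetric_half_frequencies(self, p_ab, expected):
        f = HaplotypeFreqs(p_ab=p_ab, p_aB=0.5 - p_ab, p_Ab=0.5 - p_ab,
                           p_AB=p_ab, p_a=0.5, p_b=0.5)
        d, dprime, r2 = ld_from_freqs(f)
        assert d == pytest.approx(expected[0], abs=1e-12)
        assert dprime == pytest.approx(expected[1], abs=1e-12)
        assert r2 == pytest.approx(expected[2], abs=1e-12)

    def test_fixed_locus_rejected(self):
        f = HaplotypeFreqs(p_ab=0.0, p_aB=0.0, p_Ab=0.5, p_AB=0.5,
                           p_a=0.0, p_b=0.5)
        with pytest.raises(LDUndefinedError):
            ld_from_freqs(f)


class TestPairwiseInvariant:
    def test_r2_bounded_by_dprime_squared(self):
        ds, _ = simulate_structured(1, 0.5, 40, 120, seed=8)
        pairs = pairwise_ld(ds.sort_by_map(), max_distance_bp=1e12)
        assert len(pairs) > 0
        assert (pairs.r2 <= pairs.D_prime ** 2 + 1e-12).all()


def brute_force_prune(ds, window, step, threshold):
    """Direct re-application of the greedy window rule using scalar EM calls."""
    ds = ds.sort_by_map()
    maf = ds.maf()
    alive = np.ones(ds.n_snps, dtype=bool)
    chrom_groups = {}
    for k, snp in enumerate(ds.snps):
        chrom_groups.setdefault(snp.chromosome, []).append(k)
    for idx in chrom_groups.values():
        for start in range(0, max(len(idx) - 1, 1), step):
            win = [k for k in idx[start:start + window] if alive[k]]
            for a in range(len(win)):
                for b in range(a + 1, len(win)):
                    ka, kb = win[a], win[b]
                    if not (alive[ka] and alive[kb]):
                        continue
                    try:
                        f = em_haplotype_freqs(ds.genotypes[:, ka], ds.genotypes[:, kb])
                        _, _, r2 = ld_from_freqs(f)
                    except LDUndefinedError:
                        continue
                    if r2 > threshold:
                        if maf[ka] < maf[kb]:
                            alive[ka] = False
                        else:
                            alive[kb] = False
    return [ds.snps[k].snp_id for k in np.flatnonzero(alive)]


class TestLDPrune:
    def test_uncorrelated_panel_is_identity(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.5, size=(200, 10)).astype(np.int8)
        ds = make_dataset(g)
        assert ld_prune(ds) == ds.snp_ids

    def test_duplicate_snp_collapsed(self):
        rng = np.random.default_rng(2)
        col = rng.binomial(2, 0.4, size=200).astype(np.int8)
        other = rng.binomial(2, 0.5, size=200).astype(np.int8)
        ds = make_dataset(np.stack([col, col, other], axis=1))
        retained = ld_prune(ds)
        assert sum(sid in retained for sid in ("snp1", "snp2")) == 1
        assert "snp3" in retained

    def test_matches_brute_force_on_correlated_toy(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.5, size=(150, 3)).astype(np.int8)
        cols = [base[:, 0]]
        for k in range(9):  # chain of partially correlated SNPs
            src = cols[-1].copy()
            flip = rng.random(150) < 0.15
            src[flip] = rng.binomial(2, 0.5, size=int(flip.sum()))
            cols.append(src)
        ds = make_dataset(np.stack(cols, axis=1))
        assert ld_prune(ds, 5, 2, 0.2) == brute_force_prune(ds, 5, 2, 0.2)

    def test_retained_set_has_no_violating_window_pair(self):
        ds, _ = simulate_structured(1, 0.5, 60, 60, seed=4)
        from capripop.ld import apply_prune
        pruned = apply_prune(ds, ld_prune(ds))
        assert brute_force_prune(pruned, 50, 5, 0.2) == pruned.snp_ids


class TestDecayTable:
    def test_bin_assignment_half_open(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.5, size=(100, 3)).astype(np.int8)
        ds = make_dataset(g, positions=[1000, 11_000, 16_000])
        # pair distances: 10 000 (10-20kb bin), 15 000 (10-20), 5 000 (0-10)
        table = ld_decay_table(ds, by_population=False)
        counts = dict(zip(table.interval, table.n_pairs))
        assert counts["10-20kb"] == 2
        assert counts["0-10kb"] == 1
        assert counts["20-40kb"] == 0

    def test_unlinked_null_near_one_over_n(self):
        rng = np.random.default_rng(6)
        n = 100
        g = rng.binomial(2, rng.uniform(0.2, 0.5, size=300),
                         size=(n, 300)).astype(np.int8)
        ds = make_dataset(g, positions=[5000 * (k + 1) for k in range(300)])
        table = ld_decay_table(ds, by_population=False)
        filled = table.dropna(subset=["mean_r2"])
        assert (np.abs(filled.mean_r2 - 1.0 / n) < 0.02).all()

    def test_per_population_and_total_rows(self, structured_dataset):
        ds, _ = structured_dataset
        sub = ds.subset_snps(range(40))
        table = ld_decay_table(sub)
        assert set(table.population) == {"pop1", "pop2", "pop3", "Total"}
        assert len(table) == 4 * (len(DECAY_BIN_EDGES_KB) - 1)


class TestPerChromosome:
    def test_adjacent_distance_arithmetic(self):
        rng = np.random.default_rng(9)
        g = rng.binomial(2, 0.5, size=(80, 3)).astype(np.int8)
        ds = make_dataset(g, positions=[1, 50_001, 120_001])
        row = per_chromosome_ld(ds).iloc[0]
        assert row.mean_dist_kb == pytest.approx(60.0)
        assert row.min_dist_kb == pytest.approx(50.0)
        assert row.max_dist_kb == pytest.approx(70.0)

    def test_duplicate_adjacent_pair_enters_averages(self):
        rng = np.random.default_rng(10)
        col = rng.binomial(2, 0.5, size=80).astype(np.int8)
        ds = make_dataset(np.stack([col, col], axis=1), positions=[100, 200])
        row = per_chromosome_ld(ds).iloc[0]
        assert row.mean_r2 == pytest.approx(1.0, abs=1e-9)
        assert row.mean_D_prime == pytest.approx(1.0, abs=1e-9)

    def test_multi_chromosome_table_matches_direct_eval(self):
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.5, size=(60, 6)).astype(np.int8)
        ds = make_dataset(g, chroms=["1", "1", "2", "2", "3", "3"],
                          positions=[10, 2010, 5, 4005, 7, 1007])
        table = per_chromosome_ld(ds)
        assert table.chrom.tolist() == ["1", "2", "3"]
        for i, (a, b) in enumerate([(0, 1), (2, 3), (4, 5)]):
            f = em_haplotype_freqs(g[:, a], g[:, b])
            _, dprime, r2 = ld_from_freqs(f)
            assert table.iloc[i].mean_r2 == pytest.approx(r2, abs=1e-9)
            assert table.iloc[i].mean_D_prime == pytest.approx(dprime, abs=1e-9)

    def test_single_snp_chromosome_counts_only(self):
        rng = np.random.default_rng(12)
        g = rng.binomial(2, 0.5, size=(50, 1)).astype(np.int8)
        ds = make_dataset(g, chroms=["4"])
        row = per_chromosome_ld(ds).iloc[0]
        assert row.n_snps == 1 and np.isnan(row.mean_r2)
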