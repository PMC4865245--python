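"""Two-locus linkage disequilibrium from unphased genotypes.

Haplotype frequencies are estimated per SNP pair by expectation-maximisation
on the 3x3 table of joint dosage counts: every genotype combination except
the double heterozygote determines its two haplotypes, and the double
heterozygote is split between the cis (ab/AB) and trans (aB/Ab)
configurations at each E-step.  From the fitted frequencies the module
computes D, Lewontin's D' and r², prunes markers by windowed pairwise r²,
and builds distance-binned and per-chromosome LD summaries.

Throughout, lowercase a/b denote the dosage-counted (minor, "B") allele at
the first and second locus and capitals the other allele, so ``p_ab`` is the
frequency of the haplotype carrying the minor allele at both loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

#: Inter-SNP distance bin edges in kb for the LD-decay summary (half-open).
DECAY_BIN_EDGES_KB = (0, 10, 20, 40, 60, 100, 200, 500, 1000)

EM_TOL = 1e-10
EM_MAX_ITER = 1000


class LDUndefinedError(ValueError):
    """LD is undefined (fixed locus or too few informative samples)."""


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Two-locus haplotype frequencies and their allele-frequency margins."""

    p_ab: float  # minor at both loci
    p_aB: float  # minor at locus 1 only
    p_Ab: float  # minor at locus 2 only
    p_AB: float  # major at both loci
    p_a: float   # minor allele frequency, locus 1
    p_b: float   # minor allele frequency, locus 2

    def __post_init__(self) -> None:
        total = self.p_ab + self.p_aB + self.p_Ab + self.p_AB
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"haplotype frequencies must sum to 1, got {total}")
        if not np.isclose(self.p_ab + self.p_aB, self.p_a, atol=1e-6):
            raise ValueError("margin p_a inconsistent with haplotype frequencies")
        if not np.isclose(self.p_ab + self.p_Ab, self.p_b, atol=1e-6):
            raise ValueError("margin p_b inconsistent with haplotype frequencies")


# ---------------------------------------------------------------------------
# EM on joint dosage counts
# ---------------------------------------------------------------------------

def _joint_count_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 table n[i, j] = #samples with dosage i at locus 1 and j at locus 2,
    over pairwise-complete samples."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    table = np.zeros((3, 3), dtype=float)
    np.add.at(table, (g1[ok], g2[ok]), 1.0)
    return table


def _em_batch(tables: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
              ) -> np.ndarray:
    """Run the two-locus EM on a batch of 3x3 count tables.

    Parameters
    ----------
    tables : array, shape (npairs, 3, 3)

    Returns
    -------
    freqs : array, shape (npairs, 4) — (p_ab, p_aB, p_Ab, p_AB).
    """
    t = np.asarray(tables, dtype=float)
    n = t.sum(axis=(1, 2))
    two_n = 2.0 * np.maximum(n, 1.0)

    # haplotype counts fixed by unambiguous genotype combinations
    fixed_ab = 2 * t[:, 2, 2] + t[:, 2, 1] + t[:, 1, 2]
    fixed_aB = 2 * t[:, 2, 0] + t[:, 2, 1] + t[:, 1, 0]
    fixed_Ab = 2 * t[:, 0, 2] + t[:, 0, 1] + t[:, 1, 2]
    fixed_AB = 2 * t[:, 0, 0] + t[:, 0, 1] + t[:, 1, 0]
    dh = t[:, 1, 1]  # double heterozygotes: phase-ambiguous

    # margins are fully observed from dosages; EM preserves them
    p_a = (fixed_ab + fixed_aB + dh) / two_n
    p_b = (fixed_ab + fixed_Ab + dh) / two_n

    # initialise at linkage equilibrium
    p = np.empty((t.shape[0], 4))
    p[:, 0] = p_a * p_b
    p[:, 1] = p_a * (1 - p_b)
    p[:, 2] = (1 - p_a) * p_b
    p[:, 3] = (1 - p_a) * (1 - p_b)

    active = np.ones(t.shape[0], dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        cis = p[active, 0] * p[active, 3]
        trans = p[active, 1] * p[active, 2]
        denom = cis + trans
        w = np.where(denom > 0, cis / np.where(denom > 0, denom, 1.0), 0.5)
        d = dh[active]
        new = np.empty_like(p[active])
        new[:, 0] = (fixed_ab[active] + d * w) / two_n[active]
        new[:, 1] = (fixed_aB[active] + d * (1 - w)) / two_n[active]
        new[:, 2] = (fixed_Ab[active] + d * (1 - w)) / two_n[active]
        new[:, 3] = (fixed_AB[active] + d * w) / two_n[active]
        delta = np.abs(new - p[active]).max(axis=1)
        p[active] = new
        still = delta >= tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    return p


def em_haplotype_freqs(g1: np.ndarray, g2: np.ndarray) -> HaplotypeFreqs:
    """Maximum-likelihood two-locus haplotype frequencies for one SNP pair.

    ``g1`` and ``g2`` are dosage vectors over shared samples; samples missing
    either genotype are dropped.  Requires >= 2 informative samples and both
    loci polymorphic in the pairwise-complete subset.
    """
    table = _joint_count_table(np.asarray(g1), np.asarray(g2))
    n = table.sum()
    if n < 2:
        raise LDUndefinedError("fewer than 2 pairwise-complete samples")
    freqs = _em_batch(table[None])[0]
    p_a = freqs[0] + freqs[1]
    p_b = freqs[0] + freqs[2]
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise LDUndefinedError("locus fixed in the pairwise-complete subset")
    return HaplotypeFreqs(p_ab=freqs[0], p_aB=freqs[1], p_Ab=freqs[2],
                          p_AB=freqs[3], p_a=p_a, p_b=p_b)


# ---------------------------------------------------------------------------
# D, D', r2
# ---------------------------------------------------------------------------

def ld_from_freqs(freqs: HaplotypeFreqs) -> tuple[float, float, float]:
    """(D, D', r²) from haplotype frequencies.

    D = p_ab − p_a·p_b; r² = D² / (p_a(1−p_a) p_b(1−p_b));
    D' = |D| / D_max with D_max the tightest frequency bound on |D| given
    the sign of D.
    """
    p_a, p_b = freqs.p_a, freqs.p_b
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise LDUndefinedError("fixed locus: LD undefined")
    d, dprime, r2 = _ld_stats(np.array([freqs.p_ab]), np.array([p_a]), np.array([p_b]))
    return float(d[0]), float(dprime[0]), float(r2[0])


def _ld_stats(p_ab: np.ndarray, p_a: np.ndarray, p_b: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, d * d / denom, np.nan)
        d_max = np.where(d < 0,
                         np.minimum(p_a * p_b, (1 - p_a) * (1 - p_b)),
                         np.minimum(p_a * (1 - p_b), (1 - p_a) * p_b))
        dprime = np.where(d_max > 0, np.abs(d) / d_max, np.nan)
    return d, dprime, np.clip(r2, 0.0, 1.0)


# ---------------------------------------------------------------------------
# all-pairs LD within a distance cap
# ---------------------------------------------------------------------------

def _chromosome_indices(dataset: GenotypeDataset) -> dict[str, np.ndarray]:
    chroms: dict[str, list[int]] = {}
    for k, snp in enumerate(dataset.snps):
        chroms.setdefault(snp.chromosome, []).append(k)
    return {c: np.array(idx) for c, idx in chroms.items()}


def _pair_tables(X: np.ndarray, cols_i: np.ndarray, cols_j: np.ndarray) -> np.ndarray:
    """Joint dosage count tables for pairs (cols_i[t], cols_j[t]) via one-hot
    matrix products; missing genotypes drop out automatically."""
    onehot = [(X == g).astype(np.float64) for g in (0, 1, 2)]
    npairs = len(cols_i)
    tables = np.zeros((npairs, 3, 3))
    for a in range(3):
        Xa = onehot[a][:, cols_i]
        for b in range(3):
            Xb = onehot[b][:, cols_j]
            tables[:, a, b] = np.einsum("st,st->t", Xa, Xb)
    return tables


def pairwise_ld(dataset: GenotypeDataset, max_distance_bp: float = 1e6,
                min_samples: int = 2) -> pd.DataFrame:
    """LD for all same-chromosome SNP pairs closer than ``max_distance_bp``.

    Returns a DataFrame with columns (chrom, snp_i, snp_j, dist_bp, D,
    D_prime, r2).  Pairs where either locus is fixed in the
    pairwise-complete subset, or with fewer than ``min_samples`` informative
    samples, are skipped with a log message.
    """
    ds = dataset.sort_by_map()
    X = ds.genotypes
    pos = np.array([s.position_bp for s in ds.snps], dtype=np.int64)
    records = []
    n_skipped = 0
    for chrom, idx in _chromosome_indices(ds).items():
        p = pos[idx]
        m = len(idx)
        if m < 2:
            continue
        ii, jj = [], []
        hi = np.searchsorted(p, p + max_distance_bp, side="left")
        for a in range(m - 1):
            b = np.arange(a + 1, hi[a])
            ii.append(np.full(len(b), a))
            jj.append(b)
        if not ii:
            continue
        ii = np.concatenate(ii)
        jj = np.concatenate(jj)
        # chunk to bound the one-hot product memory
        for s in range(0, len(ii), 200_000):
            ci, cj = ii[s:s + 200_000], jj[s:s + 200_000]
            tables = _pair_tables(X, idx[ci], idx[cj])
            n = tables.sum(axis=(1, 2))
            freqs = _em_batch(tables)
            p_a = freqs[:, 0] + freqs[:, 1]
            p_b = freqs[:, 0] + freqs[:, 2]
            d, dprime, r2 = _ld_stats(freqs[:, 0], p_a, p_b)
            ok = (n >= min_samples) & (p_a > 0) & (p_a < 1) & (p_b > 0) & (p_b < 1)
            n_skipped += int((~ok).sum())
            records.append(pd.DataFrame({
                "chrom": chrom,
                "snp_i": [ds.snps[idx[a]].snp_id for a in ci[ok]],
                "snp_j": [ds.snps[idx[b]].snp_id for b in cj[ok]],
                "dist_bp": p[cj[ok]] - p[ci[ok]],
                "D": d[ok], "D_prime": dprime[ok], "r2": r2[ok],
            }))
    if n_skipped:
        logger.info("skipped %d pairs with undefined LD", n_skipped)
    if not records:
        return pd.DataFrame(columns=["chrom", "snp_i", "snp_j", "dist_bp",
                                     "D", "D_prime", "r2"])
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(dataset: GenotypeDataset, window_snps: int = 50, step_snps: int = 5,
             r2_threshold: float = 0.2) -> list[str]:
    """Windowed pairwise r² pruning; returns the retained snp_ids.

    Within each ``window_snps``-wide window (per chromosome, map order) any
    pair with r² above the threshold loses one member — the SNP with the
    lower MAF, ties broken by dropping the later map position — then the
    window shifts by ``step_snps``.  The retained set contains no
    within-window pair exceeding the threshold.
    """
    ds = dataset.sort_by_map()
    X = ds.genotypes
    maf = ds.maf()
    alive = np.ones(ds.n_snps, dtype=bool)
    for chrom, idx in _chromosome_indices(ds).items():
        m = len(idx)
        for start in range(0, max(m - 1, 1), step_snps):
            win = idx[start:start + window_snps]
            win = win[alive[win]]
            if len(win) < 2:
                continue
            a, b = np.triu_indices(len(win), k=1)
            tables = _pair_tables(X, win[a], win[b])
            freqs = _em_batch(tables)
            p_a = freqs[:, 0] + freqs[:, 1]
            p_b = freqs[:, 0] + freqs[:, 2]
            _, _, r2 = _ld_stats(freqs[:, 0], p_a, p_b)
            for t in np.lexsort((b, a)):
                if not (r2[t] > r2_threshold):
                    continue
                ka, kb = win[a[t]], win[b[t]]
                if not (alive[ka] and alive[kb]):
                    continue
                if maf[ka] < maf[kb]:
                    drop = ka
                elif maf[kb] < maf[ka]:
                    drop = kb
                else:  # tie: drop the later map position
                    drop = kb
                alive[drop] = False
    return [ds.snps[k].snp_id for k in np.flatnonzero(alive)]


def apply_prune(dataset: GenotypeDataset, retained_ids: list[str]) -> GenotypeDataset:
    """Subset a dataset to the retained snp_ids (original order preserved)."""
    keep = set(retained_ids)
    idx = [k for k, snp in enumerate(dataset.snps) if snp.snp_id in keep]
    return dataset.subset_snps(idx)


# ---------------------------------------------------------------------------
# decay table and per-chromosome summary
# ---------------------------------------------------------------------------

def _bin_labels() -> list[str]:
    e = DECAY_BIN_EDGES_KB
    return [f"{e[i]}-{e[i+1]}kb" for i in range(len(e) - 1)]


def ld_decay_table(dataset: GenotypeDataset, max_distance_bp: float = 1e6,
                   by_population: bool = True) -> pd.DataFrame:
    """Mean r² ± SD per inter-SNP distance interval.

    Intervals are half-open [lo, hi) in kb over the standard chip-analysis
    grid (0-10, 10-20, 20-40, 40-60, 60-100, 100-200, 200-500, 500-1000).
    With ``by_population`` the table is computed separately per population
    label and once on the pooled dataset (labelled ``Total``).  Empty bins
    report count 0 with NaN mean/SD.
    """
    groups: list[tuple[str, GenotypeDataset]] = []
    if by_population:
        for pop in sorted(set(dataset.populations)):
            groups.append((pop, dataset.subset_population(pop)))
    groups.append(("Total", dataset))

    edges_bp = np.array(DECAY_BIN_EDGES_KB, dtype=float) * 1000.0
    labels = _bin_labels()
    rows = []
    for name, ds in groups:
        pairs = pairwise_ld(ds, max_distance_bp=max_distance_bp)
        which = np.digitize(pairs["dist_bp"].to_numpy(), edges_bp, right=False) - 1
        for i, label in enumerate(labels):
            vals = pairs["r2"].to_numpy()[which == i]
            rows.append({
                "population": name,
                "interval": label,
                "n_pairs": len(vals),
                "mean_r2": float(np.mean(vals)) if len(vals) else np.nan,
                "sd_r2": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            })
    return pd.DataFrame(rows)


def per_chromosome_ld(dataset: GenotypeDataset) -> pd.DataFrame:
    """Adjacent-pair LD summary per chromosome.

    For consecutive map-order SNP pairs on each chromosome: mean D', mean
    r², and the mean/min/max adjacent spacing in kb.  Chromosomes with
    fewer than 2 SNPs report counts only.
    """
    ds = dataset.sort_by_map()
    X = ds.genotypes
    pos = np.array([s.position_bp for s in ds.snps], dtype=np.int64)
    rows = []
    for chrom, idx in sorted(_chromosome_indices(ds).items(),
                             key=lambda kv: (kv[0].isdigit() is False, int(kv[0]) if kv[0].isdigit() else 0, kv[0])):
        m = len(idx)
        if m < 2:
            rows.append({"chrom": chrom, "n_snps": m, "mean_D_prime": np.nan,
                         "mean_r2": np.nan, "mean_dist_kb": np.nan,
                         "min_dist_kb": np.nan, "max_dist_kb": np.nan})
            continue
        a = idx[:-1]
        b = idx[1:]
        tables = _pair_tables(X, a, b)
        freqs = _em_batch(tables)
        p_a = freqs[:, 0] + freqs[:, 1]
        p_b = freqs[:, 0] + freqs[:, 2]
        d, dprime, r2 = _ld_stats(freqs[:, 0], p_a, p_b)
        ok = np.isfinite(r2) & np.isfinite(dprime)
        dist_kb = (pos[b] - pos[a]) / 1000.0
        rows.append({
            "chrom": chrom, "n_snps": m,
            "mean_D_prime": float(np.mean(dprime[ok])) if ok.any() else np.nan,
            "mean_r2": float(np.mean(r2[ok])) if ok.any() else np.nan,
            "mean_dist_kb": float(np.mean(dist_kb)),
            "min_dist_kb": float(np.min(dist_kb)),
            "max_dist_kb": float(np.max(dist_kb)),
        })
    return pd.DataFrame(rows)
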