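"""Heterozygosity, individual inbreeding and method-of-moments relatedness.

Expected heterozygosity is the plug-in 2p(1-p) per SNP (a 2n/(2n-1)
small-sample correction is available but off by default).  The inbreeding
coefficient f and the pairwise IBD proportions (Z0, Z1, Z2, PI_HAT) are the
classic method-of-moments estimators computed from identity-by-state counts
against the allele frequencies of the analysed cohort, or against
externally supplied frequencies when the truth is known (e.g. simulations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

#: Pairs with fewer overlapping SNPs than this are flagged low-confidence.
MIN_OVERLAP_SNPS = 100


@dataclass(frozen=True)
class DiversitySummary:
    """Dataset-level averages of MAF, expected/observed heterozygosity and f."""

    average_maf: float
    mean_he: float
    mean_ho: float
    mean_f: float


def het_stats(dataset: GenotypeDataset, unbiased: bool = False
              ) -> tuple[pd.DataFrame, float, float]:
    """Per-SNP observed and expected heterozygosity, plus the dataset means.

    Ho is the heterozygote fraction among non-missing calls; He = 2p(1-p)
    with p the sample allele frequency (Nei's unbiased 2n/(2n-1) factor
    applied when ``unbiased``).  Returns (per-SNP frame, mean_He, mean_Ho),
    means taken over SNPs.
    """
    if dataset.n_samples < 2:
        raise ValueError("heterozygosity needs at least 2 samples")
    g = dataset.genotypes
    nonmiss = (g != MISSING).sum(axis=0)
    het = (g == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)
    p = dataset.allele_freq_b()
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        two_n = 2.0 * nonmiss
        he = np.where(two_n > 1, he * two_n / np.maximum(two_n - 1, 1), he)
    frame = pd.DataFrame({
        "snp_id": dataset.snp_ids, "p_b": p, "He": he, "Ho": ho,
        "n_called": nonmiss,
    })
    return frame, float(np.nanmean(he)), float(np.nanmean(ho))


def individual_inbreeding(dataset: GenotypeDataset,
                          freqs: np.ndarray | None = None) -> np.ndarray:
    """Method-of-moments inbreeding coefficient per individual.

    f = (O_hom - E_hom) / (L - E_hom) over the individual's non-missing
    SNPs, with E_hom = sum(1 - 2 p_k (1 - p_k)).  ``freqs`` overrides the
    cohort allele frequencies (B-allele frequency per SNP).
    """
    p = dataset.allele_freq_b() if freqs is None else np.asarray(freqs, dtype=float)
    g = dataset.genotypes
    nonmiss = g != MISSING
    hom = (g == 0) | (g == 2)
    two_pq = 2.0 * p * (1.0 - p)
    o_hom = (hom & nonmiss).sum(axis=1).astype(float)
    e_hom = (nonmiss * (1.0 - two_pq)).sum(axis=1)
    length = nonmiss.sum(axis=1).astype(float)
    denom = length - e_hom
    if np.any(denom <= 0):
        raise ValueError("inbreeding undefined: all informative SNPs fixed "
                         "for some individual")
    return (o_hom - e_hom) / denom


# ---------------------------------------------------------------------------
# pairwise IBD (PI_HAT)
# ---------------------------------------------------------------------------

def _ibs_expectations(p: np.ndarray) -> np.ndarray:
    """Per-SNP P(IBS=i | IBD=z) for the 3x3 (ibs, ibd) grid, summed later.

    Rows i = IBS state 0/1/2, columns z = IBD state 0/1/2; entries are
    polynomial in the allele frequency p under Hardy-Weinberg genotypes.
    Shape (len(p), 3, 3).
    """
    q = 1.0 - p
    e = np.zeros((len(p), 3, 3))
    e[:, 0, 0] = 2.0 * p**2 * q**2
    e[:, 1, 0] = 4.0 * p**3 * q + 4.0 * p * q**3
    e[:, 2, 0] = p**4 + q**4 + 4.0 * p**2 * q**2
    e[:, 1, 1] = 2.0 * p**2 * q + 2.0 * p * q**2
    e[:, 2, 1] = p**3 + q**3 + p**2 * q + p * q**2
    e[:, 2, 2] = 1.0
    return e


def _solve_ibd(n_ibs: np.ndarray, exp_sums: np.ndarray) -> np.ndarray:
    """Invert summed IBS expectations to (Z0, Z1, Z2); truncate to [0, 1]
    and renormalise (the standard method-of-moments repair — note this
    biases PI_HAT slightly upward near 0)."""
    z0 = n_ibs[0] / exp_sums[0, 0] if exp_sums[0, 0] > 0 else 0.0
    z1 = ((n_ibs[1] - z0 * exp_sums[1, 0]) / exp_sums[1, 1]
          if exp_sums[1, 1] > 0 else 0.0)
    z2 = ((n_ibs[2] - z0 * exp_sums[2, 0] - z1 * exp_sums[2, 1]) / exp_sums[2, 2]
          if exp_sums[2, 2] > 0 else 0.0)
    z = np.clip(np.array([z0, z1, z2]), 0.0, 1.0)
    s = z.sum()
    return z / s if s > 0 else np.array([1.0, 0.0, 0.0])


def pairwise_pihat(dataset: GenotypeDataset,
                   freqs: np.ndarray | None = None,
                   pairs: list[tuple[int, int]] | None = None) -> pd.DataFrame:
    """Method-of-moments IBD estimates for sample pairs.

    For each pair, identity-by-state counts over overlapping non-missing
    SNPs are equated with their expectations given the IBD state
    probabilities and solved for (Z0, Z1, Z2); PI_HAT = Z1/2 + Z2.

    ``freqs`` supplies the B-allele frequency per SNP (defaults to the
    cohort frequencies); ``pairs`` restricts the computation to the listed
    sample-index pairs (default: all pairs).  Pairs with fewer than
    ``MIN_OVERLAP_SNPS`` overlapping SNPs are flagged ``low_confidence``.
    """
    p = dataset.allele_freq_b() if freqs is None else np.asarray(freqs, dtype=float)
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    g = dataset.genotypes
    n = dataset.n_samples
    if pairs is None:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    e = _ibs_expectations(p[usable])

    rows = []
    gu = g[:, usable]
    for i, j in pairs:
        gi, gj = gu[i], gu[j]
        ok = (gi != MISSING) & (gj != MISSING)
        ibs = 2 - np.abs(gi[ok] - gj[ok])
        n_ibs = np.array([(ibs == 0).sum(), (ibs == 1).sum(), (ibs == 2).sum()],
                         dtype=float)
        exp_sums = e[ok].sum(axis=0)  # (ibs, ibd)
        z = _solve_ibd(n_ibs, exp_sums)
        rows.append({
            "id1": dataset.samples[i].sample_id,
            "id2": dataset.samples[j].sample_id,
            "Z0": z[0], "Z1": z[1], "Z2": z[2],
            "PI_HAT": z[1] / 2.0 + z[2],
            "n_snps": int(ok.sum()),
            "low_confidence": bool(ok.sum() < MIN_OVERLAP_SNPS),
        })
    if any(r["low_confidence"] for r in rows):
        warnings.warn("some pairs have <100 overlapping SNPs; their IBD "
                      "estimates are low-confidence", stacklevel=2)
    return pd.DataFrame(rows)


def diversity_summary(dataset: GenotypeDataset) -> DiversitySummary:
    """Convenience bundle: average MAF, mean He/Ho and mean f for a cohort."""
    _, mean_he, mean_ho = het_stats(dataset)
    f = individual_inbreeding(dataset)
    maf = dataset.maf()
    return DiversitySummary(
        average_maf=float(np.nanmean(maf)),
        mean_he=mean_he,
        mean_ho=mean_ho,
        mean_f=float(np.mean(f)),
    )
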