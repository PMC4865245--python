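"""Sample- and marker-based quality control for SNP-array genotype panels.

The cascade mirrors standard chip QC practice: drop samples with call rate
below threshold first, then drop SNPs failing (in order) marker call rate,
minor allele frequency, and an exact Hardy-Weinberg test.  Each SNP failure
is attributed to the first criterion it fails, so the per-criterion counts
partition the removed markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeDataset


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the QC cascade (all fractions in [0, 1]).

    Samples with call rate strictly below ``sample_call_threshold`` are
    removed; likewise SNPs below ``snp_call_threshold`` or with
    MAF < ``maf_threshold`` or HWE exact p < ``hwe_p_threshold``.
    """

    sample_call_threshold: float = 0.95
    snp_call_threshold: float = 0.95
    maf_threshold: float = 0.05
    hwe_p_threshold: float = 0.001

    def __post_init__(self) -> None:
        for name in ("sample_call_threshold", "snp_call_threshold",
                     "maf_threshold", "hwe_p_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class QCReport:
    """Per-criterion exclusion counts; percentages are of the pre-QC panel."""

    n_samples_in: int
    n_samples_removed: int
    n_snps_in: int
    n_snps_failed_call: int
    n_snps_failed_maf: int
    n_polymorphic: int
    n_snps_failed_hwe: int
    n_snps_remaining: int

    @property
    def pct_polymorphic(self) -> float:
        return 100.0 * self.n_polymorphic / self.n_snps_in if self.n_snps_in else 0.0

    @property
    def pct_remaining(self) -> float:
        return 100.0 * self.n_snps_remaining / self.n_snps_in if self.n_snps_in else 0.0

    def to_table_row(self, label: str) -> str:
        return "\t".join([
            label,
            str(self.n_snps_failed_call),
            str(self.n_snps_failed_maf),
            f"{self.n_polymorphic} ({self.pct_polymorphic:.1f})",
            str(self.n_snps_failed_hwe),
            f"{self.n_snps_remaining} ({self.pct_remaining:.1f})",
        ])


TABLE_HEADER = "\t".join([
    "Population", "SNP call rate<95%", "MAF<5%", "Polymorphic loci (%)",
    "HWE (p<0.001)", "SNPs remaining (%)",
])


def sample_call_rates(dataset: GenotypeDataset) -> np.ndarray:
    """Fraction of non-missing genotypes per sample."""
    if dataset.n_snps == 0:
        raise ValueError("call rate undefined for a dataset with no SNPs")
    return 1.0 - (dataset.genotypes == MISSING).mean(axis=1)


def snp_call_rates(dataset: GenotypeDataset) -> np.ndarray:
    """Fraction of non-missing genotypes per SNP."""
    if dataset.n_samples == 0:
        raise ValueError("call rate undefined for a dataset with no samples")
    return 1.0 - (dataset.genotypes == MISSING).mean(axis=0)


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities of outcomes no more probable than the observed
    one under the conditional (given allele counts) distribution.  No mid-p
    adjustment.  Monomorphic loci return 1 by convention.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    # heterozygote count has the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het | allele counts) up to a constant:
    # n! / (n_AA! n_AB! n_BB!) * 2^n_AB  with n_AA,n_BB determined by n_het
    n_aa_all = (n_a - hets) // 2
    n_bb_all = (n_b - hets) // 2
    logp = (hets * np.log(2.0)
            - gammaln(n_aa_all + 1) - gammaln(hets + 1) - gammaln(n_bb_all + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_ab][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def genotype_counts(dataset: GenotypeDataset) -> np.ndarray:
    """Per-SNP (n_AA, n_AB, n_BB) counts, shape (n_snps, 3)."""
    g = dataset.genotypes
    return np.stack([(g == 0).sum(axis=0), (g == 1).sum(axis=0), (g == 2).sum(axis=0)], axis=1)


def run_qc(dataset: GenotypeDataset, config: QCConfig | None = None
           ) -> tuple[GenotypeDataset, QCReport]:
    """Apply the QC cascade and report per-criterion exclusion counts.

    Order: sample call rate, then per-SNP call rate, MAF, HWE — each stage
    evaluated on the dataset surviving the previous one.  Raises if nothing
    survives, since downstream analyses need at least 2 samples and 2 SNPs.
    """
    config = config or QCConfig()
    n_snps_in = dataset.n_snps
    n_samples_in = dataset.n_samples

    rates = sample_call_rates(dataset)
    keep_samples = np.flatnonzero(rates >= config.sample_call_threshold)
    ds = dataset.subset_samples(keep_samples)
    n_samples_removed = n_samples_in - ds.n_samples
    if ds.n_samples == 0:
        raise ValueError("no samples survive the call-rate filter")

    call = snp_call_rates(ds)
    fail_call = call < config.snp_call_threshold

    maf = ds.maf()
    fail_maf = ~fail_call & (np.isnan(maf) | (maf < config.maf_threshold))
    polymorphic = ~fail_call & ~np.isnan(maf) & (maf > 0)

    counts = genotype_counts(ds)
    fail_hwe = np.zeros(ds.n_snps, dtype=bool)
    for k in np.flatnonzero(~fail_call & ~fail_maf):
        p = hwe_exact_p(*counts[k])
        fail_hwe[k] = p < config.hwe_p_threshold

    keep = ~(fail_call | fail_maf | fail_hwe)
    out = ds.subset_snps(np.flatnonzero(keep))
    if out.n_snps == 0:
        raise ValueError("no SNPs survive QC")

    report = QCReport(
        n_samples_in=n_samples_in,
        n_samples_removed=n_samples_removed,
        n_snps_in=n_snps_in,
        n_snps_failed_call=int(fail_call.sum()),
        n_snps_failed_maf=int(fail_maf.sum()),
        n_polymorphic=int(polymorphic.sum()),
        n_snps_failed_hwe=int(fail_hwe.sum()),
        n_snps_remaining=out.n_snps,
    )
    return out, report


def panel_accounting(n_total: int, n_removed: int) -> int:
    """Markers (or samples) remaining after a filtering step removes
    ``n_removed`` of ``n_total``; validates the bookkeeping."""
    if n_removed < 0 or n_removed > n_total:
        raise ValueError("removed count must be between 0 and the panel size")
    return n_total - n_removed
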