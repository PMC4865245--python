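"""Read, write, merge and subset diploid biallelic genotype panels in PED/MAP text format.

The in-memory model is a :class:`GenotypeDataset`: a samples × SNPs matrix of
B-allele dosages (0/1/2, ``MISSING`` = -1) together with a SNP map (chromosome,
bp position, A/B alleles) and per-sample population labels.  Per SNP the
(A, B) alleles are assigned as (major, minor) by observed frequency with a
lexicographic tie-break, so dosage 2 is the minor-allele homozygote and the
minor allele frequency equals ``mean(dosage) / 2`` in the coding population.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

#: Autosome labels for the goat genome (CHI 1..29).
AUTOSOMES = frozenset(str(i) for i in range(1, 30))

_VALID_ALLELES = frozenset("ACGT")


class PedMapError(ValueError):
    """Malformed or inconsistent PED/MAP content."""


@dataclass(frozen=True)
class SNPRecord:
    """One marker: id, chromosome label, bp position and its A/B alleles."""

    snp_id: str
    chromosome: str
    position_bp: int
    allele_a: str
    allele_b: str


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual and its population label."""

    sample_id: str
    population: str


@dataclass
class GenotypeDataset:
    """Diploid biallelic genotype matrix plus marker map and sample metadata.

    ``genotypes[i, k]`` is the count of ``snps[k].allele_b`` carried by
    ``samples[i]`` (0, 1, 2) or :data:`MISSING`.
    """

    samples: list[SampleRecord]
    snps: list[SNPRecord]
    genotypes: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or MISSING")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def populations(self) -> list[str]:
        return [s.population for s in self.samples]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def allele_freq_b(self) -> np.ndarray:
        """Per-SNP frequency of the B allele among non-missing calls (NaN if none)."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-missing column -> NaN
            return np.asarray(g.mean(axis=0).filled(np.nan), dtype=float) / 2.0

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency (NaN where no calls)."""
        p = self.allele_freq_b()
        return np.minimum(p, 1.0 - p)

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index, dtype=int)
        return GenotypeDataset(
            samples=[self.samples[i] for i in index],
            snps=list(self.snps),
            genotypes=self.genotypes[index, :].copy(),
        )

    def subset_snps(self, index: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index, dtype=int)
        return GenotypeDataset(
            samples=list(self.samples),
            snps=[self.snps[i] for i in index],
            genotypes=self.genotypes[:, index].copy(),
        )

    def subset_population(self, population: str) -> "GenotypeDataset":
        idx = [i for i, s in enumerate(self.samples) if s.population == population]
        return self.subset_samples(idx)

    def sort_by_map(self) -> "GenotypeDataset":
        """Order SNPs by (numeric-aware chromosome, bp position)."""
        order = sorted(
            range(self.n_snps),
            key=lambda k: (_chrom_key(self.snps[k].chromosome), self.snps[k].position_bp),
        )
        return self.subset_snps(order)


def _chrom_key(label: str) -> tuple[int, str]:
    return (int(label), "") if label.isdigit() else (10**6, label)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path) -> GenotypeDataset:
    """Parse a PLINK text PED/MAP pair into a :class:`GenotypeDataset`.

    The MAP file supplies (chromosome, snp_id, cM, bp) per line; the genetic
    position column is read and ignored, physical bp drives all distances.
    The PED family-ID column becomes the population label.  ``0`` allele
    tokens are missing; a half-called genotype ("A 0") is treated as missing
    with a warning.
    """
    map_rows: list[tuple[str, str, int]] = []
    with _open_text(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise PedMapError(f"{map_path}: line {lineno}: expected 4 columns, got {len(fields)}")
            chrom, snp_id, _cm, bp = fields[0], fields[1], fields[2], fields[3]
            map_rows.append((chrom, snp_id, int(bp)))
    n_snps = len(map_rows)
    ids = [r[1] for r in map_rows]
    if len(set(ids)) != n_snps:
        raise PedMapError(f"{map_path}: duplicate snp_ids")

    sample_records: list[SampleRecord] = []
    allele1_rows: list[np.ndarray] = []
    allele2_rows: list[np.ndarray] = []
    with _open_text(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            expected = 6 + 2 * n_snps
            if len(fields) != expected:
                raise PedMapError(
                    f"{ped_path}: line {lineno}: expected {expected} columns "
                    f"(6 + 2x{n_snps} SNPs), got {len(fields)}"
                )
            fid, iid = fields[0], fields[1]
            sample_records.append(SampleRecord(sample_id=iid, population=fid))
            alleles = fields[6:]
            a1 = np.array(alleles[0::2], dtype="U1")
            a2 = np.array(alleles[1::2], dtype="U1")
            bad = ~(np.isin(a1, list(_VALID_ALLELES) + ["0"]) & np.isin(a2, list(_VALID_ALLELES) + ["0"]))
            if bad.any():
                k = int(np.flatnonzero(bad)[0])
                raise PedMapError(
                    f"{ped_path}: line {lineno}: invalid allele token at SNP {ids[k]}"
                )
            half = (a1 == "0") ^ (a2 == "0")
            if half.any():
                logger.warning(
                    "%s: line %d: %d half-missing genotypes treated as MISSING",
                    ped_path, lineno, int(half.sum()),
                )
                a1[half] = "0"
                a2[half] = "0"
            allele1_rows.append(a1)
            allele2_rows.append(a2)

    n_samples = len(sample_records)
    if n_samples == 0:
        a1m = np.empty((0, n_snps), dtype="U1")
        a2m = np.empty((0, n_snps), dtype="U1")
    else:
        a1m = np.vstack(allele1_rows)
        a2m = np.vstack(allele2_rows)

    snps: list[SNPRecord] = []
    genotypes = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    for k, (chrom, snp_id, bp) in enumerate(map_rows):
        col = np.concatenate([a1m[:, k], a2m[:, k]])
        observed = col[col != "0"]
        counts = {a: int(np.sum(observed == a)) for a in set(observed.tolist())}
        if len(counts) > 2:
            raise PedMapError(f"SNP {snp_id}: more than 2 distinct alleles observed: {sorted(counts)}")
        major, minor = _assign_major_minor(counts)
        snps.append(SNPRecord(snp_id=snp_id, chromosome=chrom, position_bp=bp,
                              allele_a=major, allele_b=minor))
        if n_samples:
            nonmiss = a1m[:, k] != "0"
            dosage = (a1m[:, k] == minor).astype(np.int8) + (a2m[:, k] == minor).astype(np.int8)
            genotypes[nonmiss, k] = dosage[nonmiss]

    return GenotypeDataset(samples=sample_records, snps=snps, genotypes=genotypes)


def _assign_major_minor(counts: dict[str, int]) -> tuple[str, str]:
    """(major, minor) by observed count; lexicographic tie-break; monomorphic
    or unobserved loci get a placeholder complement as the B allele."""
    if not counts:
        return "A", "C"
    alleles = sorted(counts, key=lambda a: (-counts[a], a))
    if len(alleles) == 1:
        other = "G" if alleles[0] == "A" else "A"
        return alleles[0], other
    return alleles[0], alleles[1]


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_ped_map(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """Write a dataset as a PED/MAP pair; read ∘ write round-trips exactly."""
    with _open_text(map_path, "wt") as fh:
        for snp in dataset.snps:
            fh.write(f"{snp.chromosome}\t{snp.snp_id}\t0\t{snp.position_bp}\n")
    with _open_text(ped_path, "wt") as fh:
        for i, sample in enumerate(dataset.samples):
            tokens = [sample.population, sample.sample_id, "0", "0", "0", "-9"]
            row = dataset.genotypes[i]
            for k, snp in enumerate(dataset.snps):
                g = row[k]
                if g == MISSING:
                    tokens += ["0", "0"]
                elif g == 0:
                    tokens += [snp.allele_a, snp.allele_a]
                elif g == 1:
                    tokens += [snp.allele_a, snp.allele_b]
                else:
                    tokens += [snp.allele_b, snp.allele_b]
            fh.write(" ".join(tokens) + "\n")


# ---------------------------------------------------------------------------
# merging and subsetting
# ---------------------------------------------------------------------------

def merge_datasets(datasets: Sequence[GenotypeDataset]) -> GenotypeDataset:
    """Merge cohorts genotyped on the same chip into one dataset.

    Keeps the intersection of snp_ids, anchors A/B assignment to the first
    dataset (flipping dosages x -> 2-x where a later cohort assigned the
    alleles the other way round) and concatenates samples.  Allele sets that
    disagree even after an A/B swap are an error: no strand flipping is
    attempted, since same-chip cohorts share strand by construction.
    """
    if len(datasets) < 2:
        raise ValueError("merge requires at least 2 datasets")
    all_ids = [set(d.snp_ids) for d in datasets]
    shared = set.intersection(*all_ids)
    sample_ids = [sid for d in datasets for sid in d.sample_ids]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("merge requires disjoint sample_ids across datasets")

    first = datasets[0]
    keep = [k for k, sid in enumerate(first.snp_ids) if sid in shared]
    anchor = first.subset_snps(keep)
    anchor_index = {snp.snp_id: j for j, snp in enumerate(anchor.snps)}

    blocks = [anchor.genotypes]
    samples = list(anchor.samples)
    incompatible: list[str] = []
    for d in datasets[1:]:
        idx = {snp.snp_id: k for k, snp in enumerate(d.snps)}
        cols = np.full((d.n_samples, anchor.n_snps), MISSING, dtype=np.int8)
        for snp_id, j in anchor_index.items():
            k = idx[snp_id]
            ref, other = anchor.snps[j], d.snps[k]
            col = d.genotypes[:, k]
            if (other.allele_a, other.allele_b) == (ref.allele_a, ref.allele_b):
                cols[:, j] = col
            elif (other.allele_b, other.allele_a) == (ref.allele_a, ref.allele_b):
                flipped = col.copy()
                nonmiss = flipped != MISSING
                flipped[nonmiss] = 2 - flipped[nonmiss]
                cols[:, j] = flipped
            elif _alleles_reconcilable(ref, other, anchor.genotypes[:, j], col):
                cols[:, j] = _reconcile(ref, other, col)
            else:
                incompatible.append(snp_id)
        if incompatible:
            raise ValueError(
                "incompatible allele sets at shared SNPs (no strand flipping "
                f"attempted): {sorted(incompatible)[:10]}"
            )
        blocks.append(cols)
        samples.extend(d.samples)

    return GenotypeDataset(samples=samples, snps=list(anchor.snps),
                           genotypes=np.vstack(blocks))


def _alleles_reconcilable(ref: SNPRecord, other: SNPRecord,
                          ref_col: np.ndarray, other_col: np.ndarray) -> bool:
    """A cohort monomorphic at a SNP may carry a placeholder B allele; it is
    compatible when its observed alleles are a subset of the reference pair."""
    observed = set()
    if np.any((other_col == 0) | (other_col == 1)):
        observed.add(other.allele_a)
    if np.any((other_col == 1) | (other_col == 2)):
        observed.add(other.allele_b)
    return observed <= {ref.allele_a, ref.allele_b}


def _reconcile(ref: SNPRecord, other: SNPRecord, col: np.ndarray) -> np.ndarray:
    out = col.copy()
    nonmiss = out != MISSING
    if other.allele_a == ref.allele_b:
        out[nonmiss] = 2 - out[nonmiss]
    return out


def canonicalize_coding(dataset: GenotypeDataset) -> GenotypeDataset:
    """Flip dosage columns (and swap A/B) so allele_b is the minor allele.

    Restores the (major, minor) coding convention after operations that can
    change observed allele frequencies (e.g. masking genotypes), so that a
    PED/MAP write-read round-trip reproduces the codes exactly.  Ties at
    frequency 0.5 keep the lexicographically smaller allele as allele_a.
    """
    g = dataset.genotypes.copy()
    snps = list(dataset.snps)
    freq = dataset.allele_freq_b()
    for k, snp in enumerate(snps):
        f = freq[k]
        flip = (np.isfinite(f) and f > 0.5) or (
            f == 0.5 and snp.allele_b < snp.allele_a)
        if flip:
            col = g[:, k]
            nonmiss = col != MISSING
            col[nonmiss] = 2 - col[nonmiss]
            snps[k] = replace(snp, allele_a=snp.allele_b, allele_b=snp.allele_a)
    return GenotypeDataset(samples=list(dataset.samples), snps=snps, genotypes=g)


def subset_autosomes(dataset: GenotypeDataset) -> GenotypeDataset:
    """Keep SNPs on autosomes 1..29 (the goat karyotype), dropping X and
    unplaced markers."""
    keep = [k for k, snp in enumerate(dataset.snps) if snp.chromosome in AUTOSOMES]
    return dataset.subset_snps(keep)
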