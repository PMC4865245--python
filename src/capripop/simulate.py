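"""Genotype simulators with recorded truth for estimator validation.

The study's genotype data are not publicly deposited, so every estimator in
the package is validated against simulations with known parameters instead:

* :func:`simulate_wright_fisher` — forward-in-time constant-size random
  mating with Poisson recombination on a linear genetic map; known Ne.
* :func:`simulate_structured` — Balding-Nichols drift-differentiated
  populations with known FST.
* :func:`simulate_pedigree` — gene-dropping through minimal pedigrees with
  known expected kinship (parent-offspring ... first-cousin).
* :func:`simulate_admixed` — individuals with known ancestry fractions Q.
* :func:`inject_missingness` — cell-level missingness for exercising QC.

Every simulator is a pure function of its seed, returns a
(:class:`~capripop.genotype_io.GenotypeDataset`, :class:`SimTruth`) pair,
and produces datasets whose A/B allele coding already follows the
(major, minor) convention so PED/MAP round-trips are exact.  Founder and
initial allele frequencies default to a chip-like spectrum, uniform on
[0.05, 0.5], approximating SNP-array ascertainment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import (MISSING, GenotypeDataset, SampleRecord, SNPRecord,
                          canonicalize_coding)

#: Expected IBD-sharing proportion (PI_HAT) per supported relationship.
RELATIONSHIP_PIHAT = {
    "parent-offspring": 0.5,
    "full-sib": 0.5,
    "half-sib": 0.25,
    "avuncular": 0.25,
    "first-cousin": 0.125,
}


@dataclass
class SimTruth:
    """Known generative parameters attached to a simulated dataset."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)

    def write_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"scenario": self.scenario, "seed": self.seed,
                       "params": _jsonable(self.params)}, fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# shared assembly helpers
# ---------------------------------------------------------------------------

def _canonical_dataset(genotypes: np.ndarray, samples: list[SampleRecord],
                       chroms: Sequence[str], positions: Sequence[int],
                       snp_ids: Sequence[str] | None = None) -> GenotypeDataset:
    """Assemble a dataset, flipping dosage columns so that the counted (B)
    allele is the minor one — the same convention the PED/MAP reader uses."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if snp_ids is None:
        snp_ids = [f"snp{k+1}" for k in range(m)]
    snps = []
    for k in range(m):
        col = g[:, k]
        nonmiss = col != MISSING
        freq_b = col[nonmiss].mean() / 2.0 if nonmiss.any() else 0.0
        allele_a, allele_b = "A", "G"
        if freq_b > 0.5:
            col2 = col.copy()
            col2[nonmiss] = 2 - col2[nonmiss]
            g[:, k] = col2
            allele_a, allele_b = "G", "A"
        snps.append(SNPRecord(snp_id=snp_ids[k], chromosome=str(chroms[k]),
                              position_bp=int(positions[k]),
                              allele_a=allele_a, allele_b=allele_b))
    return GenotypeDataset(samples=samples, snps=snps, genotypes=g)


def _unlinked_map(n_snps: int, spacing_bp: int = 1_000_000,
                  n_chrom: int = 29) -> tuple[list[str], list[int]]:
    """Spread unlinked SNPs over autosomes with wide spacing."""
    per = -(-n_snps // n_chrom)
    chroms, positions = [], []
    for k in range(n_snps):
        chroms.append(str(k // per + 1))
        positions.append((k % per + 1) * spacing_bp)
    return chroms, positions


# ---------------------------------------------------------------------------
# Wright-Fisher with recombination
# ---------------------------------------------------------------------------

def simulate_wright_fisher(N_diploid: int | Sequence[int], n_generations: int,
                           n_chrom: int, chrom_length_bp: float, n_snps: int,
                           map_rate: float = 1e-8, sample_size: int | None = None,
                           seed: int = 0) -> tuple[GenotypeDataset, SimTruth]:
    """Forward-in-time Wright-Fisher population with recombination.

    Discrete generations, random mating (monoecious, selfing allowed);
    recombination between adjacent SNPs follows Haldane's map function at
    ``map_rate`` Morgans/bp, with free recombination across chromosome
    boundaries.  Initial haplotypes are drawn site-independently at
    frequencies uniform on [0.05, 0.5].  ``N_diploid`` may be a single
    constant size (a burn-in of ~4N generations reaches
    drift-recombination equilibrium) or a per-generation size schedule of
    length ``n_generations`` for non-constant demographies (e.g. a recent
    decline).  Monomorphic SNPs at sampling time are retained (QC removes
    them).
    """
    schedule = ([int(N_diploid)] * n_generations if np.isscalar(N_diploid)
                else [int(x) for x in N_diploid])
    if len(schedule) != n_generations:
        raise ValueError("size schedule length must equal n_generations")
    if min(schedule) < 10:
        raise ValueError("N_diploid must be >= 10 in every generation")
    if not 1 <= n_chrom <= 29:
        raise ValueError("n_chrom must be in 1..29")
    rng = np.random.default_rng(seed)
    N0 = schedule[0]
    sample_size = sample_size or schedule[-1]

    per = n_snps // n_chrom
    if per < 2:
        raise ValueError("need at least 2 SNPs per chromosome")
    chroms, positions = [], []
    for c in range(n_chrom):
        pos = np.sort(rng.choice(int(chrom_length_bp), size=per, replace=False)) + 1
        chroms.extend([str(c + 1)] * per)
        positions.extend(pos.tolist())
    positions = np.array(positions, dtype=np.int64)
    chrom_arr = np.array([int(c) for c in chroms])
    L = len(positions)

    # per-adjacent-site switch probability (Haldane), 0.5 across chromosomes
    d = np.diff(positions).astype(float)
    r_adj = 0.5 * (1.0 - np.exp(-2.0 * map_rate * d))
    r_adj[np.diff(chrom_arr) != 0] = 0.5

    p0 = rng.uniform(0.05, 0.5, size=L)
    H = (rng.random((2 * N0, L)) < p0).astype(np.int8)

    def gametes(parent_idx: np.ndarray) -> np.ndarray:
        """One recombinant gamete per listed parent (vectorised)."""
        k = len(parent_idx)
        start = rng.integers(0, 2, size=(k, 1))
        switches = rng.random((k, L - 1)) < r_adj
        which = (start + np.concatenate(
            [np.zeros((k, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1)) % 2
        rows = 2 * parent_idx[:, None] + which
        return H[rows, np.arange(L)[None, :]]

    n_parents = N0
    for g in range(n_generations):
        n_offspring = schedule[g]
        mothers = rng.integers(0, n_parents, size=n_offspring)
        fathers = rng.integers(0, n_parents, size=n_offspring)
        newH = np.empty((2 * n_offspring, L), dtype=np.int8)
        newH[0::2] = gametes(mothers)
        newH[1::2] = gametes(fathers)
        H = newH
        n_parents = n_offspring

    take = rng.choice(n_parents, size=sample_size, replace=False)
    genotypes = (H[2 * take] + H[2 * take + 1]).astype(np.int8)
    samples = [SampleRecord(sample_id=f"wf{i+1}", population="WF")
               for i in range(sample_size)]
    dataset = _canonical_dataset(genotypes, samples, chroms, positions)
    truth = SimTruth(scenario="wright_fisher", seed=seed, params={
        "true_Ne": schedule[-1] if len(set(schedule)) > 1 else schedule[0],
        "size_schedule": schedule if len(set(schedule)) > 1 else None,
        "n_generations": n_generations,
        "map_rate": map_rate, "n_chrom": n_chrom,
        "chrom_length_bp": chrom_length_bp, "sample_size": sample_size,
    })
    return dataset, truth


# ---------------------------------------------------------------------------
# Balding-Nichols structured populations
# ---------------------------------------------------------------------------

def simulate_structured(n_pops: int, fst: float, n_per_pop: int, n_snps: int,
                        seed: int = 0) -> tuple[GenotypeDataset, SimTruth]:
    """Drift-differentiated populations under the Balding-Nichols model.

    Ancestral frequencies p ~ U[0.05, 0.95]; each population's frequency is
    Beta(p (1-F)/F, (1-p)(1-F)/F) with F = ``fst``; genotypes are
    Binomial(2, p_pop).
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    pop_freqs = rng.beta(a, b, size=(n_pops, n_snps))
    genotypes = np.concatenate(
        [rng.binomial(2, pop_freqs[p], size=(n_per_pop, n_snps)) for p in range(n_pops)],
        axis=0).astype(np.int8)
    samples = [SampleRecord(sample_id=f"p{p+1}_s{i+1}", population=f"pop{p+1}")
               for p in range(n_pops) for i in range(n_per_pop)]
    chroms, positions = _unlinked_map(n_snps)
    dataset = _canonical_dataset(genotypes, samples, chroms, positions)
    truth = SimTruth(scenario="structured", seed=seed, params={
        "true_FST": fst, "n_pops": n_pops, "n_per_pop": n_per_pop,
        "ancestral_freqs": p_anc, "population_freqs": pop_freqs,
    })
    return dataset, truth


# ---------------------------------------------------------------------------
# pedigree gene-dropping
# ---------------------------------------------------------------------------

def _founder(rng, p):
    """Founder allele pair: two Bernoulli(p) haploid genomes."""
    shape = (len(p),) if p.ndim == 1 else p.shape
    return (rng.random(p.shape) < p).astype(np.int8), (rng.random(p.shape) < p).astype(np.int8)


def _child(rng, mother, father):
    """Mendelian transmission at unlinked loci."""
    pick_m = rng.integers(0, 2, size=mother[0].shape, dtype=np.int8)
    pick_f = rng.integers(0, 2, size=father[0].shape, dtype=np.int8)
    from_m = np.where(pick_m == 0, mother[0], mother[1])
    from_f = np.where(pick_f == 0, father[0], father[1])
    return from_m, from_f


def simulate_pedigree(founder_freqs: np.ndarray | None, relationship: str,
                      n_pairs: int, n_snps: int, seed: int = 0
                      ) -> tuple[GenotypeDataset, SimTruth]:
    """Gene-drop sample pairs with a known pedigree relationship.

    Each pair descends from its own founders (pairs are unrelated to each
    other) through the minimal pedigree for ``relationship``; loci are
    unlinked.  Expected PI_HAT: parent-offspring and full-sib 0.5, half-sib
    and avuncular 0.25, first-cousin 0.125.  ``founder_freqs`` defaults to
    the chip-like uniform [0.05, 0.5] spectrum.
    """
    if relationship not in RELATIONSHIP_PIHAT:
        raise ValueError(f"unknown relationship {relationship!r}; "
                         f"choose from {sorted(RELATIONSHIP_PIHAT)}")
    rng = np.random.default_rng(seed)
    if founder_freqs is None:
        founder_freqs = rng.uniform(0.05, 0.5, size=n_snps)
    p = np.broadcast_to(np.asarray(founder_freqs, dtype=float), (n_pairs, n_snps))

    F = lambda: _founder(rng, p)
    C = lambda m, f: _child(rng, m, f)
    if relationship == "parent-offspring":
        a = F()
        first, second = a, C(a, F())
    elif relationship == "full-sib":
        m, f = F(), F()
        first, second = C(m, f), C(m, f)
    elif relationship == "half-sib":
        shared = F()
        first, second = C(shared, F()), C(shared, F())
    elif relationship == "avuncular":
        g1, g2 = F(), F()
        s1, s2 = C(g1, g2), C(g1, g2)
        first, second = s1, C(s2, F())
    else:  # first-cousin
        g1, g2 = F(), F()
        s1, s2 = C(g1, g2), C(g1, g2)
        first, second = C(s1, F()), C(s2, F())

    g_first = (first[0] + first[1]).astype(np.int8)
    g_second = (second[0] + second[1]).astype(np.int8)
    genotypes = np.empty((2 * n_pairs, n_snps), dtype=np.int8)
    genotypes[0::2] = g_first
    genotypes[1::2] = g_second
    samples = []
    for i in range(n_pairs):
        samples.append(SampleRecord(sample_id=f"pair{i+1}_a", population="PED"))
        samples.append(SampleRecord(sample_id=f"pair{i+1}_b", population="PED"))
    chroms, positions = _unlinked_map(n_snps)
    dataset = _canonical_dataset(genotypes, samples, chroms, positions)
    truth = SimTruth(scenario="pedigree", seed=seed, params={
        "relationship": relationship,
        "expected_pihat": RELATIONSHIP_PIHAT[relationship],
        "founder_freqs": np.asarray(founder_freqs),
        "pairs": [(f"pair{i+1}_a", f"pair{i+1}_b") for i in range(n_pairs)],
    })
    return dataset, truth


# ---------------------------------------------------------------------------
# admixed individuals
# ---------------------------------------------------------------------------

def simulate_admixed(Q_rows: np.ndarray, fst_between_ancestries: float,
                     n_snps: int, seed: int = 0
                     ) -> tuple[GenotypeDataset, SimTruth]:
    """Individuals with known ancestry fractions over Balding-Nichols clusters.

    ``Q_rows`` is (n_samples, K) with rows summing to 1; per-cluster allele
    frequencies come from the Balding-Nichols model at
    F = ``fst_between_ancestries``; dosage ~ Binomial(2, sum_c q_c p_c).
    """
    Q = np.asarray(Q_rows, dtype=float)
    if Q.ndim != 2 or not np.allclose(Q.sum(axis=1), 1.0):
        raise ValueError("Q_rows must be 2-D with rows summing to 1")
    rng = np.random.default_rng(seed)
    K = Q.shape[1]
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    F = fst_between_ancestries
    cluster_freqs = rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F,
                             size=(K, n_snps))
    mix = Q @ cluster_freqs
    genotypes = rng.binomial(2, mix).astype(np.int8)
    major = np.argmax(Q, axis=1)
    samples = [SampleRecord(sample_id=f"adm{i+1}", population=f"cl{major[i]+1}")
               for i in range(Q.shape[0])]
    chroms, positions = _unlinked_map(n_snps)
    dataset = _canonical_dataset(genotypes, samples, chroms, positions)
    truth = SimTruth(scenario="admixed", seed=seed, params={
        "true_Q": Q, "fst_between_ancestries": F,
        "cluster_freqs": cluster_freqs,
    })
    return dataset, truth


# ---------------------------------------------------------------------------
# missingness injection
# ---------------------------------------------------------------------------

def inject_missingness(dataset: GenotypeDataset,
                       sample_rates: float | np.ndarray,
                       snp_rates: float | np.ndarray,
                       seed: int = 0) -> GenotypeDataset:
    """Mask genotype cells independently at rate sample_rate x snp_rate.

    Rates may be scalars or per-sample / per-SNP vectors in [0, 1];
    deterministic under ``seed``.
    """
    s = np.broadcast_to(np.asarray(sample_rates, dtype=float), (dataset.n_samples,))
    k = np.broadcast_to(np.asarray(snp_rates, dtype=float), (dataset.n_snps,))
    if s.min() < 0 or s.max() > 1 or k.min() < 0 or k.max() > 1:
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rate = s[:, None] * k[None, :]
    mask = rng.random(rate.shape) < rate
    g = dataset.genotypes.copy()
    g[mask] = MISSING
    out = GenotypeDataset(samples=list(dataset.samples), snps=list(dataset.snps),
                          genotypes=g)
    # masking can change which allele is minor; restore the coding convention
    return canonicalize_coding(out)
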