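"""Population structure: GRM, PCA, AMOVA with permutation, FST, admixture.

The genetic relationship matrix (GRM) standardises genotypes by allele
frequency and averages cross-products over markers; PCA of the GRM gives
the sample eigenvectors used for structure visualisation.  AMOVA partitions
allele-level variance into among-population, among-individual-within-
population and within-individual components, with a label-permutation null
for the among-population component.  The admixture model treats each
genotype as Binomial(2, sum_c q_ic p_ck) and is fitted by EM with random
restarts; model order K is chosen by masked-entry cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

_P_CLAMP = 1e-6


# ---------------------------------------------------------------------------
# GRM and PCA
# ---------------------------------------------------------------------------

def grm(dataset: GenotypeDataset, freqs: np.ndarray | None = None) -> np.ndarray:
    """Allele-frequency-standardised genomic relationship matrix.

    G_ij = (1/m_ij) * sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k)),
    where missing genotypes contribute 0 and m_ij counts the markers called
    in both samples.  ``freqs`` overrides the cohort allele frequencies
    (e.g. with known generative frequencies); monomorphic SNPs are excluded
    with a warning.
    """
    p = dataset.allele_freq_b() if freqs is None else np.asarray(freqs, dtype=float)
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    if not usable.all():
        warnings.warn(f"excluding {int((~usable).sum())} monomorphic SNPs from GRM",
                      stacklevel=2)
    X = dataset.genotypes[:, usable].astype(float)
    p = p[usable]
    called = X != MISSING
    Z = np.where(called, (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p)), 0.0)
    m_pair = called.astype(float) @ called.astype(float).T
    if np.any(m_pair == 0):
        raise ValueError("sample pair with no overlapping called SNPs")
    return (Z @ Z.T) / m_pair


@dataclass(frozen=True)
class PCAResult:
    """Top-k eigenpairs of the GRM; variance fractions are of the retained set."""

    eigenvalues: np.ndarray            # descending, length k
    eigenvectors: np.ndarray           # (n_samples, k), orthonormal columns
    variance_fractions: np.ndarray     # eigenvalue / sum of retained eigenvalues


def pca(grm_matrix: np.ndarray, k: int = 3) -> PCAResult:
    """Top-k principal components of a symmetric relationship matrix.

    Sign convention: the largest-magnitude loading of each eigenvector is
    made positive, so results are deterministic.
    """
    G = np.asarray(grm_matrix, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("GRM must be a square matrix")
    if k > G.shape[0]:
        raise ValueError(f"k={k} exceeds matrix dimension {G.shape[0]}")
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1][:k]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(k):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    total = vals.sum()
    fractions = vals / total if total != 0 else np.full(k, np.nan)
    return PCAResult(eigenvalues=vals, eigenvectors=vecs, variance_fractions=fractions)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AMOVAResult:
    """Three-level AMOVA table, FST and the permutation p-value."""

    df: tuple[int, int, int]                 # among pops, among ind, within ind
    sums_of_squares: tuple[float, float, float]
    variance_components: tuple[float, float, float]
    percentages: tuple[float, float, float]
    fst: float
    p_value: float
    n_permutations: int

    def to_table(self) -> pd.DataFrame:
        rows = ["Among populations", "Among individuals within populations",
                "Within individuals"]
        frame = pd.DataFrame({
            "Source of variation": rows + ["Total"],
            "Degrees of freedom": list(self.df) + [sum(self.df)],
            "Sum of squares": list(self.sums_of_squares) + [sum(self.sums_of_squares)],
            "Variance components": list(self.variance_components)
            + [sum(self.variance_components)],
            "Percentage of variation": list(self.percentages) + [100.0],
        })
        return frame


def _amova_fixed_parts(dosage: np.ndarray, het: np.ndarray) -> tuple[float, float]:
    """(SS among individuals overall, SS within individuals) — both invariant
    under population-label permutation."""
    N = dosage.shape[0]
    ybar_ind = dosage / 2.0
    grand = dosage.mean(axis=0) / 2.0
    ss_among_ind_total = float((2.0 * (ybar_ind - grand) ** 2).sum())
    ss_within = float(0.5 * het.sum())
    return ss_among_ind_total, ss_within


def _ss_among_pops(dosage: np.ndarray, groups: list[np.ndarray]) -> float:
    grand = dosage.mean(axis=0) / 2.0
    ss = 0.0
    for idx in groups:
        ybar = dosage[idx].mean(axis=0) / 2.0
        ss += float((2.0 * len(idx) * (ybar - grand) ** 2).sum())
    return ss


def amova(dataset: GenotypeDataset, labels: list[str] | None = None,
          n_permutations: int = 1000, seed: int | None = None) -> AMOVAResult:
    """Three-level AMOVA on allele dosages with a permutation null.

    Each individual contributes two allele copies per locus; squared
    deviations of copies from individual, population and grand means give
    the within-individual, among-individual and among-population sums of
    squares, summed over loci.  Missing dosages are imputed at the locus
    grand mean (contributing nothing to the within-individual level), which
    keeps the decomposition permutation-invariant.  FST is the
    among-population fraction of total variance; the p-value is the
    (b+1)/(m+1) fraction of label permutations whose among-population
    component reaches the observed one.
    """
    labels = list(labels) if labels is not None else dataset.populations
    if len(labels) != dataset.n_samples:
        raise ValueError("one label per sample required")
    pops = sorted(set(labels))
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    lab = np.array(labels)
    groups = [np.flatnonzero(lab == p) for p in pops]
    sizes = np.array([len(g) for g in groups])
    if sizes.min() < 2:
        raise ValueError("AMOVA needs at least 2 individuals per population")

    g = dataset.genotypes.astype(float)
    missing = dataset.genotypes == MISSING
    col_mean = np.nanmean(np.where(missing, np.nan, g), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    dosage = np.where(missing, col_mean, g)
    het = (dataset.genotypes == 1)

    N = dataset.n_samples
    P = len(pops)
    df_ap, df_ai, df_wi = P - 1, N - P, N

    ss_among_ind_total, ss_wi = _amova_fixed_parts(dosage, het)
    ss_ap = _ss_among_pops(dosage, groups)
    ss_ai = ss_among_ind_total - ss_ap

    m_p = 2.0 * sizes  # gamete counts per population
    n_c = (m_p.sum() - (m_p ** 2).sum() / m_p.sum()) / (P - 1)

    def components(ss_ap_: float, ss_ai_: float) -> tuple[float, float, float]:
        ms_ap = ss_ap_ / df_ap
        ms_ai = ss_ai_ / df_ai
        ms_wi = ss_wi / df_wi
        sigma_w = ms_wi
        sigma_ind = (ms_ai - ms_wi) / 2.0
        sigma_pop = (ms_ap - ms_wi - 2.0 * sigma_ind) / n_c
        return sigma_pop, sigma_ind, sigma_w

    sigma_pop, sigma_ind, sigma_w = components(ss_ap, ss_ai)
    total = sigma_pop + sigma_ind + sigma_w
    fst = sigma_pop / total
    percentages = tuple(100.0 * s / total for s in (sigma_pop, sigma_ind, sigma_w))

    rng = np.random.default_rng(seed)
    exceed = 0
    order = np.arange(N)
    bounds = np.cumsum(sizes)[:-1]
    for _ in range(n_permutations):
        perm = rng.permutation(order)
        perm_groups = np.split(perm, bounds)
        ss_ap_perm = _ss_among_pops(dosage, perm_groups)
        sp, _, _ = components(ss_ap_perm, ss_among_ind_total - ss_ap_perm)
        if sp >= sigma_pop:
            exceed += 1
    p_value = (exceed + 1) / (n_permutations + 1)

    return AMOVAResult(
        df=(df_ap, df_ai, df_wi),
        sums_of_squares=(ss_ap, ss_ai, ss_wi),
        variance_components=(sigma_pop, sigma_ind, sigma_w),
        percentages=percentages,
        fst=float(fst),
        p_value=float(p_value),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def fst_weir_cockerham(dataset: GenotypeDataset, labels: list[str] | None = None
                       ) -> tuple[pd.DataFrame, float]:
    """Weir-Cockerham variance-components FST, per SNP and global.

    The global estimate is the ratio of summed among-population components
    to summed total components across loci.  SNPs monomorphic across all
    populations are skipped.
    """
    labels = list(labels) if labels is not None else dataset.populations
    pops = sorted(set(labels))
    r = len(pops)
    if r < 2:
        raise ValueError("FST needs at least 2 populations")
    lab = np.array(labels)
    g = dataset.genotypes

    n_i = np.zeros((r, dataset.n_snps))
    p_i = np.zeros((r, dataset.n_snps))
    h_i = np.zeros((r, dataset.n_snps))
    for a, pop in enumerate(pops):
        sub = g[lab == pop]
        called = sub != MISSING
        n_i[a] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[a] = np.where(n_i[a] > 0,
                              np.where(called, sub, 0).sum(axis=0) / (2.0 * np.maximum(n_i[a], 1)),
                              np.nan)
            h_i[a] = np.where(n_i[a] > 0,
                              (sub == 1).sum(axis=0) / np.maximum(n_i[a], 1), np.nan)

    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * nbar - (n_i ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)

        a_comp = (nbar / n_c) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
                                 / (nbar - 1))
        b_comp = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                        - hbar * (2 * nbar - 1) / (4 * nbar))
        c_comp = hbar / 2.0

    poly = np.isfinite(pbar) & (pbar > 0) & (pbar < 1) & (nbar > 1) & (n_c > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = np.where(poly, a_comp / (a_comp + b_comp + c_comp), np.nan)
    frame = pd.DataFrame({"snp_id": dataset.snp_ids, "fst": per_snp})
    global_fst = float(a_comp[poly].sum() / (a_comp + b_comp + c_comp)[poly].sum())
    return frame, global_fst


# ---------------------------------------------------------------------------
# admixture model
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureResult:
    """Fitted admixture model: ancestry fractions Q, cluster frequencies P."""

    K: int
    Q: np.ndarray                  # (n_samples, K), rows sum to 1
    P: np.ndarray                  # (K, n_snps), cluster B-allele frequencies
    log_likelihood: float
    n_iterations: int
    cv_error: float | None = None


def _admixture_loglik(X: np.ndarray, W: np.ndarray, Q: np.ndarray, P: np.ndarray
                      ) -> float:
    G = np.clip(Q @ P, _P_CLAMP, 1 - _P_CLAMP)
    return float((W * (X * np.log(G) + (2.0 - X) * np.log(1.0 - G))).sum())


def _admixture_em_once(X: np.ndarray, W: np.ndarray, K: int,
                       rng: np.random.Generator, max_iter: int, tol: float
                       ) -> tuple[np.ndarray, np.ndarray, float, int]:
    n, m = X.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.clip(rng.uniform(0.05, 0.95, size=(K, m)), _P_CLAMP, 1 - _P_CLAMP)
    ll = _admixture_loglik(X, W, Q, P)
    Xw = X * W
    Yw = (2.0 - X) * W
    for it in range(1, max_iter + 1):
        G = np.clip(Q @ P, _P_CLAMP, 1 - _P_CLAMP)
        RB = Xw / G          # (n, m)
        RA = Yw / (1.0 - G)
        newQ = np.empty_like(Q)
        newP = np.empty_like(P)
        for c in range(K):
            a_c = RB * (Q[:, [c]] * P[[c], :])          # expected B-allele copies
            b_c = RA * (Q[:, [c]] * (1.0 - P[[c], :]))  # expected A-allele copies
            newQ[:, c] = (a_c + b_c).sum(axis=1)
            newP[c] = a_c.sum(axis=0) / np.maximum((a_c + b_c).sum(axis=0), 1e-300)
        newQ /= np.maximum(newQ.sum(axis=1, keepdims=True), 1e-300)
        Q = newQ
        P = np.clip(newP, _P_CLAMP, 1 - _P_CLAMP)
        new_ll = _admixture_loglik(X, W, Q, P)
        assert new_ll >= ll - 1e-6, "EM log-likelihood decreased"
        if new_ll - ll < tol:
            ll = new_ll
            break
        ll = new_ll
    return Q, P, ll, it


def admixture_em(dataset: GenotypeDataset, K: int, seed: int | None = None,
                 max_iter: int = 500, tol: float = 1e-6, n_restarts: int = 5,
                 _mask: np.ndarray | None = None) -> AdmixtureResult:
    """Fit the K-cluster admixture model by EM with random restarts.

    Maximises the binomial likelihood of dosages given per-sample ancestry
    fractions Q and per-cluster allele frequencies P; the best of
    ``n_restarts`` runs by log-likelihood is returned.  ``_mask`` (internal,
    used by cross-validation) marks genotype cells to exclude from fitting.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    X = dataset.genotypes.astype(float)
    W = (dataset.genotypes != MISSING).astype(float)
    if _mask is not None:
        W = W * (~_mask)
    X = np.where(W > 0, X, 0.0)

    if K == 1:  # closed form: Q = 1, P = allele frequencies on unmasked cells
        denom = 2.0 * W.sum(axis=0)
        P = (X * W).sum(axis=0) / np.maximum(denom, 1e-300)
        P = np.clip(P, _P_CLAMP, 1 - _P_CLAMP)[None, :]
        Q = np.ones((dataset.n_samples, 1))
        return AdmixtureResult(K=1, Q=Q, P=P,
                               log_likelihood=_admixture_loglik(X, W, Q, P),
                               n_iterations=0)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        Q, P, ll, it = _admixture_em_once(X, W, K, rng, max_iter, tol)
        if best is None or ll > best[2]:
            best = (Q, P, ll, it)
    Q, P, ll, it = best
    return AdmixtureResult(K=K, Q=Q, P=P, log_likelihood=ll, n_iterations=it)


def admixture_cv(dataset: GenotypeDataset, K_list: list[int], folds: int = 5,
                 seed: int | None = None, max_iter: int = 300, tol: float = 1e-4,
                 n_restarts: int = 2) -> dict[int, float]:
    """Cross-validated model-order selection for the admixture model.

    Genotype cells are split into ``folds`` random folds; for each fold the
    model is fitted on the remaining cells and scored by mean binomial
    deviance on the held-out cells.  Returns the mean CV error per K; the
    optimal K is the argmin.  A fold that would blank out an entire sample
    or SNP is re-drawn.
    """
    if not K_list:
        raise ValueError("K_list must be non-empty")
    rng = np.random.default_rng(seed)
    called = dataset.genotypes != MISSING
    n, m = called.shape
    for _ in range(100):
        fold_of = rng.integers(0, folds, size=(n, m))
        ok = True
        for f in range(folds):
            train = called & (fold_of != f)
            if train.sum(axis=1).min() == 0 or train.sum(axis=0).min() == 0:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("could not draw a valid CV mask")

    X = dataset.genotypes.astype(float)
    errors: dict[int, float] = {}
    for K in K_list:
        fold_err = []
        for f in range(folds):
            mask = called & (fold_of == f)
            fit = admixture_em(dataset, K, seed=int(rng.integers(2**31)),
                               max_iter=max_iter, tol=tol, n_restarts=n_restarts,
                               _mask=mask)
            G = np.clip(fit.Q @ fit.P, _P_CLAMP, 1 - _P_CLAMP)
            x = X[mask]
            g = G[mask]
            dev = -2.0 * (x * np.log(g) + (2.0 - x) * np.log(1.0 - g))
            fold_err.append(float(dev.mean()))
        errors[K] = float(np.mean(fold_err))
    return errors
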