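"""Historical effective population size from distance-binned LD.

Under drift-recombination equilibrium the expected r² between loci at
recombination fraction c is approximately 1 / (alpha + 4 N c), so the LD
observed at distance d reflects the effective size roughly t = 1/(2c)
generations ago (c = map_rate * d).  The estimator bins all same-chromosome
pairwise r² values by physical distance, corrects each bin mean for the
finite-sample expectation (r²_adj = r² - 1/(beta n)), maps distance to
recombination fraction through Sved's f(c) = c (1 - c/2) / (1 - c)² (or the
identity), and inverts:

    N(t) = (1 / (4 f(c))) * (1 / E[r²_adj] - alpha).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset
from .ld import pairwise_ld

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NeConfig:
    """Binning, map and inversion constants for the Ne trajectory.

    ``map_rate`` is in Morgans per bp (default 1e-8 = 1 cM/Mb, the
    genome-wide average for the goat); ``alpha`` is the constant in the
    equilibrium expectation (1 for drift only, 2.2 with mutation);
    ``sved_mapping`` selects f(c) (True: Sved's mapping, False: identity);
    ``phased`` switches the sampling-bias correction from beta = 1
    (genotype-based r²) to beta = 2 (haplotype counts).
    """

    n_bins: int = 20
    bin_width_bp: float = 50_000.0
    min_distance_bp: float = 0.0
    max_distance_bp: float = 1_000_000.0
    alpha: float = 1.0
    map_rate: float = 1e-8
    sved_mapping: bool = True
    phased: bool = False

    def __post_init__(self) -> None:
        if self.map_rate <= 0:
            raise ValueError("map_rate must be positive")
        span = self.max_distance_bp - self.min_distance_bp
        if not np.isclose(span, self.n_bins * self.bin_width_bp):
            raise ValueError("bins must tile [min_distance, max_distance)")


def adjust_r2(r2, n_samples: int, phased: bool = False):
    """Sampling-bias-adjusted r²: subtract the null expectation 1/(beta n).

    beta = 2 for phased haplotype data (2n chromosomes), beta = 1 for r²
    estimated from n unphased diploid genotypes.  Floored at 0.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    beta = 2.0 if phased else 1.0
    return np.maximum(np.asarray(r2, dtype=float) - 1.0 / (beta * n_samples), 0.0)


def sved_f(c, identity: bool = False):
    """Sved's recombination mapping f(c) = c (1 - c/2) / (1 - c)².

    With ``identity`` the raw recombination fraction is returned.  Valid
    for 0 < c <= 0.5; f(c)/c -> 1 as c -> 0 under both mappings.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("recombination fraction must be positive")
    if identity:
        return c
    return c * (1.0 - c / 2.0) / (1.0 - c) ** 2


def ne_at_bin(mean_r2_adj: float, c: float, alpha: float = 1.0,
              identity_mapping: bool = False) -> float:
    """Invert the equilibrium LD expectation at one bin:
    Ne = (1 / (4 f(c))) (1 / E[r²_adj] - alpha).  Requires
    1/E[r²_adj] > alpha, otherwise the bin has no positive solution."""
    if mean_r2_adj <= 0:
        raise ValueError("mean adjusted r² must be positive")
    if 1.0 / mean_r2_adj <= alpha:
        raise ValueError("non-positive Ne: 1/E[r²_adj] <= alpha")
    f = float(sved_f(c, identity=identity_mapping))
    return (1.0 / (4.0 * f)) * (1.0 / mean_r2_adj - alpha)


def ne_trajectory(dataset: GenotypeDataset, config: NeConfig | None = None
                  ) -> pd.DataFrame:
    """Effective-population-size trajectory from binned pairwise LD.

    Computes all same-chromosome r² within the configured distance range,
    bins them (default 20 x 50 kb tiling 0-1 Mb), averages the adjusted r²
    per bin, and converts each bin's mean distance to (c, t = 1/(2c), Ne).
    Deterministic; rows sorted by t ascending (recent past first).  Bins
    that are empty or admit no positive Ne are skipped with a log message.
    """
    config = config or NeConfig()
    pairs = pairwise_ld(dataset, max_distance_bp=config.max_distance_bp)
    n = dataset.n_samples
    edges = config.min_distance_bp + config.bin_width_bp * np.arange(config.n_bins + 1)
    dist = pairs["dist_bp"].to_numpy(dtype=float)
    r2_adj = adjust_r2(pairs["r2"].to_numpy(), n, phased=config.phased)
    which = np.digitize(dist, edges, right=False) - 1

    rows = []
    for b in range(config.n_bins):
        sel = which == b
        if not sel.any():
            logger.warning("Ne bin %d (%.0f-%.0f bp) empty; skipped",
                           b, edges[b], edges[b + 1])
            continue
        mean_dist = float(dist[sel].mean())
        mean_r2_adj = float(r2_adj[sel].mean())
        c = config.map_rate * mean_dist
        t = 1.0 / (2.0 * c)
        if mean_r2_adj <= 0 or 1.0 / mean_r2_adj <= config.alpha:
            logger.warning("Ne bin %d: mean adjusted r² %.4f admits no positive "
                           "Ne; skipped", b, mean_r2_adj)
            continue
        ne = ne_at_bin(mean_r2_adj, c, alpha=config.alpha,
                       identity_mapping=not config.sved_mapping)
        rows.append({"t_generations": t, "c": c, "mean_dist_bp": mean_dist,
                     "n_pairs": int(sel.sum()), "mean_r2_adj": mean_r2_adj,
                     "Ne": ne})
    frame = pd.DataFrame(rows, columns=["t_generations", "c", "mean_dist_bp",
                                        "n_pairs", "mean_r2_adj", "Ne"])
    return frame.sort_values("t_generations", ignore_index=True)
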