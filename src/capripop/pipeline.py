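"""End-to-end orchestration: QC per cohort, merge, prune, and all analyses.

Mirrors the chip-analysis workflow: per-population QC, merge, a second QC
pass on the merged panel, autosome subsetting, LD pruning for the
diversity/structure stages (LD decay and Ne run on the un-pruned post-QC
panel, since pruning mechanically depresses r²), then the enabled analysis
stages.  Every output table starts with a provenance header (seed,
thresholds, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as div
from . import ld as ldmod
from . import ne as nemod
from . import structure as st
from .genotype_io import GenotypeDataset, merge_datasets, read_ped_map, subset_autosomes
from .ne import NeConfig
from .qc import QCConfig, QCReport, TABLE_HEADER, run_qc

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and stage toggles for :func:`run_pipeline`."""

    inputs: list[tuple[str, str]] = field(default_factory=list)  # (ped, map) pairs
    qc: QCConfig = field(default_factory=QCConfig)
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2
    run_diversity: bool = True
    run_amova: bool = True
    run_pca: bool = True
    admixture_K: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    run_ld_decay: bool = True
    run_ne: bool = True
    ne: NeConfig = field(default_factory=NeConfig)
    n_permutations: int = 1000
    out_dir: str = "capripop_out"
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps({k: str(v) for k, v in vars(self).items()
                              if k != "out_dir"}, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _write_table(frame: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# capripop config={config.digest()} seed={config.seed} "
                 f"qc={config.qc} prune=({config.prune_window},"
                 f"{config.prune_step},{config.prune_r2})\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig,
                 datasets: list[GenotypeDataset] | None = None) -> dict:
    """Run the full workflow and write report tables under ``out_dir``.

    ``datasets`` may be passed directly (e.g. from the simulators) instead
    of reading the PED/MAP pairs in ``config.inputs``.  Returns a dict of
    in-memory results keyed by stage name; tables are also written as TSV.
    Any stage error aborts with a stage-named message; outputs of earlier
    stages are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if datasets is None:
        if not config.inputs:
            raise ValueError("pipeline needs input PED/MAP pairs or datasets")
        datasets = [read_ped_map(ped, map_) for ped, map_ in config.inputs]

    # --- per-population QC, merge, merged QC ---------------------------
    stage = "qc"
    try:
        qc_rows = []
        cleaned = []
        for ds in datasets:
            label = ds.samples[0].population if ds.samples else "?"
            filtered, report = run_qc(ds, config.qc)
            cleaned.append(filtered)
            qc_rows.append(report.to_table_row(label))
        if len(cleaned) > 1:
            merged = merge_datasets(cleaned)
            merged, merged_report = run_qc(merged, config.qc)
            qc_rows.append(merged_report.to_table_row("Merged"))
        else:
            merged = cleaned[0]
            merged_report = None
        with open(out / "qc_report.tsv", "w") as fh:
            fh.write(f"# capripop config={config.digest()} seed={config.seed}; "
                     "counts attribute each SNP to the first failed criterion\n")
            fh.write(TABLE_HEADER + "\n")
            fh.write("\n".join(qc_rows) + "\n")
        results["qc"] = merged_report
        results["merged"] = merged
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "autosomes"
    merged = subset_autosomes(merged)
    if merged.n_snps < 2:
        raise RuntimeError(f"stage {stage!r} failed: fewer than 2 autosomal SNPs")

    stage = "prune"
    try:
        retained = ldmod.ld_prune(merged, config.prune_window, config.prune_step,
                                  config.prune_r2)
        pruned = ldmod.apply_prune(merged, retained)
        results["pruned"] = pruned
        logger.info("pruning retained %d of %d SNPs", pruned.n_snps, merged.n_snps)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    pops = sorted(set(merged.populations))

    if config.run_diversity:
        stage = "diversity"
        try:
            rows = []
            for name, full, lite in (
                [(p, merged.subset_population(p), pruned.subset_population(p)) for p in pops]
                + [("Merged", merged, pruned)]):
                _, he_full, ho_full = div.het_stats(full)
                _, he_pruned, ho_pruned = div.het_stats(lite)
                rows.append({
                    "Population": name,
                    "Average MAF": float(np.nanmean(full.maf())),
                    "He (post-QC)": he_full, "Ho (post-QC)": ho_full,
                    "He (LD-pruned)": he_pruned, "Ho (LD-pruned)": ho_pruned,
                    "f (post-QC)": float(np.mean(div.individual_inbreeding(full))),
                    "f (LD-pruned)": float(np.mean(div.individual_inbreeding(lite))),
                })
            table = pd.DataFrame(rows)
            _write_table(table, out / "diversity.tsv", config)
            kin = div.pairwise_pihat(pruned)
            _write_table(kin, out / "kinship.tsv", config)
            results["diversity"] = table
            results["kinship"] = kin
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if config.run_amova and len(pops) >= 2:
        stage = "amova"
        try:
            res = st.amova(pruned, n_permutations=config.n_permutations,
                           seed=config.seed)
            _write_table(res.to_table(), out / "amova.tsv", config)
            _, wc = st.fst_weir_cockerham(pruned)
            results["amova"] = res
            results["fst_wc"] = wc
            with open(out / "fst.txt", "w") as fh:
                fh.write(f"# capripop config={config.digest()} seed={config.seed}\n")
                fh.write(f"FST_AMOVA\t{res.fst:.4f}\nFST_WC\t{wc:.4f}\n"
                         f"AMOVA_p\t{res.p_value:.4g}\n")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    elif config.run_amova:
        raise RuntimeError("stage 'amova' failed: needs >= 2 populations")

    if config.run_pca:
        stage = "pca"
        try:
            G = st.grm(pruned)
            res = st.pca(G, k=min(3, pruned.n_samples))
            vec = pd.DataFrame(res.eigenvectors,
                               columns=[f"PC{i+1}" for i in range(res.eigenvectors.shape[1])])
            vec.insert(0, "sample_id", pruned.sample_ids)
            vec.insert(1, "population", pruned.populations)
            _write_table(vec, out / "pca_eigenvectors.tsv", config)
            _write_table(pd.DataFrame({
                "eigenvalue": res.eigenvalues,
                "variance_fraction": res.variance_fractions,
            }), out / "pca_eigenvalues.tsv", config)
            results["pca"] = res
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if config.admixture_K:
        stage = "admixture"
        try:
            cv = st.admixture_cv(pruned, config.admixture_K, seed=config.seed)
            best_k = min(cv, key=cv.get)
            fit = st.admixture_em(pruned, best_k, seed=config.seed)
            q = pd.DataFrame(fit.Q, columns=[f"Q{c+1}" for c in range(best_k)])
            q.insert(0, "sample_id", pruned.sample_ids)
            _write_table(q, out / f"admixture_Q_K{best_k}.tsv", config)
            _write_table(pd.DataFrame({"K": list(cv), "cv_error": list(cv.values())}),
                         out / "admixture_cv.tsv", config)
            results["admixture_cv"] = cv
            results["admixture"] = fit
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if config.run_ld_decay:
        stage = "ld_decay"
        try:
            decay = ldmod.ld_decay_table(merged)
            _write_table(decay, out / "ld_decay.tsv", config)
            per_chrom = ldmod.per_chromosome_ld(merged)
            _write_table(per_chrom, out / "ld_per_chromosome.tsv", config)
            results["ld_decay"] = decay
            results["ld_per_chromosome"] = per_chrom
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if config.run_ne:
        stage = "ne"
        try:
            traj = nemod.ne_trajectory(merged, config.ne)
            _write_table(traj, out / "ne_trajectory.tsv", config)
            results["ne"] = traj
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    return results
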