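"""End-to-end analysis pipeline and report writers.

Runs QC -> LD pruning -> per-subpopulation diversity -> mating-plan and
ROH inbreeding -> differentiation (FST matrix, Nei/NJ tree, PCA) -> LD decay
and Ne, and writes a directory of TSV/newick/JSON outputs in the layout of
the survey's report tables. Every output carries a provenance header
(package version, seed, parameters); the pipeline is a pure function of
(inputs, config, seed) and repeated runs agree byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .differentiation import genotype_pca, nei_distance_matrix, neighbor_joining, weir_cockerham_fst
from .diversity import diversity_summary, generational_trend
from .inbreeding import MatingPlan, f_es, f_roh, fes_froh_correlation, InbreedingRecord
from .io import (
    GenotypeMatrix,
    SubpopulationMap,
    read_matrix_tsv,
    read_subpopulation_tsv,
    read_vcf,
    split_by_subpopulation,
)
from .ld import ld_decay, ne_from_ld
from .qc import PruneParams, QcThresholds, apply_qc, ld_prune
from .roh import RohParams, detect_roh, merge_segments_per_individual, summarize_roh

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    genotypes: str | Path | None = None  # VCF (.vcf) or matrix TSV
    subpopulations: str | Path | None = None  # sample -> subpop TSV
    out_dir: str | Path = "consgen_out"
    qc: QcThresholds = field(default_factory=QcThresholds)
    prune: PruneParams = field(default_factory=PruneParams)
    roh: RohParams = field(default_factory=RohParams)
    plans: dict[str, MatingPlan] = field(default_factory=dict)  # breed -> plan
    sampling_years: dict[str, list[int]] = field(default_factory=dict)
    ld_max_distance_bp: int = 500_000
    ld_bins: int = 5
    ld_method: str = "composite"  # decay estimator; "em" is the survey-parity choice
    retention_threshold: float = 0.9
    inbreeding_threshold: float = 0.1
    seed: int = 0
    skip_ld: bool = False  # decay + Ne are the slow stages on dense panels


def _header(cfg: PipelineConfig, stage: str) -> str:
    return (
        f"# consgen {__version__} | stage={stage} | seed={cfg.seed}\n"
        f"# qc: call_rate>={cfg.qc.min_call_rate} maf>={cfg.qc.min_maf} "
        f"hwe_alpha={cfg.qc.hwe_alpha} | prune: {cfg.prune.window_snps} "
        f"{cfg.prune.step_snps} {cfg.prune.r2_threshold}\n"
    )


def _load(cfg: PipelineConfig) -> tuple[GenotypeMatrix, SubpopulationMap]:
    if cfg.genotypes is None or cfg.subpopulations is None:
        raise ValueError("pipeline needs genotype and sub-population inputs")
    path = Path(cfg.genotypes)
    gm = read_vcf(path) if path.suffix in (".vcf", ".gz") else read_matrix_tsv(path)
    smap = read_subpopulation_tsv(cfg.subpopulations)
    return gm, smap


def run_pipeline(
    cfg: PipelineConfig,
    gm: GenotypeMatrix | None = None,
    smap: SubpopulationMap | None = None,
) -> dict:
    """Execute the full analysis; returns the summary dict also written to disk.

    ``gm``/``smap`` may be passed directly (e.g. a simulated fixture) instead
    of file paths. Outputs land in ``cfg.out_dir``; a MANIFEST.json records
    the completed stages, so a failure leaves partial outputs accounted for.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {"version": __version__, "seed": cfg.seed}

    def done(stage: str) -> None:
        manifest.append(stage)
        (out / "MANIFEST.json").write_text(json.dumps({"completed": manifest}, indent=2) + "\n")

    try:
        if gm is None or smap is None:
            gm, smap = _load(cfg)
        done("load")

        gm_qc, report = apply_qc(gm, cfg.qc)
        (out / "qc_report.json").write_text(report.to_json() + "\n")
        summary["qc"] = {"input": report.n_input, "retained": report.n_retained, "excluded": report.excluded}
        done("qc")

        kept = ld_prune(gm_qc, cfg.prune)
        gm_pruned = gm_qc.subset_variants(kept)
        summary["prune"] = {"retained": int(len(kept))}
        done("prune")

        pops = split_by_subpopulation(gm_qc, smap)
        pops_pruned = split_by_subpopulation(gm_pruned, smap)
        labels = list(pops)

        # --- diversity (on the pruned panel, survey convention) + F_ES + F_ROH
        g = int(
            min(
                2 * min((p.calls != -1).sum(axis=0).min() for p in pops_pruned.values()),
                2 * min(p.n_samples for p in pops_pruned.values()),
            )
        )
        div = {lab: diversity_summary(p, g=g, panel_size=gm_pruned.n_variants) for lab, p in pops_pruned.items()}

        genome_length = int(
            sum(
                gm_qc.variants.position[gm_qc.variants.chromosome == c].max()
                for c in gm_qc.variants.chromosomes()
            )
        )
        froh: dict[str, float] = {}
        roh_tables = {}
        for lab, p in pops.items():
            segs = detect_roh(p, cfg.roh)
            merged = merge_segments_per_individual(segs)
            for s in p.samples:
                merged.setdefault(s, [])
            froh[lab], _ = f_roh(merged, genome_length)
            roh_tables[lab] = summarize_roh(segs, p.samples, p).table
        done("roh")

        records: list[InbreedingRecord] = []
        fes_by_label: dict[str, float] = {}
        for breed, plan in cfg.plans.items():
            for year in cfg.sampling_years.get(breed, []):
                lab = f"{breed}{str(year)[-2:]}"
                fes_by_label[lab] = round(f_es(plan, year), 4)
                if lab in froh:
                    records.append(
                        InbreedingRecord(lab, year - plan.start_year, fes_by_label[lab], froh[lab])
                    )

        with (out / "diversity_table.tsv").open("w") as fh:
            fh.write(_header(cfg, "diversity"))
            fh.write(f"# A_R standardized gene copies g={g}\n")
            fh.write("subpop\tHo\tHe\tP_N\tA_R\tF_ES\tF_ROH\n")
            for lab in labels:
                d = div[lab]
                fes_s = f"{fes_by_label[lab]:.4f}" if lab in fes_by_label else "NA"
                fh.write(
                    f"{lab}\t{d.Ho:.4f}\t{d.He:.4f}\t{d.P_N:.4f}\t{d.A_R:.4f}"
                    f"\t{fes_s}\t{froh[lab]:.4f}\n"
                )
        summary["diversity"] = {
            lab: {"Ho": div[lab].Ho, "He": div[lab].He, "P_N": div[lab].P_N, "A_R": div[lab].A_R}
            for lab in labels
        }
        summary["f_roh"] = froh
        summary["f_es"] = fes_by_label
        if len(records) >= 3:
            summary["fes_froh_r2"] = round(fes_froh_correlation(records), 2)
        done("diversity")

        with (out / "roh_summary.tsv").open("w") as fh:
            fh.write(_header(cfg, "roh"))
            fh.write("subpop\tmeasure\tmean\tsd\tmin\tmax\n")
            for lab in labels:
                for measure, row in roh_tables[lab].iterrows():
                    fh.write(
                        f"{lab}\t{measure}\t{row['mean']:.4f}\t{row['sd']:.4f}"
                        f"\t{row['min']:.4f}\t{row['max']:.4f}\n"
                    )

        # --- differentiation on the pruned panel
        fst = np.zeros((len(labels), len(labels)))
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                res = weir_cockerham_fst(pops_pruned[labels[i]], pops_pruned[labels[j]])
                fst[i, j] = fst[j, i] = res.weighted_fst
        with (out / "fst_matrix.tsv").open("w") as fh:
            fh.write(_header(cfg, "fst"))
            fh.write("subpop\t" + "\t".join(labels) + "\n")
            for i, lab in enumerate(labels):
                fh.write(lab + "\t" + "\t".join(f"{v:.4f}" for v in fst[i]) + "\n")
        summary["fst"] = {"labels": labels, "matrix": fst.tolist()}

        nd_labels, nd = nei_distance_matrix(pops_pruned)
        if len(nd_labels) >= 3 and np.isfinite(nd).all():
            (out / "nj_tree.nwk").write_text(neighbor_joining(nd, nd_labels) + "\n")
        coords, explained = genotype_pca(gm_pruned, k=2)
        with (out / "pca.tsv").open("w") as fh:
            fh.write(_header(cfg, "pca"))
            fh.write("# explained: " + " ".join(f"{e:.4f}" for e in explained) + "\n")
            fh.write("sample\tPC1\tPC2\n")
            for s, row in zip(gm_pruned.samples, coords):
                fh.write(s + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        done("differentiation")

        # --- LD decay + Ne per sub-population (QC'd, unpruned panel)
        if not cfg.skip_ld:
            ne_rows = []
            for lab, p in pops.items():
                curve = ld_decay(p, cfg.ld_max_distance_bp, cfg.ld_bins, method=cfg.ld_method)
                with (out / f"ld_decay_{lab}.tsv").open("w") as fh:
                    fh.write(_header(cfg, "ld"))
                    hd = curve.half_decay_distance_bp
                    fh.write(f"# half_decay_bp={hd if hd is not None else f'>{cfg.ld_max_distance_bp}'}\n")
                    fh.write("bin_start\tbin_end\tmean_r2\tn_pairs\n")
                    for k in range(len(curve.n_pairs)):
                        fh.write(
                            f"{int(curve.bin_edges_bp[k])}\t{int(curve.bin_edges_bp[k + 1])}"
                            f"\t{curve.mean_r2[k]:.6f}\t{int(curve.n_pairs[k])}\n"
                        )
                ne = ne_from_ld(p)
                ne_rows.append((lab, ne))
            with (out / "ne_table.tsv").open("w") as fh:
                fh.write(_header(cfg, "ne"))
                fh.write("subpop\tchromosome\tne\n")
                for lab, ne in ne_rows:
                    for chrom, v in ne.per_chromosome.items():
                        fh.write(f"{lab}\t{chrom}\t{v:.2f}\n")
                    for cls, v in ne.class_averages.items():
                        fh.write(f"{lab}\taverage_{cls}\t{v:.2f}\n")
            summary["ne"] = {lab: ne.class_averages for lab, ne in ne_rows}
            done("ld_ne")

        # --- generational trends + conservation flags
        trends = {}
        for breed in sorted({lab[:3] for lab in labels}):
            gens = {lab: div[lab] for lab in labels if lab.startswith(breed)}
            if len(gens) < 2:
                continue
            inb = {lab: froh[lab] for lab in gens}
            inb.update({lab: fes_by_label[lab] for lab in gens if lab in fes_by_label})
            rep = generational_trend(
                gens, inb, cfg.retention_threshold, cfg.inbreeding_threshold
            )
            trends[breed] = {
                "retention_ok": rep.retention_ok,
                "inbreeding_ok": rep.inbreeding_ok,
                "relative_change": rep.relative_change,
            }
        summary["trends"] = trends
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        done("report")
    except Exception:
        logger.exception("pipeline stage failed; partial outputs retained in %s", out)
        raise
    return summary
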