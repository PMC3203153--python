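"""End-to-end orchestration of the integrated miRNA-mRNA analysis.

Stages, in order: paired differential expression of mRNAs and miRNAs
(detection filter, log2 median centering, consistent-direction calls,
SAM-style permutation FDR), per-predictor regulation values and
correlated/anti-correlated/others classification, predictor pair-overlap
arithmetic, promoter CpG classing with a CpG-class x regulation-class
cross-table, and hypergeometric GO enrichment of the up- and down-regulated
gene sets. Optionally a qPCR Ct table is analysed alongside. Every output
is a fixed-column TSV under the configured report directory, and the run
log echoes all effective parameters so a report is reproducible from its
own directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import cpg as cpg_mod
from . import enrichment, qpcr, regnet
from .core_io import (
    diffexp_to_frame,
    read_annotation,
    read_expression_bundle,
    read_fasta_promoters,
    read_target_pairs,
)
from .diffexp import (
    DOWN,
    UP,
    SamConfig,
    detection_filter,
    log2_median_center,
    permutation_fdr,
)

logger = logging.getLogger(__name__)

DIFFEXP_COLUMNS = ["feature_id", "direction", "mean_delta", "d_stat", "q_value"]


@dataclass
class PipelineConfig:
    mrna_values: str
    mrna_detection: str
    mrna_design: str
    mirna_values: str
    mirna_detection: str
    mirna_design: str
    targets: list[dict] = field(default_factory=list)  # [{label, path}, ...]
    promoters_fasta: str | None = None
    annotation: str | None = None
    ct_table: str | None = None
    ct_paired: bool = True
    sam: SamConfig = field(default_factory=SamConfig)
    cpg: cpg_mod.CpgConfig = field(default_factory=cpg_mod.CpgConfig)
    epsilon: float = 0.0
    enrich_cutoff: float = 0.001
    outdir: str = "report"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sam = SamConfig(**raw.pop("sam", {}))
        cpg_cfg = cpg_mod.CpgConfig(**raw.pop("cpg", {}))
        return cls(sam=sam, cpg=cpg_cfg, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every configured stage; returns the report directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "diffexp"
    try:
        report: dict[str, object] = {"version": __version__, "config": config.to_dict()}
        mrna = read_expression_bundle(
            config.mrna_values, config.mrna_detection, config.mrna_design, "gene"
        )
        mirna = read_expression_bundle(
            config.mirna_values, config.mirna_detection, config.mirna_design, "mirna"
        )
        mrna_f = log2_median_center(detection_filter(mrna))
        mirna_f = log2_median_center(detection_filter(mirna))
        gene_de = diffexp_to_frame(permutation_fdr(mrna_f, config.sam))[DIFFEXP_COLUMNS]
        mirna_de = diffexp_to_frame(permutation_fdr(mirna_f, config.sam))[DIFFEXP_COLUMNS]
        _write(gene_de, outdir / "diffexp_mrna.tsv")
        _write(mirna_de, outdir / "diffexp_mirna.tsv")
        n_up = int((gene_de["direction"] == UP).sum())
        n_down = int((gene_de["direction"] == DOWN).sum())
        report["n_genes_up"] = n_up
        report["n_genes_down"] = n_down
        report["n_mirnas_up"] = int((mirna_de["direction"] == UP).sum())
        report["n_mirnas_down"] = int((mirna_de["direction"] == DOWN).sum())
        expressed_genes = set(mrna_f.feature_ids)

        stage = "regnet"
        maps = {
            t["label"]: read_target_pairs(t["path"], t["label"]) for t in config.targets
        }
        gene_classes: dict[str, pd.DataFrame] = {}
        for label, tmap in maps.items():
            mir_reg = regnet.compute_mirna_regulation(mirna_de, tmap, expressed_genes)
            gene_reg = regnet.compute_gene_regulation(
                gene_de, mir_reg, regnet.restrict_to_expressed(tmap, expressed_genes),
                config.epsilon,
            )
            summary = regnet.classification_summary(gene_reg, n_up, n_down)
            _write(regnet.mirna_regulation_frame(mir_reg), outdir / f"mirna_regulation_{label}.tsv")
            gframe = regnet.gene_regulation_frame(gene_reg)
            _write(gframe, outdir / f"gene_regulation_{label}.tsv")
            _write(summary, outdir / f"summary_classes_{label}.tsv")
            gene_classes[label] = gframe

        if len(maps) >= 2:
            rows = []
            labels = list(maps)
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    a, b = labels[i], labels[j]
                    shared, pct_a, pct_b = regnet.pair_overlap(maps[a], maps[b])
                    rows.append(
                        {
                            "predictor_a": a,
                            "predictor_b": b,
                            "n_pairs_a": len(maps[a]),
                            "n_pairs_b": len(maps[b]),
                            "n_shared": shared,
                            "pct_of_a": pct_a,
                            "pct_of_b": pct_b,
                        }
                    )
            _write(pd.DataFrame(rows), outdir / "target_overlap.tsv")

        stage = "cpg"
        if config.promoters_fasta:
            records = read_fasta_promoters(config.promoters_fasta)
            rows = []
            for rec in records:
                cls, gc, oe = cpg_mod.classify_sequence(rec.sequence, config.cpg)
                rows.append(
                    {
                        "gene_id": rec.gene_id,
                        "best_window_gc": round(gc, 4),
                        "best_window_oe": round(oe, 4),
                        "cpg_class": cls,
                    }
                )
            cpg_table = pd.DataFrame(rows)
            _write(cpg_table, outdir / "cpg_classes.tsv")
            if gene_classes:
                first = next(iter(gene_classes.values()))
                merged = cpg_table.merge(
                    first[["gene_id", "reg_class"]], on="gene_id", how="inner"
                )
                cross = (
                    merged.groupby(["cpg_class", "reg_class"]).size().rename("n").reset_index()
                )
                _write(cross, outdir / "cpg_by_regulation_class.tsv")

        stage = "enrichment"
        if config.annotation:
            ann = read_annotation(config.annotation)
            universe = expressed_genes
            for direction, name in ((UP, "up"), (DOWN, "down")):
                gene_set = set(gene_de.loc[gene_de["direction"] == direction, "feature_id"])
                table = enrichment.enrich(
                    gene_set & universe, ann, universe, config.enrich_cutoff
                )
                _write(table, outdir / f"enrichment_{name}.tsv")

        stage = "qpcr"
        if config.ct_table:
            ct = qpcr.read_ct_table(config.ct_table)
            _write(qpcr.analyze_ct_table(ct, paired=config.ct_paired), outdir / "qpcr.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    logger.info("report written to %s", outdir)
    return outdir
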