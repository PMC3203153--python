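"""Synthetic paired tumor/normal datasets with planted regulatory structure.

The generator emulates the statistical shape of a 6-patient paired
two-channel microarray study: log-normal intensity baselines, per-cell
Gaussian noise on the log2 scale, a minority of features shifted
consistently in every tumor, and a planted bipartite miRNA->target
repression network in which each differentially expressed miRNA pushes its
own disjoint block of target genes in the opposite direction, scaled by
``repression_effect / t_expressed``. Truth tables record every planted
direction, class and edge so that recovery can be scored without leaking
into the pipeline.

Two construction constraints keep the planted signal exactly recoverable
in the zero-noise limit:

* planted up-shifts are placed on features whose baseline lies above the
  array median and down-shifts below it, so shifting never reorders the
  middle of any array and log2 median centering is neutral with respect to
  the planted per-pair differences;
* each differentially expressed miRNA's targets are disjoint from every
  other planted set, so each planted target has exactly one variable
  regulator and its regulation-value sign is unambiguous.

Promoters are built to satisfy the default CpG-class thresholds (verified
against the classifier at generation time), and the annotation table plants
one term over-represented in the planted up-regulated gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cpg as cpg_mod
from .core_io import (
    NORMAL,
    TUMOR,
    AnnotationTable,
    ExpressionBundle,
    PromoterRecord,
    TargetMap,
    write_annotation,
    write_expression_bundle,
    write_fasta_promoters,
    write_target_pairs,
)

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study-shaped defaults: 6 patient pairs, a scaled-down feature space
    keeping roughly the study's 1:2 up:down asymmetry for genes."""

    n_patients: int = 6
    n_genes: int = 1200
    n_mirnas: int = 80
    frac_genes_up: float = 0.05
    frac_genes_down: float = 0.10
    frac_mirnas_up: float = 0.10
    frac_mirnas_down: float = 0.10
    targets_per_mirna: tuple[int, int] = (3, 8)
    repression_effect: float = 2.0
    de_effect_log2: float = 1.5
    noise_sd: float = 0.1
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    frac_undetected: float = 0.02
    detection_floor_log2: float = 2.0
    n_terms: int = 40
    planted_term_size: int = 80
    planted_enrichment_fraction: float = 0.5
    term_size_range: tuple[int, int] = (20, 120)
    promoter_counts: dict[str, int] = field(
        default_factory=lambda: {"HCG": 5, "ICG": 5, "LCG": 5}
    )
    promoter_length: int = 1000
    rng_seed: int = 17

    def __post_init__(self) -> None:
        for name in (
            "frac_genes_up",
            "frac_genes_down",
            "frac_mirnas_up",
            "frac_mirnas_down",
            "frac_undetected",
            "planted_enrichment_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_genes_up + self.frac_genes_down + self.frac_undetected > 1:
            raise ValueError("gene fractions exceed 1")
        if self.frac_mirnas_up + self.frac_mirnas_down > 1:
            raise ValueError("miRNA fractions exceed 1")
        for name in ("n_patients", "n_genes", "n_mirnas", "n_terms", "promoter_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.targets_per_mirna
        if not 1 <= lo <= hi:
            raise ValueError("targets_per_mirna must be a nonempty positive range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SimPlan:
    """Planted assignments shared by the expression/annotation generators."""

    gene_ids: list[str]
    mirna_ids: list[str]
    gene_baseline: np.ndarray
    mirna_baseline: np.ndarray
    gene_direction: dict[str, str]  # planted up/down for DE genes
    gene_class: dict[str, str]  # anti_correlated / others for DE genes
    mirna_direction: dict[str, str]
    undetected_genes: set[str]
    edges: set[tuple[str, str]]
    repression_edges: set[tuple[str, str]]
    gene_shift: dict[str, float]
    mirna_shift: dict[str, float]


@dataclass
class SimResult:
    mrna: ExpressionBundle
    mirna: ExpressionBundle
    target_map: TargetMap
    annotation: AnnotationTable
    promoters: list[PromoterRecord]
    truth: dict[str, pd.DataFrame]
    plan: SimPlan


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def _split_halves(
    ids: list[str],
    baseline_of: dict[str, float],
    floor: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Strict upper/lower baseline halves of the detectable features.

    The two middle order statistics are excluded from both halves so that
    shifting any pooled feature up (upper half) or down (lower half) leaves
    every array's median order statistics untouched: log2 median centering
    is then exactly neutral with respect to the planted differences.
    """
    detectable = [f for f in ids if baseline_of[f] > floor]
    ordered = sorted(detectable, key=baseline_of.__getitem__)
    n = len(ordered)
    lo_end = (n - 1) // 2  # exclusive
    hi_start = n // 2 + 1
    lower = [ordered[i] for i in rng.permutation(lo_end)]
    upper_block = ordered[hi_start:]
    upper = [upper_block[i] for i in rng.permutation(len(upper_block))]
    return upper, lower


def _make_plan(config: SimConfig) -> SimPlan:
    rng = _child_rng(config.rng_seed, 0)
    gene_ids = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    mirna_ids = [f"hsa-mir-s{i:03d}" for i in range(1, config.n_mirnas + 1)]

    gene_baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
    )
    mirna_baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_mirnas
    )

    n_undet = int(round(config.frac_undetected * config.n_genes))
    undet_idx = rng.choice(config.n_genes, size=n_undet, replace=False)
    undetected = {gene_ids[i] for i in undet_idx}
    gene_baseline = gene_baseline.copy()
    gene_baseline[undet_idx] = rng.normal(
        config.detection_floor_log2 - 4.0, 0.3, n_undet
    )

    baseline_of = dict(zip(gene_ids, gene_baseline))
    floor = config.detection_floor_log2
    upper, lower = _split_halves(gene_ids, baseline_of, floor, rng)

    n_up = int(round(config.frac_genes_up * config.n_genes))
    n_down = int(round(config.frac_genes_down * config.n_genes))
    up_genes = upper[:n_up]
    down_genes = lower[:n_down]
    upper_free = upper[n_up:]
    lower_free = lower[n_down:]
    detected = [g for g in gene_ids if baseline_of[g] > floor]

    # miRNA directions: up miRNAs from the upper baseline half, down from lower
    mirna_baseline_of = dict(zip(mirna_ids, mirna_baseline))
    m_upper, m_lower = _split_halves(mirna_ids, mirna_baseline_of, floor, rng)
    n_m_up = int(round(config.frac_mirnas_up * config.n_mirnas))
    n_m_down = int(round(config.frac_mirnas_down * config.n_mirnas))
    mirna_direction = {m: "up" for m in m_upper[:n_m_up]}
    mirna_direction.update({m: "down" for m in m_lower[:n_m_down]})

    gene_direction = {g: "up" for g in up_genes}
    gene_direction.update({g: "down" for g in down_genes})
    gene_class = {g: "others" for g in list(up_genes) + list(down_genes)}

    mirna_shift = {}
    for m, d in mirna_direction.items():
        mirna_shift[m] = config.de_effect_log2 if d == "up" else -config.de_effect_log2

    lo, hi = config.targets_per_mirna
    edges: set[tuple[str, str]] = set()
    repression_edges: set[tuple[str, str]] = set()
    gene_shift = {g: (config.de_effect_log2 if d == "up" else -config.de_effect_log2)
                  for g, d in gene_direction.items()}

    # repressed target blocks, disjoint, drawn from the free halves so that a
    # down-shifted target starts below the median and an up-shifted one above
    for m in sorted(mirna_direction):
        t = int(rng.integers(lo, hi + 1))
        pool = lower_free if mirna_direction[m] == "up" else upper_free
        if len(pool) < t:
            raise ValueError("not enough free genes to plant disjoint target blocks")
        targets, remainder = pool[:t], pool[t:]
        if mirna_direction[m] == "up":
            lower_free = remainder
        else:
            upper_free = remainder
        shift = -mirna_shift[m] * config.repression_effect / t
        for g in targets:
            edges.add((m, g))
            repression_edges.add((m, g))
            if shift != 0.0:
                gene_shift[g] = shift
                gene_direction[g] = "down" if shift < 0 else "up"
                gene_class[g] = "anti_correlated"

    # background edges from unvaried miRNAs: free targets anywhere detected
    planted_de = set(gene_direction)
    background_pool = [g for g in detected if g not in planted_de]
    for m in mirna_ids:
        if m in mirna_direction:
            continue
        t = int(rng.integers(lo, hi + 1))
        targets = rng.choice(len(background_pool), size=min(t, len(background_pool)), replace=False)
        for i in targets:
            edges.add((m, background_pool[i]))

    return SimPlan(
        gene_ids=gene_ids,
        mirna_ids=mirna_ids,
        gene_baseline=np.array([baseline_of[g] for g in gene_ids]),
        mirna_baseline=mirna_baseline,
        gene_direction=gene_direction,
        gene_class=gene_class,
        mirna_direction=mirna_direction,
        undetected_genes=undetected,
        edges=edges,
        repression_edges=repression_edges,
        gene_shift=gene_shift,
        mirna_shift=mirna_shift,
    )


def _build_bundle(
    ids: list[str],
    baseline: np.ndarray,
    shift: dict[str, float],
    config: SimConfig,
    rng: np.random.Generator,
    feature_kind: str,
) -> ExpressionBundle:
    n_feat = len(ids)
    n_pat = config.n_patients
    patients = [f"P{i}" for i in range(1, n_pat + 1)]
    sample_ids = [f"{p}T" for p in patients] + [f"{p}N" for p in patients]
    design = [(p, TUMOR) for p in patients] + [(p, NORMAL) for p in patients]
    shifts = np.array([shift.get(f, 0.0) for f in ids])
    log2 = np.tile(baseline[:, None], (1, 2 * n_pat)).astype(float)
    log2[:, :n_pat] += shifts[:, None]
    if config.noise_sd > 0:
        log2 += rng.normal(0.0, config.noise_sd, size=log2.shape)
    values = pd.DataFrame(2.0 ** log2, index=ids, columns=sample_ids)
    detection = pd.DataFrame(log2 > config.detection_floor_log2, index=ids, columns=sample_ids)
    return ExpressionBundle(
        values=values,
        detection=detection,
        design=design,
        scale="raw",
        feature_kind=feature_kind,
    )


def generate_bundle(
    config: SimConfig,
) -> tuple[ExpressionBundle, ExpressionBundle, TargetMap, dict[str, pd.DataFrame]]:
    """Paired mRNA and miRNA bundles, the planted target map, and truth tables."""
    plan = _make_plan(config)
    rng = _child_rng(config.rng_seed, 1)
    mrna = _build_bundle(plan.gene_ids, plan.gene_baseline, plan.gene_shift, config, rng, "gene")
    mirna = _build_bundle(
        plan.mirna_ids, plan.mirna_baseline, plan.mirna_shift, config, rng, "mirna"
    )
    target_map = TargetMap.from_pairs("planted", plan.edges)
    truth = _truth_tables(plan)
    return mrna, mirna, target_map, truth


def _truth_tables(plan: SimPlan) -> dict[str, pd.DataFrame]:
    genes = pd.DataFrame(
        {
            "gene_id": plan.gene_ids,
            "planted_direction": [plan.gene_direction.get(g, "none") for g in plan.gene_ids],
            "planted_class": [plan.gene_class.get(g, "") for g in plan.gene_ids],
            "planted_undetected": [g in plan.undetected_genes for g in plan.gene_ids],
        }
    )
    mirnas = pd.DataFrame(
        {
            "mirna_id": plan.mirna_ids,
            "planted_direction": [plan.mirna_direction.get(m, "none") for m in plan.mirna_ids],
        }
    )
    edges = pd.DataFrame(
        sorted(plan.edges), columns=["mirna_id", "gene_id"]
    )
    edges["is_repression"] = [
        (m, g) in plan.repression_edges for m, g in zip(edges["mirna_id"], edges["gene_id"])
    ]
    return {"genes": genes, "mirnas": mirnas, "edges": edges}


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _deplete_cpg(seq: str, rng: np.random.Generator, keep_prob: float) -> str:
    out = list(seq)
    i = 0
    while i < len(out) - 1:
        if out[i] == "C" and out[i + 1] == "G" and rng.random() > keep_prob:
            out[i + 1] = "A" if rng.random() < 0.5 else "T"
        i += 1
    return "".join(out)


def _make_class_seq(cls: str, length: int, rng: np.random.Generator) -> str:
    if cls == cpg_mod.HCG:
        # CpG-dense tokens over a GC-rich background
        chunks: list[str] = []
        n = 0
        while n < length:
            if rng.random() < 0.15:
                chunks.append("CG")
                n += 2
            else:
                chunks.append(_random_seq(rng, 1, 0.55))
                n += 1
        return "".join(chunks)[:length]
    if cls == cpg_mod.ICG:
        # near-neutral GC with mildly depleted CpGs: O/E lands between bands
        return _deplete_cpg(_random_seq(rng, length, 0.46), rng, keep_prob=0.55)
    if cls == cpg_mod.LCG:
        return _deplete_cpg(_random_seq(rng, length, 0.38), rng, keep_prob=0.12)
    raise ValueError(f"unknown CpG class {cls!r}")


def generate_promoters(
    config: SimConfig, cpg_config: cpg_mod.CpgConfig | None = None
) -> tuple[list[PromoterRecord], pd.DataFrame]:
    """Promoter FASTA records constructed to satisfy each requested class.

    Each candidate is checked against the classifier itself and resampled
    until it lands in the requested class, so the emitted truth labels hold
    under the configured thresholds by construction.
    """
    cpg_config = cpg_config or cpg_mod.CpgConfig()
    rng = _child_rng(config.rng_seed, 2)
    plan = _make_plan(config)
    detected = [g for g in plan.gene_ids if g not in plan.undetected_genes]
    n_total = sum(config.promoter_counts.values())
    if n_total > len(detected):
        raise ValueError("more promoters requested than detected genes available")
    chosen = list(rng.choice(len(detected), size=n_total, replace=False))
    records: list[PromoterRecord] = []
    labels: list[str] = []
    k = 0
    for cls in sorted(config.promoter_counts):
        for _ in range(config.promoter_counts[cls]):
            gene = detected[chosen[k]]
            k += 1
            for attempt in range(100):
                seq = _make_class_seq(cls, config.promoter_length, rng)
                got, _, _ = cpg_mod.classify_sequence(seq, cpg_config)
                if got == cls:
                    break
            else:
                raise RuntimeError(f"could not construct a {cls} promoter in 100 tries")
            records.append(PromoterRecord(gene_id=gene, sequence=seq, cpg_class="unclassified"))
            labels.append(cls)
    truth = pd.DataFrame(
        {"gene_id": [r.gene_id for r in records], "planted_class": labels}
    )
    return records, truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def generate_annotation(config: SimConfig) -> tuple[AnnotationTable, str]:
    """Annotation with one term over-represented in the planted up gene set.

    Returns the table and the planted term id. The planted term draws
    ``planted_enrichment_fraction`` of its genes from the planted
    up-regulated set and the rest uniformly; the remaining terms are fully
    random, giving the enrichment stage a known positive and a calibrated
    background.
    """
    if config.n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = _child_rng(config.rng_seed, 3)
    plan = _make_plan(config)
    detected = [g for g in plan.gene_ids if g not in plan.undetected_genes]
    up_set = [g for g, d in sorted(plan.gene_direction.items()) if d == "up"]
    not_up = [g for g in detected if g not in set(up_set)]

    term_genes: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    planted_term = "SIM:0001"
    n_from_up = min(
        int(round(config.planted_term_size * config.planted_enrichment_fraction)), len(up_set)
    )
    n_rest = min(config.planted_term_size - n_from_up, len(not_up))
    planted_genes = set(rng.choice(up_set, size=n_from_up, replace=False)) | set(
        rng.choice(not_up, size=n_rest, replace=False)
    )
    term_genes[planted_term] = planted_genes
    term_names[planted_term] = "planted enriched process"
    lo, hi = config.term_size_range
    for i in range(2, config.n_terms + 1):
        tid = f"SIM:{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        term_genes[tid] = set(rng.choice(detected, size=min(size, len(detected)), replace=False))
        term_names[tid] = f"random process {i}"
    return AnnotationTable(term_genes=term_genes, term_names=term_names), planted_term


# ---------------------------------------------------------------------------
# one-call generation and file emission
# ---------------------------------------------------------------------------


def generate(config: SimConfig) -> SimResult:
    mrna, mirna, target_map, truth = generate_bundle(config)
    annotation, planted_term = generate_annotation(config)
    promoters, promoter_truth = generate_promoters(config)
    truth = dict(truth)
    truth["promoters"] = promoter_truth
    truth["annotation"] = pd.DataFrame({"planted_term": [planted_term]})
    plan = _make_plan(config)
    return SimResult(
        mrna=mrna,
        mirna=mirna,
        target_map=target_map,
        annotation=annotation,
        promoters=promoters,
        truth=truth,
        plan=plan,
    )


def write_sim_outputs(result: SimResult, outdir: str | Path) -> None:
    """Emit every input format the pipeline consumes, plus truth/ tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    write_expression_bundle(
        result.mrna,
        outdir / "mrna_values.tsv",
        outdir / "mrna_detection.tsv",
        outdir / "mrna_design.tsv",
    )
    write_expression_bundle(
        result.mirna,
        outdir / "mirna_values.tsv",
        outdir / "mirna_detection.tsv",
        outdir / "mirna_design.tsv",
    )
    write_target_pairs(result.target_map, outdir / "target_pairs.tsv")
    write_fasta_promoters(result.promoters, outdir / "promoters.fa")
    write_annotation(result.annotation, outdir / "annotation.tsv")
    for name, df in result.truth.items():
        df.to_csv(outdir / "truth" / f"{name}.tsv", sep="\t", index=False)
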