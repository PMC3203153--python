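"""miRNA regulation values and the correlated / anti-correlated / others
classification of differentially expressed genes.

A miRNA dilutes its regulatory influence over its expressed targets: its
regulation value is r = delta_e / t_expressed, where delta_e is the mean
per-pair log2 tumor-normal change of the miRNA and t_expressed the number
of its predicted targets present in the detection-filtered gene set. A
gene's regulation value R_g is the sum of r over every differentially
expressed ("variable") miRNA predicted to target it; genes with no such
regulator have a null R_g.

Classification of a differentially expressed gene then depends only on
signs: a gene whose own change opposes its net miRNA regulation (up with
negative R_g, or down with positive R_g) is *anti-correlated* -- the
pattern expected of genuine miRNA repression -- a gene moving with its
regulation is *correlated*, and a null (or, optionally, sub-epsilon) R_g
puts the gene in *others*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .core_io import TargetMap
from .diffexp import DOWN, NONE, UP, percent_of

logger = logging.getLogger(__name__)

ANTI_CORRELATED = "anti_correlated"
CORRELATED = "correlated"
OTHERS = "others"


@dataclass
class MirnaRegulation:
    mirna_id: str
    delta_e: float
    t_expressed: int
    r_value: float


@dataclass
class GeneRegulation:
    gene_id: str
    regulators: list[str]
    R_g: float | None
    direction: str  # up | down
    reg_class: str = OTHERS


def restrict_to_expressed(target_map: TargetMap, expressed_gene_ids: set[str]) -> TargetMap:
    """Keep only pairs whose gene is expressed; miRNAs left targetless drop out."""
    kept = frozenset((m, g) for m, g in target_map.pairs if g in expressed_gene_ids)
    return TargetMap(predictor_label=target_map.predictor_label, pairs=kept)


def pair_overlap(map_a: TargetMap, map_b: TargetMap) -> tuple[int, float, float]:
    """Shared pair count and its percentage of each map's pairs."""
    if not map_a.pairs or not map_b.pairs:
        raise ValueError("pair_overlap requires two non-empty target maps")
    shared = len(map_a.pairs & map_b.pairs)
    return shared, percent_of(shared, len(map_a.pairs)), percent_of(shared, len(map_b.pairs))


def mirna_regulation_value(delta_e: float, t_expressed: int) -> float:
    """r = expression variation / number of expressed targets."""
    if t_expressed < 1:
        raise ValueError("no expressed targets: t_expressed must be >= 1")
    return delta_e / t_expressed


def gene_regulation_value(gene_id: str, regulator_r_values: list[float]) -> GeneRegulation:
    """Sum regulator r-values; an empty regulator list gives a null R_g."""
    R_g = sum(regulator_r_values) if regulator_r_values else None
    return GeneRegulation(
        gene_id=gene_id, regulators=[], R_g=R_g, direction=NONE, reg_class=OTHERS
    )


def classify_gene(R_g: float | None, direction: str, epsilon: float = 0.0) -> str:
    """Sign-concordance class of a differentially expressed gene."""
    if direction not in (UP, DOWN):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if R_g is None or abs(R_g) <= epsilon:
        return OTHERS
    gene_sign = 1.0 if direction == UP else -1.0
    return CORRELATED if R_g * gene_sign > 0 else ANTI_CORRELATED


def compute_mirna_regulation(
    mirna_diffexp: pd.DataFrame,
    target_map: TargetMap,
    expressed_gene_ids: set[str],
) -> list[MirnaRegulation]:
    """Regulation values of the direction-consistent ("variable") miRNAs.

    ``mirna_diffexp`` carries columns feature_id/direction/mean_delta;
    t_expressed counts targets among the detection-filtered genes, not only
    the differentially expressed ones. Variable miRNAs with no expressed
    target get no regulation value (they are dropped with a log note).
    """
    restricted = restrict_to_expressed(target_map, expressed_gene_ids)
    by_mirna = restricted.by_mirna()
    out: list[MirnaRegulation] = []
    variable = mirna_diffexp[mirna_diffexp["direction"].isin([UP, DOWN])]
    for row in variable.itertuples(index=False):
        targets = by_mirna.get(row.feature_id)
        if not targets:
            logger.info("miRNA %s is variable but has no expressed target", row.feature_id)
            continue
        t = len(targets)
        out.append(
            MirnaRegulation(
                mirna_id=row.feature_id,
                delta_e=float(row.mean_delta),
                t_expressed=t,
                r_value=mirna_regulation_value(float(row.mean_delta), t),
            )
        )
    return out


def compute_gene_regulation(
    gene_diffexp: pd.DataFrame,
    mirna_regulations: list[MirnaRegulation],
    target_map: TargetMap,
    epsilon: float = 0.0,
) -> list[GeneRegulation]:
    """Classify every differentially expressed gene against its regulators."""
    r_by_mirna = {m.mirna_id: m.r_value for m in mirna_regulations}
    regulators_of = {
        g: sorted(ms & r_by_mirna.keys()) for g, ms in target_map.by_gene().items()
    }
    out: list[GeneRegulation] = []
    de_genes = gene_diffexp[gene_diffexp["direction"].isin([UP, DOWN])]
    for row in de_genes.itertuples(index=False):
        regs = regulators_of.get(row.feature_id, [])
        R_g = sum(r_by_mirna[m] for m in regs) if regs else None
        out.append(
            GeneRegulation(
                gene_id=row.feature_id,
                regulators=regs,
                R_g=R_g,
                direction=row.direction,
                reg_class=classify_gene(R_g, row.direction, epsilon),
            )
        )
    return out


def classification_summary(
    gene_regulations: list[GeneRegulation], n_up_total: int, n_down_total: int
) -> pd.DataFrame:
    """Per-class totals with up/down counts and printed-style percentages.

    Mirrors the three-group summary table: each class row carries its total,
    the up-regulated count as a percentage of all up-regulated genes, and
    likewise for down. Class totals sum to n_up_total + n_down_total.
    """
    counts = {c: {"up": 0, "down": 0} for c in (ANTI_CORRELATED, CORRELATED, OTHERS)}
    for gr in gene_regulations:
        if gr.reg_class not in counts or gr.direction not in (UP, DOWN):
            raise ValueError(
                f"unclassified gene {gr.gene_id!r}: class={gr.reg_class!r}, "
                f"direction={gr.direction!r}"
            )
        counts[gr.reg_class][gr.direction] += 1
    n_up = sum(c["up"] for c in counts.values())
    n_down = sum(c["down"] for c in counts.values())
    if n_up != n_up_total or n_down != n_down_total:
        raise ValueError(
            f"classified up/down counts ({n_up}/{n_down}) do not match the "
            f"stated totals ({n_up_total}/{n_down_total})"
        )
    rows = []
    for cls in (ANTI_CORRELATED, CORRELATED, OTHERS):
        up, down = counts[cls]["up"], counts[cls]["down"]
        rows.append(
            {
                "reg_class": cls,
                "total": up + down,
                "n_up": up,
                "pct_up": percent_of(up, n_up_total),
                "n_down": down,
                "pct_down": percent_of(down, n_down_total),
            }
        )
    return pd.DataFrame(rows)


def gene_regulation_frame(gene_regulations: list[GeneRegulation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in gene_regulations],
            "direction": [g.direction for g in gene_regulations],
            "regulators": [",".join(g.regulators) for g in gene_regulations],
            "R_g": [g.R_g for g in gene_regulations],
            "reg_class": [g.reg_class for g in gene_regulations],
        }
    )


def mirna_regulation_frame(mirna_regulations: list[MirnaRegulation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [m.mirna_id for m in mirna_regulations],
            "delta_e": [m.delta_e for m in mirna_regulations],
            "t_expressed": [m.t_expressed for m in mirna_regulations],
            "r_value": [m.r_value for m in mirna_regulations],
        }
    )
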