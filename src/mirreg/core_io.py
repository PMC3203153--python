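"""Domain containers and plain-text IO for the miRNA-mRNA integration pipeline.

Every external format the pipeline touches is plain text: tab-separated
matrices for expression values and detection flags, a sample design table,
two-column pair tables for predicted miRNA->target edges, FASTA for promoter
sequences, and a three-column gene/term annotation table.

Identifier normalization is applied once, in the readers, and identically
everywhere: mature miRNA names are lowercased ("hsa-miR-96" -> "hsa-mir-96")
because their capitalization is inconsistent across sources, while gene
symbols are uppercased. Joins between pair tables and expression features
therefore work by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"

RAW = "raw"
LOG2_CENTERED = "log2_centered"

UNCLASSIFIED = "unclassified"


def normalize_mirna_id(name: str) -> str:
    """Lowercase and strip a mature miRNA name. Idempotent."""
    return name.strip().lower()


def normalize_gene_id(name: str) -> str:
    """Uppercase and strip a gene symbol. Idempotent."""
    return name.strip().upper()


_NORMALIZERS = {"gene": normalize_gene_id, "mirna": normalize_mirna_id}


def normalize_feature_ids(ids: Iterable[str], feature_kind: str) -> list[str]:
    try:
        norm = _NORMALIZERS[feature_kind]
    except KeyError:
        raise ValueError(f"feature_kind must be 'gene' or 'mirna', got {feature_kind!r}")
    return [norm(i) for i in ids]


@dataclass
class ExpressionBundle:
    """Paired tumor/normal expression matrices with per-cell detection calls.

    ``values`` and ``detection`` are features x samples DataFrames sharing
    index and columns. ``design`` maps each sample to a (patient, tissue)
    pair; every patient appears exactly once as tumor and once as normal.
    """

    values: pd.DataFrame
    detection: pd.DataFrame
    design: list[tuple[str, str]]  # (patient_id, tissue) per sample column
    scale: str = RAW
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.shape != self.detection.shape:
            raise ValueError(
                f"values {self.values.shape} and detection {self.detection.shape} "
                "dimension mismatch"
            )
        if not self.values.index.equals(self.detection.index) or not self.values.columns.equals(
            self.detection.columns
        ):
            raise ValueError("values and detection must share feature ids and sample ids")
        if len(self.design) != self.values.shape[1]:
            raise ValueError(
                f"design lists {len(self.design)} samples but values has "
                f"{self.values.shape[1]} columns"
            )
        if self.scale not in (RAW, LOG2_CENTERED):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        seen: dict[str, set[str]] = {}
        for patient, tissue in self.design:
            if tissue not in (TUMOR, NORMAL):
                raise ValueError(f"tissue must be {TUMOR!r} or {NORMAL!r}, got {tissue!r}")
            if tissue in seen.setdefault(patient, set()):
                raise ValueError(f"unpaired design: patient {patient!r} listed twice as {tissue}")
            seen[patient].add(tissue)
        incomplete = [p for p, t in seen.items() if len(t) != 2]
        if incomplete:
            raise ValueError(f"unpaired design: patients missing one tissue: {incomplete}")

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def patients(self) -> list[str]:
        out: list[str] = []
        for patient, _ in self.design:
            if patient not in out:
                out.append(patient)
        return out

    def sample_of(self, patient: str, tissue: str) -> str:
        for sid, (p, t) in zip(self.values.columns, self.design):
            if p == patient and t == tissue:
                return sid
        raise KeyError(f"no sample for patient {patient!r}, tissue {tissue!r}")

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionBundle":
        return replace(
            self,
            values=self.values.loc[list(feature_ids)],
            detection=self.detection.loc[list(feature_ids)],
        )


@dataclass(frozen=True)
class TargetMap:
    """Predictor-labelled bipartite map of (mirna_id, gene_id) pairs."""

    predictor_label: str
    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, predictor_label: str, pairs: Iterable[tuple[str, str]]) -> "TargetMap":
        normed = frozenset(
            (normalize_mirna_id(m), normalize_gene_id(g)) for m, g in pairs
        )
        return cls(predictor_label=predictor_label, pairs=normed)

    def __len__(self) -> int:
        return len(self.pairs)

    def mirnas(self) -> set[str]:
        return {m for m, _ in self.pairs}

    def genes(self) -> set[str]:
        return {g for _, g in self.pairs}

    def targets_of(self, mirna_id: str) -> set[str]:
        m = normalize_mirna_id(mirna_id)
        return {g for mm, g in self.pairs if mm == m}

    def by_mirna(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for m, g in self.pairs:
            out.setdefault(m, set()).add(g)
        return out

    def by_gene(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for m, g in self.pairs:
            out.setdefault(g, set()).add(m)
        return out


@dataclass
class DiffExpResult:
    """Per-feature paired differential-expression call."""

    feature_id: str
    direction: str  # up | down | none
    mean_delta: float
    d_stat: float | None = None
    q_value: float | None = None


@dataclass
class PromoterRecord:
    """Promoter sequence with its CpG-density class call."""

    gene_id: str
    sequence: str
    cpg_class: str = UNCLASSIFIED


@dataclass
class AnnotationTable:
    """Flat gene -> GO-term annotation (no DAG propagation)."""

    term_genes: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def restrict_to(self, universe: set[str]) -> "AnnotationTable":
        return AnnotationTable(
            term_genes={t: gs & universe for t, gs in self.term_genes.items()},
            term_names=dict(self.term_names),
        )

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.term_genes.values():
            out |= gs
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_design(path: str | Path) -> tuple[list[str], list[tuple[str, str]]]:
    """Read the sample design table (columns: sample_id, patient_id, tissue)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "tissue"}
    if not required.issubset(df.columns):
        raise ValueError(f"design file must have columns {sorted(required)}")
    samples = df["sample_id"].tolist()
    design = list(zip(df["patient_id"], df["tissue"].str.lower()))
    return samples, design


def read_expression_bundle(
    values_path: str | Path,
    detection_path: str | Path,
    design_path: str | Path,
    feature_kind: str = "gene",
) -> ExpressionBundle:
    """Read a paired expression dataset from three tab-separated files.

    The values and detection matrices share layout: first column feature id,
    header row sample ids. Detection entries are 0/1 (or True/False). The
    returned bundle has ``scale='raw'`` and normalized feature ids.
    """
    values = _read_matrix(values_path)
    detection = _read_matrix(detection_path).astype(bool)
    samples, design = read_design(design_path)
    if list(values.columns) != samples:
        # allow design to define sample order
        try:
            values = values[samples]
            detection = detection[samples]
        except KeyError as exc:
            raise ValueError(f"design sample ids do not match matrix columns: {exc}")
    values.index = normalize_feature_ids(values.index, feature_kind)
    detection.index = normalize_feature_ids(detection.index, feature_kind)
    return ExpressionBundle(
        values=values.astype(float),
        detection=detection,
        design=design,
        scale=RAW,
        feature_kind=feature_kind,
    )


def write_expression_bundle(
    bundle: ExpressionBundle,
    values_path: str | Path,
    detection_path: str | Path,
    design_path: str | Path,
) -> None:
    bundle.values.to_csv(values_path, sep="\t", index_label="feature_id")
    bundle.detection.astype(int).to_csv(detection_path, sep="\t", index_label="feature_id")
    pd.DataFrame(
        {
            "sample_id": bundle.sample_ids,
            "patient_id": [p for p, _ in bundle.design],
            "tissue": [t for _, t in bundle.design],
        }
    ).to_csv(design_path, sep="\t", index=False)


def detection_from_pvalues(pvalues: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Convert a detection p-value matrix to boolean calls (p < threshold)."""
    return pvalues < threshold


_PAIR_HEADER_TOKENS = {"mirna", "mirna_id", "mir", "gene", "gene_id", "target"}


def read_target_pairs(path: str | Path, predictor_label: str) -> TargetMap:
    """Read a two-column (mirna_id, gene_id) tab-separated pair table.

    An optional header row is recognised by its column tokens. Duplicate
    rows collapse to one pair; a malformed row raises with its line number.
    """
    pairs: set[tuple[str, str]] = set()
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if lineno == 1 and fields[0].strip().lower() in _PAIR_HEADER_TOKENS:
                continue
            pairs.add((normalize_mirna_id(fields[0]), normalize_gene_id(fields[1])))
            n_rows += 1
    if not pairs:
        logger.warning("%s: empty target-pair table for predictor %r", path, predictor_label)
    else:
        logger.info(
            "%s: %d rows -> %d unique %s pairs", path, n_rows, len(pairs), predictor_label
        )
    return TargetMap(predictor_label=predictor_label, pairs=frozenset(pairs))


def write_target_pairs(target_map: TargetMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for m, g in sorted(target_map.pairs):
            fh.write(f"{m}\t{g}\n")


def read_fasta_promoters(path: str | Path) -> list[PromoterRecord]:
    """Read promoter sequences; record id = gene id, sequences uppercased."""
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = normalize_gene_id(rec.id)
        if gene_id in seen:
            raise ValueError(f"{path}: duplicate gene id {gene_id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for {gene_id!r}")
        seen.add(gene_id)
        records.append(PromoterRecord(gene_id=gene_id, sequence=seq))
    return records


def write_fasta_promoters(records: Iterable[PromoterRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a gene/term table (columns: gene_id, term_id, term_name)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file must have columns {sorted(required)}")
    term_genes: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    names = df["term_name"] if "term_name" in df.columns else None
    for i, row in enumerate(df.itertuples(index=False)):
        gene = normalize_gene_id(row.gene_id)
        term = row.term_id.strip()
        term_genes.setdefault(term, set()).add(gene)
        if names is not None:
            term_names[term] = row.term_name
    return AnnotationTable(term_genes=term_genes, term_names=term_names)


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    rows = [
        (g, t, table.term_names.get(t, ""))
        for t, gs in sorted(table.term_genes.items())
        for g in sorted(gs)
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"]).to_csv(
        path, sep="\t", index=False
    )


def diffexp_to_frame(results: Sequence[DiffExpResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "direction": [r.direction for r in results],
            "mean_delta": [r.mean_delta for r in results],
            "d_stat": [r.d_stat for r in results],
            "q_value": [r.q_value for r in results],
        }
    )


def frame_to_diffexp(df: pd.DataFrame) -> list[DiffExpResult]:
    def _opt(v):
        return None if pd.isna(v) else float(v)

    return [
        DiffExpResult(
            feature_id=str(row.feature_id),
            direction=str(row.direction),
            mean_delta=float(row.mean_delta),
            d_stat=_opt(getattr(row, "d_stat", np.nan)),
            q_value=_opt(getattr(row, "q_value", np.nan)),
        )
        for row in df.itertuples(index=False)
    ]
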