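"""Shared data model and readers/writers for the tabular formats the pipeline touches.

Coordinate convention: 1-based, closed intervals for both mutations and
copy-number segments (MAF/SEG style).  Strand is ignored throughout.  All
readers accept gzip-compressed files transparently (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROOT_PARENT = -1
"""Parent id marking the root of a clone tree."""


class FormatError(ValueError):
    """Raised when a table is missing required columns or is structurally invalid."""


class TreeStructureError(ValueError):
    """Raised when a clone tree has cycles, multiple roots, or no root."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MutationRecord:
    """A single somatic SNV with supporting read counts.

    ``vaf`` is the variant-allele fraction: the fraction of reads overlapping
    the coordinate that support the non-reference allele.  It is derived from
    counts when both are present.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int | None = None
    ref_count: int | None = None
    gene: str | None = None
    vaf: float | None = None
    # filled by assemble_tumor_sample
    local_cn: float | None = None
    ccf_cnv: float = 1.0
    unassigned: bool = False

    def __post_init__(self) -> None:
        if self.vaf is None:
            if self.alt_count is None or self.ref_count is None:
                raise ValueError("need (alt_count, ref_count) or vaf")
            depth = self.alt_count + self.ref_count
            if depth <= 0:
                raise ValueError(
                    f"zero depth at {self.chrom}:{self.pos}; cannot derive vaf"
                )
            self.vaf = self.alt_count / depth
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")


@dataclass
class CopyNumberSegment:
    """A segment of constant log2 copy-ratio (SEG convention, 1-based closed)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    seg_mean: float
    abs_cn: float | None = None
    ccf_cnv: float = 1.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if not (0.0 <= self.ccf_cnv <= 1.0):
            raise ValueError(f"ccf_cnv {self.ccf_cnv} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass
class TumorSample:
    """Joined mutations + segments + purity for one tumor: the pipeline input unit."""

    sample_id: str
    purity: float
    mutations: list[MutationRecord] = field(default_factory=list)
    segments: list[CopyNumberSegment] = field(default_factory=list)
    cancer_type: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity {self.purity} outside (0, 1]")


@dataclass
class ExpressionMatrix:
    """Genes x samples grid of log-scale expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class CloneTreeNode:
    """One node (clone) in a subclone tree."""

    node_id: int
    parent_id: int  # ROOT_PARENT marks the root
    n_mutations: int
    prevalence: float

    def __post_init__(self) -> None:
        if self.n_mutations < 0:
            raise ValueError("negative mutation count")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError(f"prevalence {self.prevalence} outside [0, 1]")


@dataclass
class CloneTree:
    """Rooted clone tree with per-node mutation counts and cellular prevalences."""

    nodes: list[CloneTreeNode]
    log_likelihood: float | None = None
    prevalence_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_id = {n.node_id: n for n in self.nodes}
        if len(by_id) != len(self.nodes):
            raise TreeStructureError("duplicate node ids")
        roots = [n for n in self.nodes if n.parent_id == ROOT_PARENT]
        if len(roots) != 1:
            raise TreeStructureError(f"expected exactly one root, found {len(roots)}")
        # walk every node up to the root; a cycle or dangling parent fails
        for node in self.nodes:
            seen = {node.node_id}
            cur = node
            while cur.parent_id != ROOT_PARENT:
                if cur.parent_id not in by_id:
                    raise TreeStructureError(
                        f"node {cur.node_id} has unknown parent {cur.parent_id}"
                    )
                cur = by_id[cur.parent_id]
                if cur.node_id in seen:
                    raise TreeStructureError(f"cycle through node {cur.node_id}")
                seen.add(cur.node_id)
        tol = self.prevalence_tolerance
        for node in self.nodes:
            if node.parent_id != ROOT_PARENT:
                parent = by_id[node.parent_id]
                if node.prevalence > parent.prevalence + tol:
                    raise TreeStructureError(
                        f"child {node.node_id} prevalence {node.prevalence} exceeds "
                        f"parent {parent.node_id} prevalence {parent.prevalence}"
                    )

    @property
    def root(self) -> CloneTreeNode:
        return next(n for n in self.nodes if n.parent_id == ROOT_PARENT)

    def children(self, node_id: int) -> list[CloneTreeNode]:
        return [n for n in self.nodes if n.parent_id == node_id]

    def ancestors(self, node_id: int) -> list[int]:
        """Node ids on the path from ``node_id``'s parent up to the root."""
        by_id = {n.node_id: n for n in self.nodes}
        out: list[int] = []
        cur = by_id[node_id]
        while cur.parent_id != ROOT_PARENT:
            out.append(cur.parent_id)
            cur = by_id[cur.parent_id]
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_table(path: str | Path) -> pd.DataFrame:
    with _open_text(path) as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


_MUTATION_ALIASES = {
    "sample": "sample",
    "sample_id": "sample",
    "tumor_sample_barcode": "sample",
    "chrom": "chrom",
    "chromosome": "chrom",
    "pos": "pos",
    "start_position": "pos",
    "position": "pos",
    "ref": "ref",
    "reference_allele": "ref",
    "alt": "alt",
    "tumor_seq_allele2": "alt",
    "alt_count": "alt_count",
    "t_alt_count": "alt_count",
    "ref_count": "ref_count",
    "t_ref_count": "ref_count",
    "vaf": "vaf",
    "gene": "gene",
    "hugo_symbol": "gene",
}


def read_mutation_table(path: str | Path, dialect: str = "tsv") -> list[MutationRecord]:
    """Read a MAF-subset mutation TSV into :class:`MutationRecord` objects.

    Requires columns sample, chrom, pos, ref, alt and either
    (alt_count, ref_count) or vaf (MAF-style aliases accepted).  Rows that
    fail numeric coercion are skipped and reported with their line numbers.
    """
    df = _read_table(path)
    df.columns = [
        _MUTATION_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns
    ]
    required = {"sample", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    has_counts = {"alt_count", "ref_count"} <= set(df.columns)
    has_vaf = "vaf" in df.columns
    if not (has_counts or has_vaf):
        raise FormatError(f"{path}: need (alt_count, ref_count) or vaf columns")

    records: list[MutationRecord] = []
    bad_rows: list[int] = []
    for idx, row in df.iterrows():
        lineno = int(idx) + 2  # header is line 1
        try:
            kwargs: dict = dict(
                sample_id=str(row["sample"]),
                chrom=str(row["chrom"]),
                pos=int(float(row["pos"])),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                gene=str(row["gene"]) if "gene" in df.columns and pd.notna(row["gene"]) else None,
            )
            if has_counts and pd.notna(row["alt_count"]) and pd.notna(row["ref_count"]):
                kwargs["alt_count"] = int(float(row["alt_count"]))
                kwargs["ref_count"] = int(float(row["ref_count"]))
                if kwargs["alt_count"] < 0 or kwargs["ref_count"] < 0:
                    raise ValueError("negative read count")
            elif has_vaf and pd.notna(row["vaf"]):
                kwargs["vaf"] = float(row["vaf"])
            else:
                raise ValueError("no usable counts or vaf")
            records.append(MutationRecord(**kwargs))
        except (ValueError, TypeError):
            bad_rows.append(lineno)
    if bad_rows:
        logger.warning(
            "%s: skipped %d malformed rows (lines %s)", path, len(bad_rows), bad_rows
        )
    return records


_SEG_ALIASES = {
    "sample": "sample",
    "sample_id": "sample",
    "id": "sample",
    "chrom": "chrom",
    "chromosome": "chrom",
    "start": "start",
    "loc.start": "start",
    "end": "end",
    "loc.end": "end",
    "seg_mean": "seg_mean",
    "segment_mean": "seg_mean",
    "seg.mean": "seg_mean",
    "num_mark": "num_mark",
    "num_probes": "num_mark",
    "num.mark": "num_mark",
}


def read_seg_file(path: str | Path) -> list[CopyNumberSegment]:
    """Read a SEG file (Broad dialect) into segments sorted by (chrom, start).

    ``abs_cn`` is left unset; it is computed downstream from ``seg_mean``.
    Overlapping segments for one sample are retained with a warning.
    """
    df = _read_table(path)
    df.columns = [
        _SEG_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns
    ]
    required = {"sample", "chrom", "start", "end", "seg_mean"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    segments: list[CopyNumberSegment] = []
    bad_rows: list[int] = []
    for idx, row in df.iterrows():
        try:
            segments.append(
                CopyNumberSegment(
                    sample_id=str(row["sample"]),
                    chrom=str(row["chrom"]),
                    start=int(float(row["start"])),
                    end=int(float(row["end"])),
                    seg_mean=float(row["seg_mean"]),
                )
            )
        except (ValueError, TypeError):
            bad_rows.append(int(idx) + 2)
    if bad_rows:
        logger.warning("%s: skipped %d malformed rows %s", path, len(bad_rows), bad_rows)
    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start))
    _warn_overlaps(segments, path)
    return segments


def _warn_overlaps(segments: Sequence[CopyNumberSegment], path: str | Path) -> None:
    for prev, cur in zip(segments, segments[1:]):
        if (
            prev.sample_id == cur.sample_id
            and prev.chrom == cur.chrom
            and cur.start <= prev.end
        ):
            logger.warning(
                "%s: overlapping segments %s:%d-%d and %s:%d-%d in %s",
                path, prev.chrom, prev.start, prev.end,
                cur.chrom, cur.start, cur.end, cur.sample_id,
            )


def read_purity_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (sample, purity) TSV; purity must lie in (0, 1]."""
    df = _read_table(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample" not in df.columns and "sample_id" in df.columns:
        df = df.rename(columns={"sample_id": "sample"})
    if not {"sample", "purity"} <= set(df.columns):
        raise FormatError(f"{path}: need columns sample, purity")
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        purity = float(row["purity"])
        if not (0.0 < purity <= 1.0):
            raise ValueError(f"purity {purity} for {row['sample']} outside (0, 1]")
        out[str(row["sample"])] = purity
    return out


def assemble_tumor_sample(
    mutations: Iterable[MutationRecord],
    segments: Iterable[CopyNumberSegment],
    purity: float,
    sample_id: str,
    cancer_type: str = "",
    default_cn: float = 2.0,
) -> TumorSample:
    """Join mutations to overlapping copy-number segments for one tumor.

    Each mutation is annotated with the total copy number of the smallest
    overlapping segment (ties logged).  Mutations overlapping no segment are
    flagged ``unassigned`` and given the diploid default, under which the CCF
    formula reduces to its copy-neutral case.  No mutation is ever dropped.
    """
    muts = [m for m in mutations if m.sample_id == sample_id]
    segs = [s for s in segments if s.sample_id == sample_id]
    for m in muts:
        hits = [s for s in segs if s.contains(m.chrom, m.pos)]
        if not hits:
            m.local_cn = default_cn
            m.ccf_cnv = 1.0
            m.unassigned = True
            continue
        if len(hits) > 1:
            logger.info(
                "%s:%d overlaps %d segments; choosing smallest", m.chrom, m.pos, len(hits)
            )
        best = min(hits, key=lambda s: s.length)
        if best.abs_cn is None:
            # late import avoids a module cycle; the conversion lives with the
            # CCF math it feeds
            from .ccf import abs_cn_from_segmean

            best.abs_cn = abs_cn_from_segmean(best.seg_mean)
        m.local_cn = best.abs_cn
        m.ccf_cnv = best.ccf_cnv
        m.unassigned = False
    return TumorSample(
        sample_id=sample_id,
        purity=purity,
        mutations=muts,
        segments=segs,
        cancer_type=cancer_type,
    )


def read_clone_trees(path: str | Path) -> list[CloneTree]:
    """Read clone trees from JSON (a list of trees, each with ``nodes``).

    Each node needs ``id``, ``parent`` (null or absent for the root),
    ``n_mutations`` and ``prevalence``; ``log_likelihood`` per tree is
    optional.  Input ordering is preserved; invariants are checked.
    """
    with _open_text(path) as fh:
        payload = json.load(fh)
    trees_raw = payload["trees"] if isinstance(payload, dict) else payload
    trees: list[CloneTree] = []
    for tree_raw in trees_raw:
        nodes = [
            CloneTreeNode(
                node_id=int(n["id"]),
                parent_id=ROOT_PARENT if n.get("parent") is None else int(n["parent"]),
                n_mutations=int(n["n_mutations"]),
                prevalence=float(n["prevalence"]),
            )
            for n in tree_raw["nodes"]
        ]
        ll = tree_raw.get("log_likelihood")
        trees.append(CloneTree(nodes=nodes, log_likelihood=None if ll is None else float(ll)))
    return trees


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------


def write_mutation_table(records: Sequence[MutationRecord], path: str | Path) -> None:
    rows = [
        {
            "sample": r.sample_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "alt_count": r.alt_count,
            "ref_count": r.ref_count,
            "vaf": r.vaf,
            "gene": r.gene,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_seg_file(segments: Sequence[CopyNumberSegment], path: str | Path) -> None:
    rows = [
        {
            "Sample": s.sample_id,
            "Chromosome": s.chrom,
            "Start": s.start,
            "End": s.end,
            "Num_Probes": s.length,
            "Segment_Mean": s.seg_mean,
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_purity_table(purities: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(purities), "purity": list(purities.values())}
    ).to_csv(path, sep="\t", index=False)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix.from_frame(df)


def write_clone_trees(trees: Sequence[CloneTree], path: str | Path) -> None:
    payload = [
        {
            "log_likelihood": t.log_likelihood,
            "nodes": [
                {
                    "id": n.node_id,
                    "parent": None if n.parent_id == ROOT_PARENT else n.parent_id,
                    "n_mutations": n.n_mutations,
                    "prevalence": n.prevalence,
                }
                for n in t.nodes
            ],
        }
        for t in trees
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
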