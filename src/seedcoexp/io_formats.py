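"""Readers, writers and validated containers for every external artifact.

All tabular formats are plain text (TSV/CSV), all outputs are written with
deterministic ordering so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .coexpression_network import CoexpressionNetwork

ANNOTATION_NAMESPACES = ("tf_family", "pathway_category")
NETWORK_FORMATS = ("sif", "edge_tsv", "graphml")

def _fmt(value: float) -> str:
    """Shortest repr that round-trips IEEE doubles exactly; keeps output
    both lossless and human-readable."""
    return repr(float(value))


class FormatError(ValueError):
    """Raised when an external file violates the expected layout."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-stage matrix of non-negative FPKM values.

    Rows are genes, columns are ordered developmental stages. This is the
    substrate of every filter and of all correlation computations.
    """

    gene_ids: tuple[str, ...]
    stage_labels: tuple[str, ...]
    values: np.ndarray

    def __init__(self, gene_ids: Iterable[str], stage_labels: Iterable[str],
                 values: np.ndarray) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in gene_ids))
        object.__setattr__(self, "stage_labels",
                           tuple(str(s) for s in stage_labels))
        arr = np.asarray(values, dtype=float)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        self._validate()

    def _validate(self) -> None:
        if not self.gene_ids:
            raise ValueError("expression matrix has no genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids
                            if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        if len(set(self.stage_labels)) != len(self.stage_labels):
            raise ValueError("duplicate stage labels")
        if len(self.stage_labels) < 3:
            raise ValueError("at least 3 stages are required "
                             "(correlation on fewer is degenerate)")
        if self.values.shape != (len(self.gene_ids), len(self.stage_labels)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.stage_labels)} stages")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None
        return self.values[i]

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """Row-subset preserving the given gene order."""
        wanted = list(gene_ids)
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in wanted]  # KeyError on unknown gene
        return ExpressionMatrix(wanted, self.stage_labels, self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.stage_labels))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.index, frame.columns, frame.to_numpy(dtype=float))


@dataclass(frozen=True)
class CountMatrix:
    """Fragment counts plus the per-gene lengths and per-stage library sizes
    needed to derive FPKM."""

    gene_ids: tuple[str, ...]
    stage_labels: tuple[str, ...]
    counts: np.ndarray
    gene_lengths: Mapping[str, float]
    library_sizes: Mapping[str, float]

    def __init__(self, gene_ids, stage_labels, counts, gene_lengths,
                 library_sizes) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in gene_ids))
        object.__setattr__(self, "stage_labels",
                           tuple(str(s) for s in stage_labels))
        arr = np.asarray(counts)
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "gene_lengths", dict(gene_lengths))
        object.__setattr__(self, "library_sizes", dict(library_sizes))
        self._validate()

    def _validate(self) -> None:
        if self.counts.shape != (len(self.gene_ids), len(self.stage_labels)):
            raise ValueError("count shape does not match gene/stage labels")
        if np.any(self.counts < 0) or not np.all(np.isfinite(
                np.asarray(self.counts, dtype=float))):
            raise ValueError("counts must be finite and non-negative")
        for g in self.gene_ids:
            length = self.gene_lengths.get(g)
            if length is None:
                raise ValueError(f"gene {g!r} has no length")
            if length <= 0:
                raise ValueError(f"gene {g!r} has non-positive length {length}")
        for s in self.stage_labels:
            size = self.library_sizes.get(s)
            if size is None:
                raise ValueError(f"stage {s!r} has no library size")
            if size <= 0:
                raise ValueError(
                    f"stage {s!r} has non-positive library size {size}")


def _read_table(path: str | Path, dialect: str) -> pd.DataFrame:
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; expected tsv or csv")
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed table: {exc}") from exc
    return frame


def read_expression_matrix(path: str | Path,
                           dialect: str = "tsv") -> ExpressionMatrix:
    """Read a gene-by-stage matrix: header row of stage labels, first column
    gene ids. Column order defines stage order."""
    frame = _read_table(path, dialect)
    dupes = frame.index[frame.index.duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate gene id(s): {dupes}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                raise FormatError(
                    f"{path}: missing value at gene {frame.index[i]!r}, "
                    f"stage {col!r}")
            try:
                v = float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {raw!r} at gene "
                    f"{frame.index[i]!r}, stage {col!r}") from None
            if v < 0:
                raise FormatError(
                    f"{path}: negative value {v} at gene "
                    f"{frame.index[i]!r}, stage {col!r}")
            values[i, j] = v
    return ExpressionMatrix(frame.index, frame.columns, values)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; expected tsv or csv")
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene",
                             float_format=None, lineterminator="\n")


def read_count_matrix(counts_path: str | Path, lengths_path: str | Path,
                      library_sizes_path: str | Path,
                      dialect: str = "tsv") -> CountMatrix:
    """Counts table laid out like the expression matrix; lengths and library
    sizes as two-column TSVs (gene/length, stage/library_size)."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    counts = pd.read_csv(counts_path, sep=sep, index_col=0)
    lengths = pd.read_csv(lengths_path, sep=sep, index_col=0)
    sizes = pd.read_csv(library_sizes_path, sep=sep, index_col=0)
    return CountMatrix(counts.index, counts.columns,
                       counts.to_numpy(),
                       lengths.iloc[:, 0].to_dict(),
                       sizes.iloc[:, 0].to_dict())


def write_count_matrix(cm: CountMatrix, counts_path: str | Path,
                       lengths_path: str | Path,
                       library_sizes_path: str | Path) -> None:
    pd.DataFrame(cm.counts, index=list(cm.gene_ids),
                 columns=list(cm.stage_labels)).to_csv(
        counts_path, sep="\t", index_label="gene", lineterminator="\n")
    pd.DataFrame({"length": [cm.gene_lengths[g] for g in cm.gene_ids]},
                 index=list(cm.gene_ids)).to_csv(
        lengths_path, sep="\t", index_label="gene", lineterminator="\n")
    pd.DataFrame({"library_size": [cm.library_sizes[s]
                                   for s in cm.stage_labels]},
                 index=list(cm.stage_labels)).to_csv(
        library_sizes_path, sep="\t", index_label="stage", lineterminator="\n")


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTable:
    """Multi-label gene annotation in two namespaces: ``tf_family`` and
    ``pathway_category``. Genes may be absent (unannotated)."""

    _data: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def add(self, gene: str, namespace: str, label: str) -> None:
        if namespace not in ANNOTATION_NAMESPACES:
            raise ValueError(
                f"unknown namespace {namespace!r}; "
                f"expected one of {ANNOTATION_NAMESPACES}")
        if not label:
            raise ValueError(f"empty label for gene {gene!r}")
        self._data.setdefault(gene, {}).setdefault(namespace, set()).add(label)

    def labels(self, gene: str, namespace: str) -> frozenset[str]:
        if namespace not in ANNOTATION_NAMESPACES:
            raise ValueError(f"unknown namespace {namespace!r}")
        return frozenset(self._data.get(gene, {}).get(namespace, set()))

    def tf_families(self, gene: str) -> frozenset[str]:
        return self.labels(gene, "tf_family")

    def is_annotated(self, gene: str, namespace: str) -> bool:
        return bool(self.labels(gene, namespace))

    def genes(self, namespace: str | None = None) -> frozenset[str]:
        if namespace is None:
            return frozenset(self._data)
        return frozenset(g for g in self._data
                         if self._data[g].get(namespace))

    def __len__(self) -> int:
        return len(self._data)


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """3-column TSV: gene, namespace, label."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["gene", "namespace", "label"]
    if list(frame.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, "
                          f"got {list(frame.columns)}")
    table = AnnotationTable()
    for row in frame.itertuples(index=False):
        try:
            table.add(row.gene, row.namespace, row.label)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return table


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    rows = []
    for gene in sorted(table.genes()):
        for ns in ANNOTATION_NAMESPACES:
            for label in sorted(table.labels(gene, ns)):
                rows.append((gene, ns, label))
    pd.DataFrame(rows, columns=["gene", "namespace", "label"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrRecord:
    gene_id: str
    stage_label: str
    replicate_index: int  # >= 1
    ct: float
    is_reference: bool


@dataclass(frozen=True)
class QpcrTable:
    """Per-gene, per-stage, per-replicate Ct values with reference-gene rows.

    Invariant: the reference gene is measured at every (stage, replicate)
    where any target gene is measured.
    """

    records: tuple[QpcrRecord, ...]
    calibrator_stage: str

    def __init__(self, records: Iterable[QpcrRecord],
                 calibrator_stage: str) -> None:
        object.__setattr__(self, "records", tuple(records))
        object.__setattr__(self, "calibrator_stage", str(calibrator_stage))
        self._validate()

    def _validate(self) -> None:
        if not self.records:
            raise ValueError("qPCR table is empty")
        ref_cells = set()
        target_cells = set()
        for rec in self.records:
            if not np.isfinite(rec.ct):
                raise ValueError(
                    f"non-finite Ct for {rec.gene_id!r} at "
                    f"{rec.stage_label!r} replicate {rec.replicate_index}")
            if rec.replicate_index < 1:
                raise ValueError("replicate_index must be >= 1")
            cell = (rec.stage_label, rec.replicate_index)
            (ref_cells if rec.is_reference else target_cells).add(cell)
        missing = sorted(target_cells - ref_cells)
        if missing:
            stage, rep = missing[0]
            raise ValueError(
                f"missing reference measurement at stage {stage!r} "
                f"replicate {rep}")
        if self.calibrator_stage not in self.stages():
            raise ValueError(
                f"calibrator stage {self.calibrator_stage!r} has no records")

    def stages(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.stage_label)
        return tuple(seen)

    def target_genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            if not rec.is_reference:
                seen.setdefault(rec.gene_id)
        return tuple(seen)

    def reference_genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            if rec.is_reference:
                seen.setdefault(rec.gene_id)
        return tuple(seen)


def _stage_sort_key(label: str):
    """Order stage labels numerically under the '<int>DAF' convention,
    falling back to plain string order."""
    if label.upper().endswith("DAF"):
        head = label[:-3]
        if head.isdigit():
            return (0, int(head), label)
    return (1, 0, label)


def read_qpcr_table(path: str | Path,
                    calibrator_stage: str | None = None) -> QpcrTable:
    """5-column CSV: gene, stage, replicate, ct, is_reference.

    When ``calibrator_stage`` is omitted the earliest stage (by the
    ``<int>DAF`` convention, else first appearance) is used.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["gene", "stage", "replicate", "ct", "is_reference"]
    if list(frame.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, "
                          f"got {list(frame.columns)}")
    records = []
    for row in frame.itertuples(index=False):
        flag = row.is_reference.strip().lower()
        if flag not in {"true", "false", "0", "1"}:
            raise FormatError(
                f"{path}: is_reference must be boolean, got {row.is_reference!r}")
        records.append(QpcrRecord(
            gene_id=row.gene,
            stage_label=row.stage,
            replicate_index=int(row.replicate),
            ct=float(row.ct),
            is_reference=flag in {"true", "1"},
        ))
    if calibrator_stage is None:
        stages = {r.stage_label for r in records}
        calibrator_stage = min(stages, key=_stage_sort_key)
    try:
        return QpcrTable(records, calibrator_stage)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_qpcr_table(table: QpcrTable, path: str | Path) -> None:
    rows = [(r.gene_id, r.stage_label, r.replicate_index,
             _fmt(r.ct), str(r.is_reference).lower())
            for r in table.records]
    pd.DataFrame(rows, columns=["gene", "stage", "replicate", "ct",
                                "is_reference"]).to_csv(
        path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Thresholds for the whole pipeline. Defaults mirror the published
    analysis: FPKM > 1 in all samples, two-fold variability, exclusion when
    silent in >= 60% of stages, |r| > 0.95 network edges with a 0.6
    prefilter, |log2FC| > 1 and FDR < 0.05 DEG calls."""

    min_fpkm_all_samples: float = 1.0
    fold_change_min: float = 2.0
    presence_exclusion_fraction: float = 0.6
    detection_floor: float = 0.0
    correlation_threshold: float = 0.95
    prefilter_threshold: float = 0.6
    threshold_mode: str = "absolute"
    log2fc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    pseudocount: float = 1.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.presence_exclusion_fraction <= 1:
            raise ValueError("presence_exclusion_fraction must be in (0, 1]")
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in (0, 1]")
        if self.prefilter_threshold > self.correlation_threshold:
            raise ValueError(
                "prefilter_threshold must not exceed correlation_threshold")
        if self.threshold_mode not in ("absolute", "positive_only"):
            raise ValueError("threshold_mode must be absolute or positive_only")
        if self.min_fpkm_all_samples < 0:
            raise ValueError("min_fpkm_all_samples must be >= 0")
        if self.fold_change_min <= 1:
            raise ValueError("fold_change_min must be > 1")
        if not 0 <= self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in [0, 1]")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        unknown = set(mapping) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)


# ---------------------------------------------------------------------------
# Network export / import
# ---------------------------------------------------------------------------


def _sorted_edges(network: "CoexpressionNetwork"):
    return sorted(network.edges, key=lambda e: (e.gene_a, e.gene_b))


def write_network(network: "CoexpressionNetwork", path: str | Path,
                  format: str = "edge_tsv") -> None:
    """Export a coexpression network.

    ``sif`` uses interaction type ``co``; ``edge_tsv`` has columns source,
    target, r, sign; ``graphml`` stores r and sign as edge attributes.
    Node and edge order is lexicographic, so output is byte-stable.
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; "
                         f"supported: {NETWORK_FORMATS}")
    path = Path(path)
    edges = _sorted_edges(network)
    if format == "sif":
        lines = [f"{e.gene_a}\tco\t{e.gene_b}" for e in edges]
        linked = {n for e in edges for n in (e.gene_a, e.gene_b)}
        lines += [n for n in sorted(network.nodes) if n not in linked]
        path.write_text("".join(line + "\n" for line in lines))
    elif format == "edge_tsv":
        lines = ["source\ttarget\tr\tsign"]
        lines += [f"{e.gene_a}\t{e.gene_b}\t{_fmt(e.r)}\t{e.sign}"
                  for e in edges]
        path.write_text("".join(line + "\n" for line in lines))
    else:  # graphml
        import networkx as nx

        graph = nx.Graph()
        graph.graph["build_threshold"] = float(network.build_threshold)
        graph.graph["threshold_mode"] = network.threshold_mode
        for node in sorted(network.nodes):
            graph.add_node(node)
        for e in edges:
            graph.add_edge(e.gene_a, e.gene_b, r=float(e.r), sign=e.sign)
        nx.write_graphml(graph, path, named_key_ids=True)


def read_network(path: str | Path, format: str = "edge_tsv",
                 build_threshold: float | None = None,
                 threshold_mode: str = "absolute"):
    """Re-import a network written by :func:`write_network` (edge_tsv or
    graphml)."""
    from .coexpression_network import CoexpressionEdge, CoexpressionNetwork

    if format not in ("edge_tsv", "graphml"):
        raise ValueError(f"cannot read network format {format!r}")
    path = Path(path)
    if format == "edge_tsv":
        frame = pd.read_csv(path, sep="\t", dtype={"source": str,
                                                   "target": str})
        edges = [CoexpressionEdge(row.source, row.target, float(row.r))
                 for row in frame.itertuples(index=False)]
        nodes = {n for e in edges for n in (e.gene_a, e.gene_b)}
        threshold = 0.0 if build_threshold is None else build_threshold
        return CoexpressionNetwork(nodes, edges, threshold, threshold_mode)
    import networkx as nx

    graph = nx.read_graphml(path)
    edges = [CoexpressionEdge(str(a), str(b), float(data["r"]))
             for a, b, data in graph.edges(data=True)]
    threshold = build_threshold
    if threshold is None:
        threshold = float(graph.graph.get("build_threshold", 0.0))
    mode = graph.graph.get("threshold_mode", threshold_mode)
    return CoexpressionNetwork(set(map(str, graph.nodes)), edges,
                               threshold, mode)


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    """One gene id per line, sorted."""
    Path(path).write_text("".join(g + "\n" for g in sorted(genes)))


def read_gene_set(path: str | Path) -> frozenset[str]:
    return frozenset(line.strip() for line in
                     Path(path).read_text().splitlines() if line.strip())
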