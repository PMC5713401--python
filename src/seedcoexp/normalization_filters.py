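"""FPKM computation, expression filters, DEG thresholding with BH control,
pairwise DEG count matrices and Z-score profiles.

The differential test itself is external (p-values are optional inputs);
this module owns only the fold-change/FDR thresholding and the
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, ExpressionMatrix, PipelineConfig


def compute_fpkm(counts: CountMatrix) -> ExpressionMatrix:
    """FPKM(g, s) = counts(g, s) * 1e9 / (length(g) * library_size(s))."""
    lengths = np.array([counts.gene_lengths[g] for g in counts.gene_ids],
                       dtype=float)
    libsizes = np.array([counts.library_sizes[s] for s in counts.stage_labels],
                        dtype=float)
    # CountMatrix validation guarantees positivity; re-check defensively
    if np.any(lengths <= 0) or np.any(libsizes <= 0):
        raise ValueError("gene lengths and library sizes must be positive")
    values = np.asarray(counts.counts, dtype=float) * 1e9
    values /= lengths[:, None]
    values /= libsizes[None, :]
    return ExpressionMatrix(counts.gene_ids, counts.stage_labels, values)


def filter_widely_expressed(m: ExpressionMatrix,
                            min_fpkm: float = 1.0) -> frozenset[str]:
    """Genes expressed above ``min_fpkm`` in EVERY stage (strict inequality)."""
    if min_fpkm < 0:
        raise ValueError("min_fpkm must be >= 0")
    keep = np.all(m.values > min_fpkm, axis=1)
    return frozenset(g for g, k in zip(m.gene_ids, keep) if k)


def filter_fold_range(m: ExpressionMatrix, fold_min: float = 2.0,
                      pseudocount: float = 0.0) -> frozenset[str]:
    """Genes whose stage-wise max/min ratio exceeds ``fold_min``.

    The ratio is (max + pseudocount) / (min + pseudocount); the default
    pseudocount is 0 because this filter normally runs downstream of
    ``filter_widely_expressed`` where all values exceed 1.
    """
    if fold_min <= 1:
        raise ValueError("fold_min must be > 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    hi = m.values.max(axis=1) + pseudocount
    lo = m.values.min(axis=1) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / lo, np.inf)
    ratio = np.where((hi == 0) & (lo == 0), 1.0, ratio)  # all-zero gene: flat
    keep = ratio > fold_min
    return frozenset(g for g, k in zip(m.gene_ids, keep) if k)


def presence_filter(m: ExpressionMatrix, exclusion_fraction: float = 0.6,
                    detection_floor: float = 0.0) -> frozenset[str]:
    """Exclude genes undetected (value <= floor) in at least
    ``exclusion_fraction`` of the stages; return the retained set."""
    if not 0 < exclusion_fraction <= 1:
        raise ValueError("exclusion_fraction must be in (0, 1]")
    absent = (m.values <= detection_floor).sum(axis=1)
    frac = absent / m.n_stages
    keep = frac < exclusion_fraction
    return frozenset(g for g, k in zip(m.gene_ids, keep) if k)


def log2_fold_change(a: float, b: float, pseudocount: float = 1.0) -> float:
    """log2((b + pseudocount) / (a + pseudocount)); antisymmetric in (a, b)."""
    if a < 0 or b < 0:
        raise ValueError("expression values must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return math.log2((b + pseudocount) / (a + pseudocount))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank downwards
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out.tolist()


@dataclass(frozen=True)
class DEGRecord:
    """One pairwise differential-expression call (stage_b relative to
    stage_a)."""

    gene_id: str
    stage_a: str
    stage_b: str
    log2fc: float
    pvalue: float | None = None
    fdr: float | None = None
    call: str = "ns"


def classify_deg(records: Iterable[DEGRecord | Mapping],
                 config: PipelineConfig | None = None) -> list[DEGRecord]:
    """Apply the thresholding rule: up iff log2fc > threshold and (FDR absent
    or FDR < fdr_threshold); symmetric for down; otherwise ns.

    Records carrying p-values but no FDR get a BH adjustment computed across
    the whole input collection.
    """
    config = config or PipelineConfig()
    recs: list[DEGRecord] = []
    for r in records:
        if isinstance(r, Mapping):
            r = DEGRecord(gene_id=r["gene_id"], stage_a=r.get("stage_a", ""),
                          stage_b=r.get("stage_b", ""), log2fc=r["log2fc"],
                          pvalue=r.get("pvalue"), fdr=r.get("fdr"))
        recs.append(r)
    need_fdr = [i for i, r in enumerate(recs)
                if r.fdr is None and r.pvalue is not None]
    if need_fdr:
        adjusted = bh_adjust([recs[i].pvalue for i in need_fdr])
        for i, q in zip(need_fdr, adjusted):
            r = recs[i]
            recs[i] = DEGRecord(r.gene_id, r.stage_a, r.stage_b, r.log2fc,
                                r.pvalue, q, r.call)
    out = []
    for r in recs:
        significant = r.fdr is None or r.fdr < config.fdr_threshold
        if significant and r.log2fc > config.log2fc_threshold:
            call = "up"
        elif significant and r.log2fc < -config.log2fc_threshold:
            call = "down"
        else:
            call = "ns"
        out.append(DEGRecord(r.gene_id, r.stage_a, r.stage_b, r.log2fc,
                             r.pvalue, r.fdr, call))
    return out


@dataclass(frozen=True)
class DEGCountMatrix:
    """Up/down-regulated gene counts for every ordered stage pair."""

    stage_labels: tuple[str, ...]
    n_up: Mapping[tuple[str, str], int]
    n_down: Mapping[tuple[str, str], int]

    def up(self, stage_a: str, stage_b: str) -> int:
        return self.n_up.get((stage_a, stage_b), 0)

    def down(self, stage_a: str, stage_b: str) -> int:
        return self.n_down.get((stage_a, stage_b), 0)

    def to_frame(self) -> pd.DataFrame:
        """Lower-triangular display of 'Nup Ndown' strings, diagonal 0."""
        stages = list(self.stage_labels)
        data = [["" for _ in stages] for _ in stages]
        for i, b in enumerate(stages):
            for j, a in enumerate(stages):
                if i == j:
                    data[i][j] = "0"
                elif j < i:
                    data[i][j] = f"{self.up(a, b)}u {self.down(a, b)}d"
        return pd.DataFrame(data, index=stages, columns=stages)


def deg_count_matrix(m: ExpressionMatrix,
                     config: PipelineConfig | None = None,
                     pvalues: Mapping[tuple[str, str], Mapping[str, float]]
                     | None = None) -> DEGCountMatrix:
    """Count up/down calls for every ordered stage pair.

    ``pvalues`` optionally supplies per-gene p-values per ordered pair
    (the external test); absent p-values mean fold-change-only calls.
    """
    if m.n_stages < 2:
        raise ValueError("need at least 2 stages")
    config = config or PipelineConfig()
    stages = m.stage_labels
    col = {s: i for i, s in enumerate(stages)}
    n_up: dict[tuple[str, str], int] = {}
    n_down: dict[tuple[str, str], int] = {}
    for a in stages:
        for b in stages:
            if a == b:
                continue
            pair_pvals = (pvalues or {}).get((a, b), {})
            records = []
            for gi, g in enumerate(m.gene_ids):
                lfc = log2_fold_change(m.values[gi, col[a]],
                                       m.values[gi, col[b]],
                                       config.pseudocount)
                records.append(DEGRecord(g, a, b, lfc,
                                         pvalue=pair_pvals.get(g)))
            calls = classify_deg(records, config)
            n_up[(a, b)] = sum(r.call == "up" for r in calls)
            n_down[(a, b)] = sum(r.call == "down" for r in calls)
    return DEGCountMatrix(stages, n_up, n_down)


@dataclass(frozen=True)
class ProfileMatrix:
    """Per-gene Z-score profiles; constant genes are flagged and zeroed."""

    gene_ids: tuple[str, ...]
    stage_labels: tuple[str, ...]
    z: np.ndarray
    constant_genes: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=list(self.gene_ids),
                            columns=list(self.stage_labels))


def zscore_profiles(m: ExpressionMatrix) -> ProfileMatrix:
    """Standardize each gene across stages with the sample (n-1) standard
    deviation. Constant genes get all-zero rows and are flagged."""
    if m.n_stages < 2:
        raise ValueError("need at least 2 stages")
    means = m.values.mean(axis=1, keepdims=True)
    sds = m.values.std(axis=1, ddof=1, keepdims=True)
    constant = sds[:, 0] == 0
    safe = np.where(sds == 0, 1.0, sds)
    z = (m.values - means) / safe
    z[constant, :] = 0.0
    return ProfileMatrix(m.gene_ids, m.stage_labels, z,
                         frozenset(g for g, c in zip(m.gene_ids, constant)
                                   if c))
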