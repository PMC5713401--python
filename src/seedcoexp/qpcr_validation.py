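"""Relative quantification by the 2^-DDCt method and qPCR-vs-expression
concordance.

DCt = target Ct - reference Ct within the same (stage, replicate);
DDCt differences each replicate's DCt against the calibrator stage's mean
DCt (per gene), so the whole pipeline is invariant to any additive plate
shift applied to target and reference alike. Amplification efficiency is
fixed at 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .coexpression_network import pearson_r
from .io_formats import QpcrTable


def delta_ct(target_ct: float, reference_ct: float) -> float:
    """Ct difference against the internal reference gene."""
    if not (math.isfinite(target_ct) and math.isfinite(reference_ct)):
        raise ValueError("Ct values must be finite")
    return target_ct - reference_ct


def ddct_fold_change(sample_dct: float, calibrator_dct: float) -> float:
    """2^-(sample_dct - calibrator_dct); calibrator maps to 1."""
    if not (math.isfinite(sample_dct) and math.isfinite(calibrator_dct)):
        raise ValueError("dCt values must be finite")
    return 2.0 ** -(sample_dct - calibrator_dct)


@dataclass(frozen=True)
class RelativeExpression:
    """Fold change of one gene at one stage relative to the calibrator
    stage (2^-DDCt units)."""

    gene_id: str
    stage_label: str
    fold_change: float
    replicate_values: tuple[float, ...]
    mean: float
    sd: float


def relative_expression_table(q: QpcrTable, mode: str = "per_replicate"
                              ) -> list[RelativeExpression]:
    """Fold changes for every (target gene, stage).

    per_replicate: each replicate's DCt is differenced against the gene's
    mean calibrator DCt, giving per-replicate fold changes whose mean/sd are
    reported. mean_of_means: fold changes are computed from stage-mean DCt,
    making the calibrator exactly 1.
    """
    if mode not in ("per_replicate", "mean_of_means"):
        raise ValueError("mode must be per_replicate or mean_of_means")

    ref_ct: dict[tuple[str, int], float] = {}
    for rec in q.records:
        if rec.is_reference:
            ref_ct[(rec.stage_label, rec.replicate_index)] = rec.ct

    # per (gene, stage): list of per-replicate dCt
    dct: dict[tuple[str, str], list[float]] = {}
    for rec in q.records:
        if rec.is_reference:
            continue
        key = (rec.gene_id, rec.stage_label)
        dct.setdefault(key, []).append(
            delta_ct(rec.ct, ref_ct[(rec.stage_label, rec.replicate_index)]))

    out = []
    for gene in q.target_genes():
        cal = dct.get((gene, q.calibrator_stage))
        if not cal:
            raise ValueError(
                f"gene {gene!r} has no measurements at calibrator stage "
                f"{q.calibrator_stage!r}")
        cal_mean_dct = float(np.mean(cal))
        for stage in q.stages():
            reps = dct.get((gene, stage))
            if not reps:
                continue
            if mode == "per_replicate":
                folds = tuple(ddct_fold_change(d, cal_mean_dct)
                              for d in reps)
                mean = float(np.mean(folds))
            else:
                fold = ddct_fold_change(float(np.mean(reps)), cal_mean_dct)
                folds = (fold,)
                mean = fold
            sd = float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0
            out.append(RelativeExpression(
                gene_id=gene, stage_label=stage, fold_change=mean,
                replicate_values=folds, mean=mean, sd=sd))
    return out


def concordance(rnaseq_profile: Mapping[str, float],
                qpcr_profile: Mapping[str, float],
                log2: bool = True, pseudocount: float = 1e-9) -> float:
    """Pearson r between an RNA-seq stage profile and a qPCR fold-change
    profile aligned by stage label.

    By default both profiles are log2-transformed (fold changes are ratios,
    FPKM is heavy-tailed); raw mode compares the values as given.
    """
    stages_a = set(rnaseq_profile)
    stages_b = set(qpcr_profile)
    if stages_a != stages_b:
        raise ValueError(
            f"stage mismatch: only in RNA-seq {sorted(stages_a - stages_b)}, "
            f"only in qPCR {sorted(stages_b - stages_a)}")
    stages = sorted(stages_a)
    x = np.array([rnaseq_profile[s] for s in stages], dtype=float)
    y = np.array([qpcr_profile[s] for s in stages], dtype=float)
    if log2:
        if np.any(x < 0) or np.any(y <= 0):
            raise ValueError("log2 concordance requires non-negative FPKM "
                             "and positive fold changes")
        x = np.log2(x + pseudocount)
        y = np.log2(y)
    return pearson_r(x, y)


def concordance_report(
        expression_profiles: Mapping[str, Mapping[str, float]],
        relexpr: Sequence[RelativeExpression],
        log2: bool = True) -> tuple[dict[str, float], float, float]:
    """Per-gene concordance plus two pooled aggregates.

    Returns (per-gene r, pooled r over all (gene, stage) points, mean of
    per-gene r). Both aggregates are reported because published summaries
    rarely say which was used.
    """
    qpcr: dict[str, dict[str, float]] = {}
    for re_ in relexpr:
        qpcr.setdefault(re_.gene_id, {})[re_.stage_label] = re_.fold_change
    per_gene = {}
    pooled_x: list[float] = []
    pooled_y: list[float] = []
    for gene, profile in qpcr.items():
        if gene not in expression_profiles:
            raise KeyError(f"no expression profile for qPCR gene {gene!r}")
        expr = {s: expression_profiles[gene][s] for s in profile}
        per_gene[gene] = concordance(expr, profile, log2=log2)
        stages = sorted(profile)
        ex = np.array([expr[s] for s in stages], dtype=float)
        qy = np.array([profile[s] for s in stages], dtype=float)
        if log2:
            ex = np.log2(ex + 1e-9)
            qy = np.log2(qy)
        # pool per-gene centered values so gene-level scale differences do
        # not masquerade as concordance
        pooled_x.extend((ex - ex.mean()).tolist())
        pooled_y.extend((qy - qy.mean()).tolist())
    pooled = pearson_r(pooled_x, pooled_y)
    mean_per_gene = float(np.mean(list(per_gene.values())))
    return per_gene, pooled, mean_per_gene
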