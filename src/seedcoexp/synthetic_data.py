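"""Staged-transcriptome simulator with planted truth.

Generates FPKM matrices (and count-level inputs, annotations and qPCR
plates) for a multi-stage seed development design: temporal modules drawn
from fixed smooth archetypes (a mid-development peak, an early-declining
and a late-rising trend) plus independent smooth background genes.

Noise is multiplicative log-normal, which preserves non-negativity and the
heavy-tailed look of FPKM data. Background genes carry random low-order
trends (not white noise) so that the null rate of |r| > 0.95 pairs at 7
stages is realistically non-trivial — a deliberate stress test of hard
correlation cutoffs at small n.

Every generator is a pure function of its spec (seed included), so fixtures
are bitwise reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .coexpression_network import SubnetworkPartition
from .guide_gene_tf import GuideQueryResult
from .io_formats import (
    AnnotationTable,
    CountMatrix,
    ExpressionMatrix,
    QpcrRecord,
    QpcrTable,
    _stage_sort_key,
)

BACKGROUND = "background"
ARCHETYPES = ("mid_peak", "early_declining", "late_rising", "flat_background")
DEFAULT_TF_FAMILIES = ("MYB", "bHLH", "AP2-EREBP", "NAC", "MADS-box",
                       "WRKY", "C2H2", "B3", "GRF", "IDD")

# Floor keeps every module gene detectable at realistic base FPKM, so the
# widely-expressed filter does not truncate planted modules.
_PROFILE_FLOOR = 0.05


def archetype_profile(name: str, n_stages: int) -> np.ndarray:
    """Fixed smooth archetype over ``n_stages`` equally spaced stages.

    Shapes are frozen (calibrated so that log-normal noise with sd 0.05
    leaves within-module pairwise r above 0.98) and mutually well separated
    (pairwise |r| <= ~0.63 at 7 stages), so planted modules neither
    dissolve nor merge at an |r| > 0.95 cutoff.
    """
    if n_stages < 3:
        raise ValueError("need at least 3 stages")
    x = np.linspace(0.0, 1.0, n_stages)
    if name == "mid_peak":
        # maximal slightly past mid-development (stages 14-18 of a
        # 2..26 design)
        return _PROFILE_FLOOR + np.exp(-((x - 7.0 / 12.0) ** 2) / (3.4 / 36.0))
    if name == "early_declining":
        return _PROFILE_FLOOR + np.exp(-5.0 * x)
    if name == "late_rising":
        return _PROFILE_FLOOR + np.exp(-5.0 * (1.0 - x))
    if name == "flat_background":
        return np.ones(n_stages)
    raise ValueError(f"unknown archetype {name!r}; expected {ARCHETYPES}")


@dataclass(frozen=True)
class ModuleSpec:
    name: str
    archetype: str
    n_genes: int
    base_fpkm: float = 200.0
    noise_sd: float = 0.05  # log-scale, multiplicative

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.base_fpkm <= 0:
            raise ValueError("base_fpkm must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic dataset."""

    modules: tuple[ModuleSpec, ...] = ()
    n_background: int = 0
    n_stages: int = 7
    tf_fraction: float = 0.0
    guides: tuple[tuple[str, int], ...] = ()  # (module name, n guides)
    qpcr_noise_sd: float = 0.0  # Ct units
    seed: int = 0
    background_base_fpkm: float = 20.0
    background_wiggle_sd: float = 0.5  # log-scale roughness of backgrounds
    tf_families: tuple[str, ...] = DEFAULT_TF_FAMILIES

    def __init__(self, modules=(), n_background=0, n_stages=7,
                 tf_fraction=0.0, guides=(), qpcr_noise_sd=0.0, seed=0,
                 background_base_fpkm=20.0, background_wiggle_sd=0.5,
                 tf_families=DEFAULT_TF_FAMILIES) -> None:
        mods = tuple(m if isinstance(m, ModuleSpec) else ModuleSpec(**m)
                     for m in modules)
        object.__setattr__(self, "modules", mods)
        object.__setattr__(self, "n_background", int(n_background))
        object.__setattr__(self, "n_stages", int(n_stages))
        object.__setattr__(self, "tf_fraction", float(tf_fraction))
        object.__setattr__(self, "guides",
                           tuple((str(m), int(c)) for m, c in guides))
        object.__setattr__(self, "qpcr_noise_sd", float(qpcr_noise_sd))
        object.__setattr__(self, "seed", int(seed))
        object.__setattr__(self, "background_base_fpkm",
                           float(background_base_fpkm))
        object.__setattr__(self, "background_wiggle_sd",
                           float(background_wiggle_sd))
        object.__setattr__(self, "tf_families", tuple(tf_families))
        self._validate()

    def _validate(self) -> None:
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")
        if BACKGROUND in names:
            raise ValueError(f"module name {BACKGROUND!r} is reserved")
        for mod_name, count in self.guides:
            spec = next((m for m in self.modules if m.name == mod_name), None)
            if spec is None:
                raise ValueError(f"guides reference unknown module "
                                 f"{mod_name!r}")
            if count > spec.n_genes:
                raise ValueError(f"module {mod_name!r} has {spec.n_genes} "
                                 f"genes but {count} guides requested")
        if not 0 <= self.tf_fraction <= 1:
            raise ValueError("tf_fraction must be in [0, 1]")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if self.qpcr_noise_sd < 0:
            raise ValueError("qpcr_noise_sd must be >= 0")

    @property
    def stage_labels(self) -> tuple[str, ...]:
        return tuple(f"{2 + 4 * i}DAF" for i in range(self.n_stages))


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: module membership, TF labels, guide ids, the
    noiseless profile of every gene, and the spec that generated it all."""

    module_of: Mapping[str, str]
    tf_family_of: Mapping[str, str | None]
    guides: tuple[str, ...]
    module_profiles: Mapping[str, np.ndarray]
    noiseless: pd.DataFrame  # genes x stages, pre-noise expression
    spec: SyntheticSpec

    def module_members(self, module: str) -> frozenset[str]:
        return frozenset(g for g, m in self.module_of.items() if m == module)

    def guide_partners(self, guide: str) -> frozenset[str]:
        """True coexpression partners of a guide: its module minus itself."""
        module = self.module_of[guide]
        if module == BACKGROUND:
            raise ValueError(f"guide {guide!r} is a background gene")
        return self.module_members(module) - {guide}

    def annotation_table(self) -> AnnotationTable:
        table = AnnotationTable()
        for gene, family in self.tf_family_of.items():
            if family is not None:
                table.add(gene, "tf_family", family)
        return table


def _background_profiles(rng: np.random.Generator, n: int, n_stages: int,
                         wiggle_sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Smooth random log-scale trends (quadratic + one sinusoid) plus
    stage-wise roughness. Returns (noiseless, noisy) multiplier arrays."""
    x = 2.0 * np.linspace(0.0, 1.0, n_stages) - 1.0
    a = rng.normal(0.0, 0.2, (n, 1))
    b = rng.normal(0.0, 0.3, (n, 1))
    c = rng.normal(0.0, 0.6, (n, 1))
    freq = rng.uniform(0.8, 1.6, (n, 1))
    phase = rng.uniform(0.0, 2.0 * np.pi, (n, 1))
    smooth = a * x + b * x ** 2 + c * np.sin(freq * np.pi * x + phase)
    noisy = smooth + rng.normal(0.0, wiggle_sd, (n, n_stages))
    return np.exp(smooth), np.exp(noisy)


def generate_matrix(spec: SyntheticSpec
                    ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw the FPKM matrix and its ground truth; deterministic in
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    stages = spec.stage_labels
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    noiseless_rows: list[np.ndarray] = []
    module_of: dict[str, str] = {}
    module_profiles: dict[str, np.ndarray] = {}

    for mod in spec.modules:
        profile = archetype_profile(mod.archetype, spec.n_stages) \
            * mod.base_fpkm
        module_profiles[mod.name] = profile
        noise = rng.normal(0.0, mod.noise_sd, (mod.n_genes, spec.n_stages))
        for i in range(mod.n_genes):
            gene = f"{mod.name}_g{i:04d}"
            gene_ids.append(gene)
            module_of[gene] = mod.name
            rows.append(profile * np.exp(noise[i]))
            noiseless_rows.append(profile)

    if spec.n_background:
        smooth, noisy = _background_profiles(
            rng, spec.n_background, spec.n_stages, spec.background_wiggle_sd)
        for i in range(spec.n_background):
            gene = f"bg_g{i:05d}"
            gene_ids.append(gene)
            module_of[gene] = BACKGROUND
            rows.append(spec.background_base_fpkm * noisy[i])
            noiseless_rows.append(spec.background_base_fpkm * smooth[i])

    # TF labels at tf_fraction, uniformly inside and outside modules, so
    # guide queries see annotated true and false candidates alike
    tf_family_of: dict[str, str | None] = {}
    is_tf = rng.random(len(gene_ids)) < spec.tf_fraction
    families = rng.choice(len(spec.tf_families), size=len(gene_ids))
    for gene, flag, fam in zip(gene_ids, is_tf, families):
        tf_family_of[gene] = spec.tf_families[int(fam)] if flag else None

    guides: list[str] = []
    for mod_name, count in spec.guides:
        members = sorted(g for g, m in module_of.items() if m == mod_name)
        chosen = rng.choice(len(members), size=count, replace=False)
        guides.extend(members[int(i)] for i in sorted(chosen))

    matrix = ExpressionMatrix(gene_ids, stages, np.array(rows))
    truth = SyntheticTruth(
        module_of=module_of, tf_family_of=tf_family_of,
        guides=tuple(guides), module_profiles=module_profiles,
        noiseless=pd.DataFrame(np.array(noiseless_rows), index=gene_ids,
                               columns=list(stages)),
        spec=spec)
    return matrix, truth


def generate_counts(spec: SyntheticSpec
                    ) -> tuple[CountMatrix, SyntheticTruth]:
    """Counts, gene lengths (uniform 300-3000 bp) and library sizes
    (uniform 10-30 M) whose FPKM reproduces :func:`generate_matrix` up to
    integer rounding."""
    matrix, truth = generate_matrix(spec)
    rng = np.random.default_rng([spec.seed, 1])
    lengths = rng.integers(300, 3001, size=matrix.n_genes)
    libsizes = rng.integers(10_000_000, 30_000_001, size=matrix.n_stages)
    counts = np.rint(matrix.values * lengths[:, None] * libsizes[None, :]
                     / 1e9).astype(np.int64)
    cm = CountMatrix(
        matrix.gene_ids, matrix.stage_labels, counts,
        {g: int(L) for g, L in zip(matrix.gene_ids, lengths)},
        {s: int(n) for s, n in zip(matrix.stage_labels, libsizes)})
    return cm, truth


def generate_qpcr(truth: SyntheticTruth, genes: Sequence[str],
                  stages: Sequence[str], n_replicates: int = 4,
                  reference_gene: str = "actin",
                  reference_ct: float = 20.0,
                  calibrator_stage: str | None = None) -> QpcrTable:
    """Simulate a qPCR plate encoding each gene's noiseless relative
    profile: target Ct = reference Ct - log2(level) + Gaussian Ct noise."""
    spec = truth.spec
    unknown = [g for g in genes if g not in truth.noiseless.index]
    if unknown:
        raise KeyError(f"genes not in truth: {unknown}")
    unknown_stages = [s for s in stages
                      if s not in truth.noiseless.columns]
    if unknown_stages:
        raise KeyError(f"stages not in truth: {unknown_stages}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng([spec.seed, 2])
    records = []
    for stage in stages:
        for rep in range(1, n_replicates + 1):
            records.append(QpcrRecord(
                reference_gene, stage, rep,
                reference_ct + rng.normal(0.0, spec.qpcr_noise_sd), True))
    for gene in genes:
        for stage in stages:
            level = float(truth.noiseless.loc[gene, stage])
            base_ct = reference_ct - np.log2(level)
            for rep in range(1, n_replicates + 1):
                records.append(QpcrRecord(
                    gene, stage, rep,
                    base_ct + rng.normal(0.0, spec.qpcr_noise_sd), False))
    if calibrator_stage is None:
        calibrator_stage = min(stages, key=_stage_sort_key)
    return QpcrTable(records, calibrator_stage)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


def score_partition_recovery(partition: SubnetworkPartition,
                             truth: SyntheticTruth) -> dict[str, float]:
    """Adjusted Rand index between recovered components and planted modules,
    restricted to non-background genes. Genes absent from every component
    count as their own singletons."""
    genes = sorted(g for g, m in truth.module_of.items() if m != BACKGROUND)
    if not genes:
        raise ValueError("truth contains no module genes")
    comp_of = partition.component_of()
    true_labels = [truth.module_of[g] for g in genes]
    pred_labels = []
    next_singleton = len(partition.components)
    for g in genes:
        if g in comp_of:
            pred_labels.append(comp_of[g])
        else:
            pred_labels.append(next_singleton)
            next_singleton += 1
    return {"ari": float(adjusted_rand_score(true_labels, pred_labels)),
            "n_genes": float(len(genes))}


def score_guide_recovery(result: GuideQueryResult,
                         truth: SyntheticTruth) -> dict[str, float]:
    """Precision/recall of a guide query against the guide's planted module
    membership."""
    true_set = truth.guide_partners(result.guide_id)
    predicted = result.neighbor_ids()
    tp = len(predicted & true_set)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(true_set) if true_set else 1.0
    return {"precision": float(precision), "recall": float(recall),
            "n_true": float(len(true_set)),
            "n_predicted": float(len(predicted))}


def score_recovery(predicted, truth: SyntheticTruth) -> dict[str, float]:
    """Dispatch on the prediction type (partition or guide query result)."""
    if isinstance(predicted, SubnetworkPartition):
        return score_partition_recovery(predicted, truth)
    if isinstance(predicted, GuideQueryResult):
        return score_guide_recovery(predicted, truth)
    raise TypeError(f"cannot score object of type {type(predicted).__name__}")


# ---------------------------------------------------------------------------
# Truth (de)serialization for the CLI
# ---------------------------------------------------------------------------


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "module_of": dict(truth.module_of),
        "tf_family_of": dict(truth.tf_family_of),
        "guides": list(truth.guides),
        "module_profiles": {k: list(map(float, v))
                            for k, v in truth.module_profiles.items()},
        "noiseless": {g: [float(v) for v in truth.noiseless.loc[g]]
                      for g in truth.noiseless.index},
        "stage_labels": list(truth.noiseless.columns),
        "spec": {
            "modules": [{"name": m.name, "archetype": m.archetype,
                         "n_genes": m.n_genes, "base_fpkm": m.base_fpkm,
                         "noise_sd": m.noise_sd} for m in truth.spec.modules],
            "n_background": truth.spec.n_background,
            "n_stages": truth.spec.n_stages,
            "tf_fraction": truth.spec.tf_fraction,
            "guides": [list(g) for g in truth.spec.guides],
            "qpcr_noise_sd": truth.spec.qpcr_noise_sd,
            "seed": truth.spec.seed,
            "background_base_fpkm": truth.spec.background_base_fpkm,
            "background_wiggle_sd": truth.spec.background_wiggle_sd,
            "tf_families": list(truth.spec.tf_families),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    spec = SyntheticSpec(**payload["spec"])
    stage_labels = payload["stage_labels"]
    genes = sorted(payload["noiseless"])
    noiseless = pd.DataFrame(
        [payload["noiseless"][g] for g in genes], index=genes,
        columns=stage_labels)
    return SyntheticTruth(
        module_of=payload["module_of"],
        tf_family_of=payload["tf_family_of"],
        guides=tuple(payload["guides"]),
        module_profiles={k: np.array(v)
                         for k, v in payload["module_profiles"].items()},
        noiseless=noiseless, spec=spec)
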