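"""Synthetic metabolome/transcriptome generator with planted ground truth.

Emulates a widely-targeted metabolomics experiment over three culture
stages with three biological replicates each: per-feature log-normal
baseline peak areas, multiplicative stage effects of 2^(log2 effect) on
planted differential features, multiplicative log-normal replicate noise
with sd = ln(1 + cv), true zeros in the first stage to exercise zero
imputation (the generative account of fold changes in the 10^4 range),
compound-class labels apportioned by largest remainder, and pathway
membership with planted over-represented pathways.  The transcriptome
side plants differential genes and couples selected genes to metabolite
replicate profiles so gene–metabolite pairs carry a target correlation
sign.

Ground truth is derived from the realized stage-effect matrix (plus zero
flags), so it is consistent with the emitted values by construction: a
feature planted "up" for one contrast may truthfully be "down" in another
that shares its perturbed stage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    DEFAULT_STAGES,
    AbundanceMatrix,
    ComparisonSpec,
    FeatureAnnotation,
    SampleDesign,
    write_abundance,
    write_annotations,
    write_design,
    write_pathway_map,
)

__all__ = [
    "PlantedEffect",
    "PlantedPathway",
    "PlantedPair",
    "SimulationConfig",
    "GroundTruth",
    "largest_remainder",
    "generate_metabolome",
    "generate_transcriptome",
    "write_fixture_bundle",
]

DEFAULT_CLASS_PROPORTIONS = {
    "Amino acid and its derivates": 0.15,
    "Flavone": 0.15,
    "Organic acid": 0.12,
    "Lipid": 0.11,
    "Nucleotide and its derivates": 0.10,
}


@dataclasses.dataclass(frozen=True)
class PlantedEffect:
    """A block of features perturbed for one contrast.

    ``log2_effect`` is signed (negative for direction ``down``) and applied
    multiplicatively to the test stage.  ``zero_reference`` additionally
    zeroes the reference-stage baseline (valid for ``up`` only), producing
    fold changes bounded only by imputation.
    """

    comparison: str
    direction: str
    log2_effect: float
    count: int
    zero_reference: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        if abs(self.log2_effect) < 1:
            raise ValueError("planted |log2 effect| must be >= 1 so FC >= 2 is achievable")
        if (self.log2_effect > 0) != (self.direction == "up"):
            raise ValueError("log2_effect sign must match direction")
        if self.zero_reference and self.direction != "up":
            raise ValueError("zero_reference only meaningful for up effects")
        if self.count < 1:
            raise ValueError("count must be positive")


@dataclasses.dataclass(frozen=True)
class PlantedPathway:
    pathway_id: str
    member_count: int
    planted_dam_count: int

    def __post_init__(self) -> None:
        if not (0 < self.planted_dam_count <= self.member_count):
            raise ValueError("need 0 < planted_dam_count <= member_count")


@dataclasses.dataclass(frozen=True)
class PlantedPair:
    """Gene–metabolite coupling with a target correlation sign (+1/-1).

    Ids left as None are resolved at generation time: the metabolite from
    the planted differential pool (never a zeroed feature), the gene from
    the unplanted gene pool.
    """

    gene_id: str | None
    metabolite_id: str | None
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


def _default_planted_dams() -> tuple[PlantedEffect, ...]:
    return (
        PlantedEffect("PEC:NEC", "up", 3.0, 50),
        PlantedEffect("PEC:NEC", "down", -3.0, 15),
        PlantedEffect("GE:PEC", "up", 3.0, 40),
        PlantedEffect("GE:PEC", "down", -3.0, 20),
        PlantedEffect("GE:NEC", "up", 3.0, 50),
        PlantedEffect("GE:NEC", "down", -3.0, 15),
    )


def _default_planted_degs() -> tuple[PlantedEffect, ...]:
    return (
        PlantedEffect("PEC:NEC", "up", 3.0, 80),
        PlantedEffect("PEC:NEC", "down", -3.0, 30),
        PlantedEffect("GE:PEC", "up", 3.0, 60),
        PlantedEffect("GE:PEC", "down", -3.0, 30),
    )


def _default_planted_pairs() -> tuple[PlantedPair, ...]:
    return tuple(
        [PlantedPair(None, None, 1) for _ in range(20)]
        + [PlantedPair(None, None, -1) for _ in range(10)]
    )


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the simulator (defaults mirror the experiment:
    581 metabolites, 3 stages x 3 replicates, the published class mix)."""

    n_metabolites: int = 581
    n_genes: int = 2000
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 3
    class_proportions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    baseline_log_mean: float = 13.8  # natural-log scale; exp ~ 1e6 peak area
    baseline_log_sd: float = 1.5
    replicate_cv: float = 0.1
    planted_dams: tuple[PlantedEffect, ...] = dataclasses.field(
        default_factory=_default_planted_dams
    )
    planted_degs: tuple[PlantedEffect, ...] = dataclasses.field(
        default_factory=_default_planted_degs
    )
    planted_pathways: tuple[PlantedPathway, ...] = dataclasses.field(
        default_factory=lambda: (PlantedPathway("ko00230", 25, 15), PlantedPathway("ko00941", 20, 12))
    )
    planted_pairs: tuple[PlantedPair, ...] = dataclasses.field(
        default_factory=_default_planted_pairs
    )
    background_pathways: int = 30
    zero_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        # coerce plain sequences/mappings (e.g. parsed YAML) into dataclasses
        def coerce(items, cls):
            out = []
            for item in items:
                if isinstance(item, cls):
                    out.append(item)
                elif isinstance(item, Mapping):
                    out.append(cls(**item))
                else:
                    out.append(cls(*item))
            return tuple(out)

        self.stages = tuple(self.stages)
        self.planted_dams = coerce(self.planted_dams, PlantedEffect)
        self.planted_degs = coerce(self.planted_degs, PlantedEffect)
        self.planted_pathways = coerce(self.planted_pathways, PlantedPathway)
        self.planted_pairs = coerce(self.planted_pairs, PlantedPair)
        if self.n_metabolites < 1 or self.n_genes < 1:
            raise ValueError("feature counts must be positive")
        if self.replicates_per_stage < 2:
            raise ValueError("need >= 2 replicates per stage")
        if len(self.stages) < 2:
            raise ValueError("need >= 2 stages")
        total = sum(self.class_proportions.values())
        if total > 1 + 1e-9:
            raise ValueError(f"class proportions sum to {total} > 1")
        if not (0 <= self.zero_fraction < 1):
            raise ValueError("zero_fraction must lie in [0, 1)")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be non-negative")

    @property
    def design(self) -> SampleDesign:
        rows = [
            (f"{stage}_{r}", stage, r)
            for stage in self.stages
            for r in range(1, self.replicates_per_stage + 1)
        ]
        return SampleDesign(rows, stages=self.stages)

    def comparisons(self) -> list[ComparisonSpec]:
        seen: list[str] = []
        for eff in tuple(self.planted_dams) + tuple(self.planted_degs):
            if eff.comparison not in seen:
                seen.append(eff.comparison)
        return [ComparisonSpec.parse(c) for c in seen]


@dataclasses.dataclass
class GroundTruth:
    """Planted structure, derived from the realized effect matrices."""

    dam_status: dict[str, pd.Series] = dataclasses.field(default_factory=dict)
    deg_status: dict[str, pd.Series] = dataclasses.field(default_factory=dict)
    enriched_pathways: dict[str, bool] = dataclasses.field(default_factory=dict)
    pair_signs: list[tuple[str, str, int]] = dataclasses.field(default_factory=list)

    def dam_set(self, comparison_label: str) -> set[str]:
        status = self.dam_status[comparison_label]
        return set(status.index[status != "unchanged"])


def largest_remainder(proportions: Mapping[str, float], total: int) -> dict[str, int]:
    """Apportion ``total`` items to categories by the largest-remainder rule.

    Any fraction left over is assigned to the category ``other``.
    Deterministic: ties go to the category appearing first.
    """
    props = dict(proportions)
    leftover = 1.0 - sum(props.values())
    if leftover > 1e-9:
        props["other"] = props.get("other", 0.0) + leftover
    quotas = {c: total * p for c, p in props.items()}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    remaining = total - sum(counts.values())
    order = sorted(props, key=lambda c: quotas[c] - counts[c], reverse=True)
    for c in order[:remaining]:
        counts[c] += 1
    return counts


def _status_from_effects(
    effect_diff: np.ndarray, zero_ref: np.ndarray, zero_test: np.ndarray, index: Sequence[str]
) -> pd.Series:
    """Status per feature from the realized log2 stage-effect difference
    and the zero-baseline flags of the two compared stages."""
    status = np.where(effect_diff >= 1, "up", np.where(effect_diff <= -1, "down", "unchanged"))
    status = np.where(zero_ref & ~zero_test, "up", status)
    status = np.where(zero_test & ~zero_ref, "down", status)
    status = np.where(zero_test & zero_ref, "unchanged", status)
    return pd.Series(status, index=list(index), name="status")


def _plant_effects(
    effects: Sequence[PlantedEffect],
    n_features: int,
    stages: Sequence[str],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict[str, list[int]]]:
    """Build the features x stages log2 effect matrix and zero flags.

    Each feature receives at most one planted effect.  Returns the effect
    matrix, per-feature zero-stage flags (features x stages bool), and the
    planted feature indices per effect-list position.
    """
    stage_index = {s: i for i, s in enumerate(stages)}
    E = np.zeros((n_features, len(stages)))
    zero = np.zeros((n_features, len(stages)), dtype=bool)
    available = list(range(n_features))
    planted: dict[str, list[int]] = {}
    for pos, eff in enumerate(effects):
        cmp = ComparisonSpec.parse(eff.comparison)
        for s in (cmp.test_stage, cmp.ref_stage):
            if s not in stage_index:
                raise ValueError(f"planted effect references unknown stage {s!r}")
        if eff.count > len(available):
            raise ValueError(
                f"infeasible planting: {eff.count} features requested, {len(available)} free"
            )
        picked = rng.choice(len(available), size=eff.count, replace=False)
        idx = [available[i] for i in sorted(picked, reverse=True)]
        for i in sorted(picked, reverse=True):
            available.pop(i)
        for f in idx:
            E[f, stage_index[cmp.test_stage]] += eff.log2_effect
            if eff.zero_reference:
                zero[f, stage_index[cmp.ref_stage]] = True
        planted[f"{pos}"] = sorted(idx)
    return E, zero, planted


def _sample_matrix(
    baselines: np.ndarray,
    E: np.ndarray,
    zero: np.ndarray,
    design: SampleDesign,
    cv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    sigma = np.log(1.0 + cv)
    n_features = baselines.shape[0]
    stage_index = {s: i for i, s in enumerate(design.stages)}
    cols = []
    for sid, stage, _rep in design.to_frame().itertuples(index=False):
        si = stage_index[stage]
        noise = np.exp(rng.normal(0.0, sigma, size=n_features)) if cv > 0 else 1.0
        col = baselines * np.exp2(E[:, si]) * noise
        col = np.where(zero[:, si], 0.0, col)
        cols.append(col)
    return np.column_stack(cols)


def generate_metabolome(config: SimulationConfig) -> tuple[AbundanceMatrix, GroundTruth]:
    """Generate the metabolite peak-area matrix and its ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_metabolites
    ids = [f"pmb{i + 1:04d}" for i in range(n)]

    class_counts = largest_remainder(config.class_proportions, n)
    labels = [c for c, k in class_counts.items() for _ in range(k)]
    rng.shuffle(labels)

    E, zero, _ = _plant_effects(config.planted_dams, n, config.stages, rng)

    # true zeros among unplanted features: first stage baseline set to 0
    unplanted = np.flatnonzero((E == 0).all(axis=1) & ~zero.any(axis=1))
    n_zero = int(round(config.zero_fraction * n))
    if n_zero > len(unplanted):
        raise ValueError("infeasible zero_fraction: not enough unplanted features")
    if n_zero:
        zz = rng.choice(unplanted, size=n_zero, replace=False)
        zero[zz, 0] = True

    baselines = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n))
    design = config.design
    values = _sample_matrix(baselines, E, zero, design, config.replicate_cv, rng)

    truth = GroundTruth()
    stage_index = {s: i for i, s in enumerate(config.stages)}
    for cmp in config.comparisons():
        ti, ri = stage_index[cmp.test_stage], stage_index[cmp.ref_stage]
        truth.dam_status[cmp.label] = _status_from_effects(
            E[:, ti] - E[:, ri], zero[:, ri], zero[:, ti], ids
        )

    # pathway assignment: planted over-represented pathways + random background
    pathway_sets: dict[str, set[str]] = {fid: set() for fid in ids}
    first_cmp = config.comparisons()[0] if config.comparisons() else None
    for planted in config.planted_pathways:
        if first_cmp is None:
            raise ValueError("planted pathways require at least one planted comparison")
        status = truth.dam_status[first_cmp.label]
        dam_idx = np.flatnonzero((status != "unchanged").to_numpy())
        non_idx = np.flatnonzero((status == "unchanged").to_numpy())
        if planted.planted_dam_count > dam_idx.size:
            raise ValueError(f"infeasible pathway planting for {planted.pathway_id}")
        rest = planted.member_count - planted.planted_dam_count
        if rest > non_idx.size:
            raise ValueError(f"infeasible pathway planting for {planted.pathway_id}")
        chosen = list(rng.choice(dam_idx, size=planted.planted_dam_count, replace=False))
        chosen += list(rng.choice(non_idx, size=rest, replace=False))
        for f in chosen:
            pathway_sets[ids[f]].add(planted.pathway_id)
        truth.enriched_pathways[planted.pathway_id] = True
    for i in range(n):
        for _ in range(rng.integers(0, 3)):
            pid = f"ko9{rng.integers(0, config.background_pathways):04d}"
            pathway_sets[ids[i]].add(pid)

    annotations = {
        fid: FeatureAnnotation(fid, f"metabolite {fid}", labels[i], frozenset(pathway_sets[fid]))
        for i, fid in enumerate(ids)
    }
    matrix = AbundanceMatrix(
        pd.DataFrame(values, index=pd.Index(ids, name="feature_id"), columns=design.sample_ids),
        design,
        annotations,
    )
    return matrix, truth


def generate_transcriptome(
    config: SimulationConfig,
    truth: GroundTruth,
    metabolome: AbundanceMatrix,
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Generate the gene matrix with planted DEGs and coupled gene–metabolite pairs.

    For each planted pair the gene's log2 replicate profile is an affine
    transform of the metabolite's with slope ``sign``, plus replicate noise,
    so the replicate-level correlation approaches ``sign`` x 1 as noise
    vanishes.
    """
    truth = GroundTruth(  # do not mutate the caller's truth
        dam_status=dict(truth.dam_status),
        deg_status=dict(truth.deg_status),
        enriched_pathways=dict(truth.enriched_pathways),
        pair_signs=list(truth.pair_signs),
    )
    rng = np.random.default_rng(config.seed + 1_000_003)
    n = config.n_genes
    ids = [f"Gh_A01G{i + 1:04d}" for i in range(n)]
    design = config.design
    stage_index = {s: i for i, s in enumerate(config.stages)}

    E, zero, _ = _plant_effects(config.planted_degs, n, config.stages, rng)
    baselines = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n))
    values = _sample_matrix(baselines, E, zero, design, config.replicate_cv, rng)
    values_df = pd.DataFrame(
        values, index=pd.Index(ids, name="feature_id"), columns=design.sample_ids
    )

    # resolve and couple planted pairs
    coupled_genes = set()
    unplanted = [i for i in range(n) if (E[i] == 0).all()]
    first_cmp = config.comparisons()[0] if config.comparisons() else None
    met_zero_free = [
        fid
        for fid in metabolome.feature_ids
        if (metabolome.values.loc[fid] > 0).all()
    ]
    candidate_mets = []
    if first_cmp is not None and first_cmp.label in truth.dam_status:
        status = truth.dam_status[first_cmp.label]
        candidate_mets = [f for f in met_zero_free if status[f] != "unchanged"]
    log_diffs = np.zeros(n)  # realized log2 stage diffs for coupled genes (per first cmp)
    for pair in config.planted_pairs:
        met = pair.metabolite_id
        if met is None:
            if not candidate_mets:
                raise ValueError("no differential zero-free metabolite available for pairing")
            met = candidate_mets[len(truth.pair_signs) % len(candidate_mets)]
        elif met not in metabolome.values.index:
            raise ValueError(f"pair references unknown metabolite {met!r}")
        gene = pair.gene_id
        if gene is None:
            if not unplanted:
                raise ValueError("no free gene available for pairing")
            gene = ids[unplanted.pop()]
        elif gene not in values_df.index:
            raise ValueError(f"pair references unknown gene {gene!r}")
        sigma = np.log(1.0 + config.replicate_cv)
        met_log2 = np.log2(metabolome.values.loc[met].to_numpy(dtype=float))
        base_log2 = np.log2(baselines[ids.index(gene)])
        profile_log2 = base_log2 + pair.sign * (met_log2 - met_log2.mean())
        if config.replicate_cv > 0:
            profile_log2 = profile_log2 + rng.normal(0.0, sigma / np.log(2), size=len(met_log2))
        values_df.loc[gene] = np.exp2(profile_log2)
        coupled_genes.add(gene)
        truth.pair_signs.append((gene, met, pair.sign))

    # DEG truth from realized effects; coupled genes from their metabolite's profile
    gene_index = {g: i for i, g in enumerate(ids)}
    for cmp in config.comparisons():
        ti, ri = stage_index[cmp.test_stage], stage_index[cmp.ref_stage]
        status = _status_from_effects(E[:, ti] - E[:, ri], zero[:, ri], zero[:, ti], ids)
        for gene, met, sign in truth.pair_signs:
            met_status = truth.dam_status[cmp.label][met]
            if met_status == "unchanged":
                status[gene] = "unchanged"
            elif sign > 0:
                status[gene] = met_status
            else:
                status[gene] = "down" if met_status == "up" else "up"
        truth.deg_status[cmp.label] = status

    annotations = {
        fid: FeatureAnnotation(fid, f"gene {fid}", "gene", frozenset()) for fid in ids
    }
    matrix = AbundanceMatrix(values_df, design, annotations)
    return matrix, truth


def write_fixture_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate both matrices and write every TSV the pipeline consumes.

    Emits metabolome.tsv, transcriptome.tsv, annotations.tsv, pathway_map.tsv
    and design.tsv, plus a truth.json recording the planted structure.
    Returns the file manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metabolome, truth = generate_metabolome(config)
    transcriptome, truth = generate_transcriptome(config, truth, metabolome)
    manifest = {
        "metabolome": out / "metabolome.tsv",
        "transcriptome": out / "transcriptome.tsv",
        "annotations": out / "annotations.tsv",
        "pathway_map": out / "pathway_map.tsv",
        "design": out / "design.tsv",
    }
    write_abundance(metabolome, manifest["metabolome"])
    write_abundance(transcriptome, manifest["transcriptome"])
    all_annotations = {**metabolome.annotations, **transcriptome.annotations}
    write_annotations(all_annotations, manifest["annotations"])
    write_pathway_map(metabolome.pathway_map(), manifest["pathway_map"])
    write_design(config.design, manifest["design"])
    truth_path = out / "truth.json"
    with open(truth_path, "w", encoding="utf-8") as handle:
        json.dump(
            {
                "dam_status": {c: s.to_dict() for c, s in truth.dam_status.items()},
                "deg_status": {c: s.to_dict() for c, s in truth.deg_status.items()},
                "enriched_pathways": truth.enriched_pathways,
                "pair_signs": truth.pair_signs,
            },
            handle,
            indent=1,
        )
    manifest["truth"] = truth_path
    return manifest
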