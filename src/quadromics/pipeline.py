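"""End-to-end orchestration: QC, differential calling, enrichment,
association and network export, driven by one config and one seed.

The result bundle is a directory of TSV tables plus GraphML/SIF networks
and a ``manifest.json`` recording the config hash, seed and per-output
record counts.  Identical config + seed reproduces an identical bundle
(timing is logged to stderr, never written into outputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import association, enrichment, qc
from .data_io import (
    AbundanceMatrix,
    ComparisonSpec,
    load_abundance,
    load_annotations,
    load_design,
    load_pathway_map,
    write_table,
)
from .differential import (
    Thresholds,
    call_degs,
    class_composition,
    run_differential,
    venn_partition,
)
from .simulate import SimulationConfig, generate_metabolome, generate_transcriptome

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

DEFAULT_COMPARISONS = ("PEC:NEC", "GE:PEC", "GE:NEC")


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of the pipeline, mirroring the CLI flags.

    Either ``simulate`` is set (synthetic inputs are generated with the
    run seed) or the four input paths are.
    """

    out_dir: str = "results"
    seed: int = 0
    simulate: SimulationConfig | None = None
    metabolome_path: str | None = None
    transcriptome_path: str | None = None
    annotations_path: str | None = None
    pathway_map_path: str | None = None
    design_path: str | None = None
    comparisons: tuple[str, ...] = DEFAULT_COMPARISONS
    fc_up: float = 2.0
    fc_down: float = 0.5
    vip: float = 1.0
    p: float = 0.05
    p_filter: bool = True
    fdr: float = 0.05
    pcc: float = 0.8
    pcc_mode: str = "replicates"
    imputation: str = "half_min_positive"
    n_components: int = 2
    deg_log2fc: float = 1.0

    def thresholds(self) -> Thresholds:
        return Thresholds(self.fc_up, self.fc_down, self.vip, self.p, self.p_filter)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config document mirroring the PipelineConfig fields."""
    with open(path, encoding="utf-8") as handle:
        raw: Mapping[str, Any] = yaml.safe_load(handle) or {}
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        cfg.simulate = SimulationConfig(**sim) if isinstance(sim, Mapping) else SimulationConfig()
    return cfg


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        metabolome, truth = generate_metabolome(sim)
        transcriptome, truth = generate_transcriptome(sim, truth, metabolome)
        return metabolome, transcriptome
    if not (config.metabolome_path and config.design_path):
        raise ValueError("either a simulation block or input paths must be configured")
    design = load_design(config.design_path)
    annotations = (
        load_annotations(config.annotations_path) if config.annotations_path else None
    )
    metabolome = load_abundance(config.metabolome_path, design, annotations)
    if config.pathway_map_path:
        pmap = load_pathway_map(config.pathway_map_path)
        for fid, ann in metabolome.annotations.items():
            if fid in pmap:
                metabolome.annotations[fid] = dataclasses.replace(ann, pathway_ids=pmap[fid])
    transcriptome = (
        load_abundance(config.transcriptome_path, design, annotations)
        if config.transcriptome_path
        else None
    )
    return metabolome, transcriptome


def _validate_comparisons(config: PipelineConfig, matrix: AbundanceMatrix) -> list[ComparisonSpec]:
    comps = [ComparisonSpec.parse(c) for c in config.comparisons]
    for cmp in comps:
        cmp.validate(matrix.design)  # fail before any compute
    return comps


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        write_table(frame, out / name)
        counts[name] = len(frame)

    def staged(stage_name: str):
        start = time.perf_counter()

        def done() -> None:
            logger.info("%s finished in %.2fs", stage_name, time.perf_counter() - start)

        return done

    try:
        metabolome, transcriptome = _load_inputs(config)
        comps = _validate_comparisons(config, metabolome)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'inputs' failed: {exc}") from exc

    # ---- qc ----
    done = staged("qc")
    corr = qc.sample_correlation_matrix(metabolome)
    emit("qc_sample_correlation.tsv", corr.reset_index(names="sample_id"))
    report = qc.pca_variance(metabolome)
    emit(
        "qc_pc_variance.tsv",
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(report.pc_variance_fractions))],
                "variance_fraction": report.pc_variance_fractions,
            }
        ),
    )
    done()

    # ---- differential + enrichment + association per comparison ----
    dam_sets: dict[str, set[str]] = {}
    pathway_map = metabolome.pathway_map()
    background = metabolome.feature_ids
    for cmp in comps:
        done = staged(f"differential {cmp.label}")
        try:
            dams = run_differential(
                metabolome,
                cmp,
                thresholds=config.thresholds(),
                n_components=config.n_components,
                imputation=config.imputation,
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'differential {cmp.label}' failed: {exc}") from exc
        emit(f"dam_{cmp.label}.tsv", dams)
        volcano = pd.DataFrame(
            {
                "feature_id": dams["feature_id"],
                "log2fc": dams["log2fc"],
                "neg_log10_p": -np.log10(dams["p"].clip(lower=1e-300)),
                "status": dams["status"],
            }
        )
        emit(f"volcano_{cmp.label}.tsv", volcano)
        status = dams.set_index("feature_id")["status"]
        dam_ids = set(status.index[status != "unchanged"])
        dam_sets[cmp.label] = dam_ids
        emit(
            f"class_composition_{cmp.label}.tsv",
            class_composition(sorted(dam_ids), metabolome.annotations),
        )
        done()

        done = staged(f"enrichment {cmp.label}")
        met_enrich = enrichment.enrich_pathways(
            dam_ids, background, pathway_map, fdr_threshold=config.fdr
        ) if dam_ids else pd.DataFrame(columns=enrichment.ENRICHMENT_COLUMNS)
        emit(f"enrichment_{cmp.label}.tsv", met_enrich)
        done()

        if transcriptome is not None:
            done = staged(f"association {cmp.label}")
            try:
                degs = call_degs(
                    transcriptome,
                    cmp,
                    log2fc_threshold=config.deg_log2fc,
                    fdr_threshold=config.fdr,
                    imputation=config.imputation,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage 'association {cmp.label}' failed: {exc}"
                ) from exc
            emit(f"deg_{cmp.label}.tsv", degs)
            gene_status = degs.set_index("feature_id")["status"]
            deg_ids = sorted(gene_status.index[gene_status != "unchanged"])
            gene_pmap = transcriptome.pathway_map()
            if any(gene_pmap.get(g) for g in transcriptome.feature_ids):
                gene_enrich = enrichment.enrich_pathways(
                    deg_ids, transcriptome.feature_ids, gene_pmap, fdr_threshold=config.fdr
                )
                emit(f"gene_enrichment_{cmp.label}.tsv", gene_enrich)
                emit(
                    f"co_mapped_{cmp.label}.tsv",
                    enrichment.co_mapped_pathways(met_enrich, gene_enrich),
                )
            pairs = association.associate(
                transcriptome,
                metabolome,
                cmp,
                gene_status=gene_status,
                metabolite_status=status,
                gene_log2fc=degs.set_index("feature_id")["log2fc"],
                metabolite_log2fc=dams.set_index("feature_id")["log2fc"],
                gene_ids=deg_ids,
                metabolite_ids=sorted(dam_ids),
                mode=config.pcc_mode,
            )
            quad_counts, quad_table = association.quadrant_table(pairs)
            emit(f"quadrants_{cmp.label}.tsv", quad_table)
            emit(
                f"quadrant_counts_{cmp.label}.tsv",
                quad_counts.rename_axis("quadrant").reset_index(),
            )
            net = association.build_network(pairs, pcc_threshold=config.pcc)
            association.export_network(net, out / f"network_{cmp.label}.graphml", "graphml")
            association.export_network(net, out / f"network_{cmp.label}.sif", "sif")
            association.export_network(net, out / f"network_{cmp.label}.edges.tsv", "edge_tsv")
            summary = association.network_summary(net)
            emit(f"network_degree_{cmp.label}.tsv", summary.pop("degree"))
            counts[f"network_{cmp.label}.edges"] = summary["edges"]
            done()

    if len(comps) == 3:
        regions = venn_partition(dam_sets)
        emit(
            "venn_regions.tsv",
            pd.DataFrame(
                [
                    {"region": "&".join(key), "size": len(val), "features": ";".join(sorted(val))}
                    for key, val in sorted(regions.items(), key=lambda kv: (len(kv[0]), kv[0]))
                ]
            ),
        )

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "record_counts": counts,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True, default=str)
    return manifest
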