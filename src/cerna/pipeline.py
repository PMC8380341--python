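"""End-to-end orchestration: simulate? -> diffexpr -> targets -> network -> enrich.

Each stage reads and writes the shared TSV dialects, so the pipeline is a
thin, deterministic sequencing of the library calls with provenance-stamped
outputs and a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cernet, enrich, io, synthdata, targetpred
from .diffexpr import RNA_CLASSES, Thresholds, call_differential

log = logging.getLogger("cerna")

DATASET_FILES = {
    "counts": {cls: f"{cls}_counts.tsv" for cls in RNA_CLASSES},
    "fasta": {cls: f"{cls}.fasta" for cls in RNA_CLASSES},
    "sample_map": "sample_map.tsv",
    "mapped_totals": "mapped_totals.tsv",
}


@dataclass
class PipelineConfig:
    """Everything one run needs, serializable to/from YAML."""

    out_dir: str = "cerna_out"
    seed: int = 0
    data_dir: str | None = None  # pre-existing dataset; None -> simulate
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    thresholds: dict = field(default_factory=dict)  # Thresholds overrides
    context_cutoff: float = 50.0
    energy_cutoff: float = -10.0
    permissive: bool = False
    quad_requires_shared_mrna: bool = True
    top_k: int = 10
    gmt: str | None = None
    enrich_class: str = "mRNA"
    log_level: str = "INFO"

    def make_thresholds(self) -> Thresholds:
        return Thresholds(**self.thresholds)

    def make_simconfig(self) -> synthdata.SimConfig:
        params = dict(self.simulate)
        params.setdefault("seed", self.seed)
        return synthdata.SimConfig(**params)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written as manifest.json)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "files": {}}
    params = {"seed": config.seed}

    if config.data_dir is None:
        _stage("simulate")
        data_dir = out / "dataset"
        dataset = synthdata.generate_dataset(config.make_simconfig())
        synthdata.write_dataset(dataset, data_dir)
    else:
        data_dir = Path(config.data_dir)
    manifest["files"]["dataset"] = str(data_dir)

    sample_map = io.read_sample_map(data_dir / DATASET_FILES["sample_map"])
    totals = io.read_mapped_totals(data_dir / DATASET_FILES["mapped_totals"])

    _stage("diffexpr")
    thresholds = config.make_thresholds()
    de_frames = []
    for cls in RNA_CLASSES:
        matrix = io.read_counts(data_dir / DATASET_FILES["counts"][cls], cls, sample_map)
        de_frames.append(call_differential(matrix, sample_map, totals, thresholds))
    de_table = pd.concat(de_frames, ignore_index=True)
    de_path = out / "diffexpr.tsv"
    io.write_table(de_table, de_path, params | dataclasses.asdict(thresholds))
    manifest["files"]["diffexpr"] = str(de_path)

    _stage("targets")
    fastas = {
        cls: io.read_fasta(data_dir / DATASET_FILES["fasta"][cls]) for cls in RNA_CLASSES
    }
    mirnas = {e.id: e.seq for e in fastas["miRNA"]}
    targets = {
        cls: {e.id: (e.seq, e.circular) for e in fastas[cls]}
        for cls in ("mRNA", "lncRNA", "circRNA")
    }
    pairs = targetpred.predict_targets(
        mirnas, targets, config.context_cutoff, config.energy_cutoff
    )
    pair_frame = targetpred.pairs_to_frame(pairs)
    pairs_path = out / "target_pairs.tsv"
    io.write_table(
        pair_frame,
        pairs_path,
        params | {"context_cutoff": config.context_cutoff, "energy_cutoff": config.energy_cutoff},
    )
    manifest["files"]["target_pairs"] = str(pairs_path)

    _stage("network")
    edges = cernet.build_edges(de_table, pair_frame, permissive=config.permissive)
    triads = cernet.assemble_triads(edges)
    network = cernet.integrate_networks(
        triads, edges, require_shared_mrna=config.quad_requires_shared_mrna
    )
    manifest["files"].update(cernet.export_network(network, out))
    hubs = cernet.hub_ranking(network, config.top_k)
    hub_frame = pd.DataFrame(hubs.top(config.top_k), columns=["mrna_id", "degree"])
    hub_path = out / "hubs.tsv"
    io.write_table(hub_frame, hub_path, params | {"top_k": config.top_k})
    manifest["files"]["hubs"] = str(hub_path)

    _stage("enrich")
    if config.gmt is not None:
        collection = enrich.read_gmt(config.gmt)
        class_de = de_table[de_table["class"] == config.enrich_class]
        results = enrich.enrich_terms(
            class_de,
            collection,
            lfc_threshold=thresholds.lfc_threshold,
            alpha=thresholds.alpha_for(config.enrich_class),
        )
        enrich_path = out / "enrichment.tsv"
        io.write_table(results, enrich_path, params | {"gmt": config.gmt})
        manifest["files"]["enrichment"] = str(enrich_path)

    manifest["summary"] = {
        "n_de": int((de_table["direction"] != "ns").sum()),
        "n_passing_pairs": int(pair_frame["passes"].sum()) if len(pair_frame) else 0,
        "n_edges": len(edges),
        "n_triads": len(triads),
        "n_quads": len(network.quads),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
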