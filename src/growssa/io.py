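"""Model file reader/writer, trajectory/lineage writers and run logging.

Model files are YAML with top-level keys ``name``, ``species``, ``reactions``,
``genes``, ``config`` and optionally ``extrinsic_noise``.  Trajectories are
written as TSV (`time_s`, `cell_id`, `volume_L`, one column per species and
per gene copy number); lineages as annotated Newick; run summaries as JSON.
Every output records the seed, so (model file, config, seed) reproduces the
run byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Optional, TextIO

import yaml

from .dosage import CyclePeriods, replication_schedule
from .engine import CompiledModel
from .model import (
    Model,
    ModelError,
    OUParams,
    RunConfig,
    build_model,
    model_to_dict,
)
from .population import LineageTree, cycle_mean

_TOP_KEYS = {"name", "species", "reactions", "genes", "config",
             "extrinsic_noise"}
_CONFIG_KEYS = {"T", "C", "D", "v_birth", "t_end", "seed", "grid_dt",
                "max_cells", "record_events"}
_NOISE_KEYS = {"tau_c", "sigma", "applied_to", "shared"}


def _parse_config(raw: dict, noise_raw: Optional[dict]) -> RunConfig:
    for key in raw:
        if key not in _CONFIG_KEYS:
            raise ModelError(f"unknown key {key!r} in config section")
    cfg = RunConfig(**{k: v for k, v in raw.items()})
    if noise_raw is not None:
        for key in noise_raw:
            if key not in _NOISE_KEYS:
                raise ModelError(f"unknown key {key!r} in extrinsic_noise")
        cfg.noise = OUParams(
            tau_c=float(noise_raw["tau_c"]),
            sigma=float(noise_raw.get("sigma", 0.1)),
            applied_to=frozenset(noise_raw.get("applied_to", [])),
            shared=bool(noise_raw.get("shared", True)),
        )
    cfg.validate()
    return cfg


def read_model_dict(doc: dict) -> tuple[Model, RunConfig]:
    if not isinstance(doc, dict) or not doc:
        raise ModelError("empty or malformed model document")
    for key in doc:
        if key not in _TOP_KEYS:
            raise ModelError(f"unknown top-level key {key!r} in model file")
    model = build_model(doc)
    config = _parse_config(doc.get("config") or {}, doc.get("extrinsic_noise"))
    return model, config


def read_model(path: str) -> tuple[Model, RunConfig]:
    """Read and validate a model file; returns (Model, RunConfig)."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ModelError(f"parse error in {path}: {exc}") from exc
    if doc is None:
        raise ModelError(f"empty model file: {path}")
    try:
        return read_model_dict(doc)
    except ModelError as exc:
        raise ModelError(f"{path}: {exc}") from exc


def write_model(model: Model, config: RunConfig, path: str) -> None:
    doc = model_to_dict(model)
    cfg = {k: getattr(config, k) for k in
           ("T", "C", "D", "v_birth", "t_end", "seed", "grid_dt",
            "max_cells", "record_events")}
    doc["config"] = cfg
    if config.noise is not None:
        doc["extrinsic_noise"] = {
            "tau_c": config.noise.tau_c,
            "sigma": config.noise.sigma,
            "applied_to": sorted(config.noise.applied_to),
            "shared": config.noise.shared,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def to_newick(tree: LineageTree, model: Optional[Model] = None,
              annotate: bool = True) -> str:
    """Newick string with per-node comments (cell id, birth, division)."""

    def render(cid: int) -> str:
        rec = tree.nodes[cid]
        length = rec.result.t_final - rec.t_birth
        comment = ""
        if annotate:
            div = (f"{rec.t_division:.6g}" if rec.t_division is not None
                   else "NA")
            comment = (f"[&cell_id={cid},birth={rec.t_birth:.6g},"
                       f"division={div}]")
        label = f"c{cid}"
        if rec.children:
            inner = ",".join(render(c) for c in rec.children)
            return f"({inner}){label}{comment}:{length:.6g}"
        return f"{label}{comment}:{length:.6g}"

    return render(tree.root_id) + ";\n"


def write_trajectory(rec, model: Model, cm: CompiledModel, fh: TextIO) -> None:
    species = [sp.name for sp in model.species]
    genes = [g.name for g in model.genes]
    fh.write("time_s\tcell_id\tvolume_L\t"
             + "\t".join(species)
             + ("\t" if genes else "")
             + "\t".join(f"copies_{g}" for g in genes) + "\n")
    vols = rec.result.volumes(cm)
    for i, t in enumerate(rec.result.times):
        row = [f"{t:.6f}", str(rec.cell_id), f"{vols[i]:.6e}"]
        row += [str(int(v)) for v in rec.result.counts[i]]
        row += [str(int(v)) for v in rec.result.copies[i]]
        fh.write("\t".join(row) + "\n")


def write_long_table(tree: LineageTree, model: Model, path: str) -> None:
    """Heatmap-ready long-format table (cell, time, species, value)."""
    with open(path, "w") as fh:
        fh.write("cell_id\ttime_s\tspecies\tvalue\n")
        for rec in tree.cells():
            for si, sp in enumerate(model.species):
                for i, t in enumerate(rec.result.times):
                    fh.write(f"{rec.cell_id}\t{t:.6f}\t{sp.name}\t"
                             f"{int(rec.result.counts[i, si])}\n")


def write_schedule(genes, periods: CyclePeriods, t_birth: float, t_end: float,
                   path: str) -> None:
    events = replication_schedule(list(genes), periods, t_birth, t_end)
    with open(path, "w") as fh:
        fh.write("time_s\tgene\tevent\n")
        for ev in events:
            fh.write(f"{ev.time:.6f}\t{ev.gene.name}\t{ev.kind}\n")


def write_outputs(tree: LineageTree, model: Model, cm: CompiledModel,
                  outdir: str, extra_summary: Optional[dict] = None) -> dict:
    """Write trajectory TSVs, lineage Newick, JSON summary and run log."""
    os.makedirs(outdir, exist_ok=True)
    config = cm.config
    for rec in tree.cells():
        with open(os.path.join(outdir, f"cell_{rec.cell_id:04d}.tsv"),
                  "w") as fh:
            fh.write(f"# seed: {config.seed}\n")
            write_trajectory(rec, model, cm, fh)
    with open(os.path.join(outdir, "lineage.nwk"), "w") as fh:
        fh.write(to_newick(tree, model))
    idx = model.species_index
    summary = {
        "model": model.name,
        "seed": config.seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "noise"},
        "n_cells": len(tree),
        "n_leaves": len(tree.leaves()),
        "truncated": tree.truncated,
        "warnings": tree.warnings,
        "cycle_mean_counts": {
            sp.name: {str(rec.cell_id): cycle_mean(rec, idx[sp.name])
                      for rec in tree.cells()}
            for sp in model.species
        },
    }
    if extra_summary:
        summary.update(extra_summary)
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(outdir, "run.log"), "w") as fh:
        fh.write(f"model={model.name} seed={config.seed} "
                 f"cells={len(tree)} truncated={tree.truncated}\n")
        for w in tree.warnings:
            fh.write(f"warning: {w}\n")
    return summary
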