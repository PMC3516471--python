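"""Umbrella pipeline: chain all stages into one reproducible run.

``run_pipeline`` executes simulate? -> preprocess -> diffexp -> enrich ->
cluster -> pairs -> screen -> meta? on either a synthetic dataset or
user-provided TSVs, writes each stage's tables into the output directory
and records a provenance manifest (config hash, seed, per-stage row
counts).  Identical config + seed gives identical outputs; no stage reads
the wall clock or any global RNG.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import cluster as _cluster
from . import diffexp, enrich, meta, pairs, preprocess, srna_screen, synthdata
from . import io as fio


@dataclass
class RunConfig:
    """Configuration of one pipeline run (parsed from YAML for the CLI)."""

    outdir: str
    seed: int = 0
    simulate: dict | None = None  # SimulationConfig fields; None -> read inputs
    probes: str | None = None
    probe_map: str | None = None
    annotation: str | None = None
    design: str | None = None
    gene_sets: str | None = None
    study_tables: dict[str, str] = field(default_factory=dict)
    floor: float = 1.0
    aggregate: str = "any"
    thresholds: diffexp.DEThresholds = field(default_factory=diffexp.DEThresholds)
    cluster_filter: _cluster.ClusterFilter = field(default_factory=_cluster.ClusterFilter)
    screen: srna_screen.ScreenConfig = field(default_factory=srna_screen.ScreenConfig)
    meta_criteria: meta.MetaCriteria = field(default_factory=meta.MetaCriteria)
    run_enrichment: bool = True
    run_clustering: bool = True
    run_pairs: bool = True
    run_screen: bool = True
    n_clusters: int | str = "auto"
    fuzzifier: float | str = "auto"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        for key, typ in (
            ("thresholds", diffexp.DEThresholds),
            ("cluster_filter", _cluster.ClusterFilter),
            ("screen", srna_screen.ScreenConfig),
            ("meta_criteria", meta.MetaCriteria),
        ):
            if key in payload and isinstance(payload[key], dict):
                payload[key] = typ(**payload[key])
        return cls(**payload)

    def digest(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the provenance manifest."""
    fio.ensure_dir(config.outdir)
    manifest: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    # --- inputs -------------------------------------------------------------
    try:
        if config.simulate is not None:
            sim_cfg = synthdata.config_from_dict({"seed": config.seed, **config.simulate})
            dataset = synthdata.generate_dataset(sim_cfg)
            dataset.write(config.outdir)
            probes, probe_map = dataset.probes, dataset.probe_map
            annotation, design = dataset.annotation, dataset.design
            gene_sets = dataset.gene_sets
            marker_id = dataset.marker_id
            record("simulate", n_probes=len(probe_map), n_arrays=len(design))
        else:
            probes = fio.read_tsv(
                config.probes, {"probe_id": str, "array_id": str, "intensity": float}
            )
            probe_map = fio.read_tsv(
                config.probe_map,
                {"probe_id": str, "transcript_id": str, "is_control": bool},
            )
            annotation = fio.read_tsv(
                config.annotation, {"transcript_id": str, "class": str, "partner_id": str}
            )
            design = fio.read_tsv(
                config.design, {"array_id": str, "timepoint": float, "replicate": int}
            )
            gene_sets = fio.read_gmt(config.gene_sets) if config.gene_sets else {}
            marker_id = config.screen.marker_id
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'input' failed: {exc}") from exc

    # --- preprocess ---------------------------------------------------------
    try:
        expr = preprocess.preprocess(
            probes, probe_map, design, floor=config.floor, aggregate=config.aggregate
        )
        fio.write_tsv(expr.values.round(6), out("expression.tsv"), index=True)
        fio.write_tsv(
            expr.expressed.rename("expressed").to_frame(), out("expressed.tsv"), index=True
        )
        record(
            "preprocess",
            n_transcripts=len(expr.values),
            n_expressed=int(expr.expressed.sum()),
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'preprocess' failed: {exc}") from exc

    # --- differential expression --------------------------------------------
    try:
        fc = diffexp.differential_expression(expr, thresholds=config.thresholds)
        fio.write_tsv(fc.round(8), out("de_table.tsv"), index=True)
        record("diffexp", n_tested=len(fc), n_de=int(fc["de_any"].sum()))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'diffexp' failed: {exc}") from exc

    # --- enrichment ----------------------------------------------------------
    if config.run_enrichment and gene_sets:
        try:
            universe = fc.index.tolist()
            ea = enrich.eadeg_enrich(fc, gene_sets, universe)
            pg = enrich.pgsea_enrich(fc, gene_sets)
            fio.write_tsv(ea, out("enrichment_eadeg.tsv"))
            fio.write_tsv(pg, out("enrichment_pgsea.tsv"))
            record("enrich", n_eadeg_rows=len(ea), n_pgsea_rows=len(pg))
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'enrich' failed: {exc}") from exc

    # --- soft clustering ------------------------------------------------------
    if config.run_clustering:
        try:
            std = _cluster.filter_and_standardize(fc, config.cluster_filter)
            if config.n_clusters == "auto" or config.fuzzifier == "auto":
                c, m, diag = _cluster.select_parameters(std, seed=config.seed)
                fio.write_tsv(diag, out("cluster_diagnostics.tsv"))
                if config.n_clusters != "auto":
                    c = int(config.n_clusters)
                if config.fuzzifier != "auto":
                    m = float(config.fuzzifier)
            else:
                c, m = int(config.n_clusters), float(config.fuzzifier)
            soft = _cluster.fuzzy_cmeans(std, c=c, m=m, seed=config.seed)
            labels = soft.labels(config.cluster_filter.membership_cutoff)
            fio.write_tsv(soft.memberships.round(6), out("memberships.tsv"), index=True)
            fio.write_tsv(
                pd.DataFrame(soft.centroids).round(6), out("centroids.tsv"), index=True
            )
            fio.write_tsv(labels.to_frame(), out("cluster_labels.tsv"), index=True)
            record("cluster", c=c, m=m, n_clustered=int((labels > 0).sum()))
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'cluster' failed: {exc}") from exc

    # --- sense-antisense pairs -------------------------------------------------
    if config.run_pairs:
        try:
            pair_table = pairs.analyze_pairs(fc, annotation)
            fio.write_tsv(pair_table.round(6), out("pairs.tsv"))
            record(
                "pairs",
                n_pairs=len(pair_table),
                **{
                    f"class_{k}": int((pair_table.get("pair_class") == k).sum())
                    for k in ("I", "II", "III")
                },
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'pairs' failed: {exc}") from exc

    # --- sRNA marker screen -----------------------------------------------------
    if config.run_screen:
        try:
            srna_ids = annotation.loc[
                annotation["class"] == "sRNA", "transcript_id"
            ].tolist()
            screen_cfg = dataclasses.replace(config.screen, marker_id=marker_id)
            pos, neg = srna_screen.marker_screen(fc, srna_ids, screen_cfg)
            fio.write_tsv(pos.round(6), out("srna_positive.tsv"))
            fio.write_tsv(neg.round(6), out("srna_negative.tsv"))
            record("screen", n_positive=len(pos), n_negative=len(neg))
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'screen' failed: {exc}") from exc

    # --- cross-study meta-analysis ------------------------------------------------
    if config.study_tables:
        try:
            harmonized = {
                name: meta.harmonize(
                    fio.read_tsv(path, {"gene_id": str, "log2fc": float, "p": float}),
                    config.meta_criteria,
                )
                for name, path in config.study_tables.items()
            }
            core = meta.intersect(harmonized)
            fio.write_tsv(core, out("meta_core.tsv"), index=True)
            record(
                "meta",
                n_universe=len(core),
                n_ge2=int(core["in_ge2"].sum()),
                n_core=int(core["in_core"].sum()),
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'meta' failed: {exc}") from exc

    with open(out("manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
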