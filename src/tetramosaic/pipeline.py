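"""End-to-end pipeline driver.

A single YAML config drives all stages; all randomness flows from one
top-level seed. Stages run in order — simulate (or load inputs), classify
markers, infer block tracks, intersect shared non-parental windows and
variants, map to genes, co-localize with QTLs, filter by expression,
compute trait statistics — and each stage writes its outputs before the
next starts, so a partial failure leaves completed outputs intact.
Every threshold used is echoed in the run log. Outputs are deterministic
functions of the declared inputs and the config.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import pysam
import yaml

from tetramosaic import blocks as blk
from tetramosaic import sim as simmod
from tetramosaic.expression import REPRODUCTIVE_TISSUES, expressed_in
from tetramosaic.markers import Origin, classify_all
from tetramosaic.qtl import overlap_qtls, read_qtl_table
from tetramosaic.shared import (
    read_gff3_genes,
    shared_np_variants,
    shared_np_windows,
    variants_to_genes,
)
from tetramosaic.traits import TraitTable, contrasts_to_frame, knockout_contrasts
from tetramosaic.vcfio import read_vcf

__all__ = ["load_config", "validate_params", "run_pipeline"]

log = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, Any] = {
    "min_qual": 30.0,
    "biallelic_only": True,
    "window_size": blk.DEFAULT_WINDOW_SIZE,
    "support_threshold": blk.DEFAULT_SUPPORT,
    "min_markers": blk.DEFAULT_MIN_MARKERS,
    "min_np_markers": blk.DEFAULT_MIN_NP_MARKERS,
    "absence_informative": False,
    "effect_filter": "nonsynonymous",
    "tissues": list(REPRODUCTIVE_TISSUES),
    "expression_threshold": 0.0,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def validate_params(params: Mapping[str, Any]) -> dict[str, Any]:
    merged = {**DEFAULT_PARAMS, **dict(params)}
    unknown = set(merged) - set(DEFAULT_PARAMS)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    if not 0.0 <= merged["support_threshold"] <= 1.0:
        raise ValueError(
            f"support_threshold must be in [0, 1], got {merged['support_threshold']}"
        )
    if merged["window_size"] <= 0:
        raise ValueError("window_size must be positive")
    for key in ("min_markers", "min_np_markers"):
        if merged[key] < 0:
            raise ValueError(f"{key} must be >= 0")
    return merged


def _sim_config_from_mapping(d: Mapping[str, Any], seed: int) -> simmod.SimConfig:
    d = dict(d)
    hotspots = [
        simmod.Hotspot(str(h[0]), int(h[1]), int(h[2]), int(h[3]))
        for h in d.pop("np_hotspots", [])
    ]
    cfg = simmod.SimConfig(seed=seed, **d)
    if hotspots:
        cfg.np_hotspots = hotspots
    cfg.validate()
    return cfg


def run_pipeline(config: str | Path | Mapping[str, Any], out_dir: str | Path | None = None,
                 seed: int | None = None) -> dict[str, Any]:
    """Run all configured stages; returns a result summary dict.

    ``config`` is a YAML path or an equivalent mapping with keys
    ``simulate`` (SimConfig fields) or ``inputs`` (paths to a combined
    VCF, GFF3, QTL table, expression matrix, trait table), plus optional
    ``params`` and ``traits`` sections, ``seed`` and ``out_dir``.
    CLI-style ``out_dir``/``seed`` arguments override the config.
    """
    cfg = load_config(config) if not isinstance(config, Mapping) else dict(config)
    params = validate_params(cfg.get("params", {}))
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("tetramosaic")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t0 = time.time()
    summary: dict[str, Any] = {"out_dir": str(out), "seed": seed, "params": params}
    log.info("parameters: %s", params)

    inputs = dict(cfg.get("inputs", {}))
    truth = None
    try:
        # stage: simulate (optional)
        if "simulate" in cfg:
            sim_cfg = _sim_config_from_mapping(cfg["simulate"] or {}, seed)
            if not sim_cfg.np_hotspots and "np_hotspots" not in (cfg["simulate"] or {}):
                sim_cfg = simmod.default_config(seed)
            ped = simmod.simulate_pedigree(sim_cfg)
            paths = ped.write(out / "sim")
            truth = ped.truth
            inputs.setdefault("vcf", str(paths["combined_vcf"]))
            inputs.setdefault("mother", sim_cfg.mother)
            inputs.setdefault("father", sim_cfg.father)
            inputs.setdefault("sisters", sim_cfg.sisters)
            log.info("simulated pedigree: %d sites, %d sisters [%.1fs]",
                     len(ped.callset), sim_cfg.n_sisters, time.time() - t0)

        # fail early on missing inputs
        for key in ("vcf",):
            if key not in inputs:
                raise FileNotFoundError(f"config declares no input {key!r}")
        for key in ("vcf", "genes_gff3", "qtl_table", "expression_tsv", "trait_table"):
            if key in inputs and not Path(inputs[key]).exists():
                raise FileNotFoundError(f"input {key!r} not found: {inputs[key]}")

        # stage: load + classify
        calls = read_vcf(inputs["vcf"], min_qual=params["min_qual"],
                         biallelic_only=params["biallelic_only"])
        mother, father = inputs["mother"], inputs["father"]
        sisters = list(inputs.get(
            "sisters",
            [s for s in calls.samples if s not in (mother, father)],
        ))
        streams = classify_all(calls, mother, father, sisters,
                               absence_informative=params["absence_informative"])
        markers_dir = out / "markers"
        markers_dir.mkdir(exist_ok=True)
        for sister, stream in streams.items():
            pd.DataFrame(
                [(c.key[0], c.key[1], c.key[2], c.key[3], c.sister, c.origin.value)
                 for c in stream],
                columns=["chrom", "pos", "ref", "alt", "sister", "origin"],
            ).to_csv(markers_dir / f"{sister}.markers.tsv", sep="\t", index=False)
        log.info("classified %d sites x %d sisters [%.1fs]",
                 len(calls), len(sisters), time.time() - t0)

        # stage: block tracks
        chrom_lengths = inputs.get("chrom_lengths")
        if chrom_lengths is None:
            with pysam.VariantFile(inputs["vcf"]) as vf:
                chrom_lengths = {c: ctg.length for c, ctg in vf.header.contigs.items()}
        scaffold = blk.tile_windows(chrom_lengths, params["window_size"])
        tracks = {}
        tracks_dir = out / "tracks"
        tracks_dir.mkdir(exist_ok=True)
        for sister in sisters:
            track = blk.infer_track(
                streams[sister], scaffold,
                support_threshold=params["support_threshold"],
                min_markers=params["min_markers"],
                min_np_markers=params["min_np_markers"],
                sister=sister,
            )
            tracks[sister] = track
            blk.write_bed(track, tracks_dir / f"{sister}.blocks.bed")
        summary["track_summaries"] = {
            s: {t.value: d for t, d in blk.summarize_track(tr).items()}
            for s, tr in tracks.items()
        }
        log.info("inferred %d block tracks [%.1fs]", len(tracks), time.time() - t0)

        # stage: shared non-parental windows / variants
        shared_wins = shared_np_windows(list(tracks.values()))
        shared_keys = shared_np_variants(streams)
        ws = params["window_size"]
        pd.DataFrame(sorted(shared_wins), columns=["chrom", "window_index"]) \
            .assign(start=lambda d: d.window_index * ws,
                    end=lambda d: (d.window_index + 1) * ws) \
            .to_csv(out / "shared_np_windows.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(shared_keys), columns=["chrom", "pos", "ref", "alt"]) \
            .to_csv(out / "shared_np_variants.tsv", sep="\t", index=False)
        summary["n_shared_np_windows"] = len(shared_wins)
        summary["n_shared_np_variants"] = len(shared_keys)
        summary["shared_np_coverage_bp"] = sum(
            min((i + 1) * ws, chrom_lengths[c]) - i * ws for c, i in shared_wins
        )
        log.info("shared non-parental: %d windows, %d variants [%.1fs]",
                 len(shared_wins), len(shared_keys), time.time() - t0)

        # stage: truth recovery (only when simulating)
        if truth is not None:
            summary["truth_recovery"] = _truth_recovery(
                truth, tracks, shared_wins, shared_keys, ws)
            pd.DataFrame([summary["truth_recovery"]]).to_csv(
                out / "truth_recovery.tsv", sep="\t", index=False)

        # stage: genes
        if "genes_gff3" in inputs:
            genes = read_gff3_genes(inputs["genes_gff3"])
            shared_sites = [calls[k] for k in sorted(shared_keys)]
            gene_counts = variants_to_genes(shared_sites, genes,
                                            effect_filter=params["effect_filter"])
            pd.DataFrame(sorted(gene_counts.items()),
                         columns=["gene_id", "n_variants"]) \
                .to_csv(out / "gene_summary.tsv", sep="\t", index=False)
            summary["n_genes_hit"] = len(gene_counts)

        # stage: QTL co-localization
        if "qtl_table" in inputs:
            qtls = read_qtl_table(inputs["qtl_table"])
            hits, tally = overlap_qtls(sorted(shared_keys), qtls)
            hits.to_csv(out / "qtl_report.tsv", sep="\t", index=False)
            summary["n_qtls_overlapped"] = len(hits)
            summary["qtl_category_tally"] = dict(tally)

        # stage: expression filter
        if "expression_tsv" in inputs:
            matrix = pd.read_csv(inputs["expression_tsv"], sep="\t", index_col=0)
            expressed = expressed_in(matrix, params["tissues"],
                                     params["expression_threshold"])
            pd.Series(sorted(expressed), name="gene_id") \
                .to_csv(out / "expressed_genes.tsv", sep="\t", index=False)
            summary["n_expressed_genes"] = len(expressed)

        # stage: trait statistics
        if "trait_table" in inputs and "traits" in cfg:
            table = TraitTable.from_tsv(inputs["trait_table"])
            tcfg = cfg["traits"]
            results, avg = knockout_contrasts(
                table, tcfg["wild_type"], tcfg["mutants"],
                traits=tcfg.get("traits"))
            contrasts_to_frame(results).to_csv(
                out / "trait_contrasts.tsv", sep="\t", index=False)
            summary["avg_decrease"] = avg

        log.info("pipeline complete [%.1fs]", time.time() - t0)
    finally:
        root.removeHandler(handler)
        handler.close()
    return summary


def _truth_recovery(truth, tracks, shared_wins, shared_keys, window_size) -> dict:
    """Compare inferred tracks and shared sets against planted truth."""
    typed = correct = 0
    for sister, track in tracks.items():
        for w in track:
            if w.block_type in (blk.BlockType.MATERNAL, blk.BlockType.PATERNAL):
                typed += 1
                if truth.block_origin.get((sister, w.chrom, w.window_index)) \
                        == w.block_type.value:
                    correct += 1
    truth_wins = truth.shared_np_windows(window_size)
    return {
        "n_typed_windows": typed,
        "n_correct_windows": correct,
        "typed_recovery_pct": 100.0 * correct / typed if typed else float("nan"),
        "shared_windows_match": shared_wins == truth_wins,
        "n_shared_windows_inferred": len(shared_wins),
        "n_shared_windows_truth": len(truth_wins),
        "shared_variants_match": shared_keys == truth.np_sites_shared,
        "n_shared_variants_inferred": len(shared_keys),
        "n_shared_variants_truth": len(truth.np_sites_shared),
    }
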