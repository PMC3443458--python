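"""End-to-end orchestration: simulate -> normalize -> diffexp -> orthologs
-> compare -> enrich, driven by one YAML config and one seed.

Every stage writes plain TSV/JSON artifacts under the output directory
so each stage is also runnable standalone on the previous stage's files;
the summary JSON is byte-identical across reruns of the same config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import arrayio, diffexp, enrich, normalize, orthomap, synthgen, xcompare
from .errors import ConfigError

log = logging.getLogger(__name__)

SPECIES = (synthgen.SPECIES_A, synthgen.SPECIES_B)


@dataclass
class PipelineConfig:
    outdir: str = "dauerx_out"
    seed: int = 0
    fdr_threshold: float = 0.05
    min_bits: float = 50.0
    spike_weight: float = 50.0
    span: float = 0.4
    loess_iterations: int = 4
    min_term_size: int = 1
    min_family_members: int = 5
    synthetic: synthgen.SyntheticStudyConfig | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None:
            raise ConfigError("a [synthetic] study section is required "
                              "(real-data input paths are handled by the "
                              "stage subcommands)")


_SIMPLE_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)} - {"synthetic"}
_SYNTH_KEYS = {f.name for f in dataclasses.fields(synthgen.SyntheticStudyConfig)}
_CLASS_KEYS = {f.name for f in dataclasses.fields(synthgen.ClassCounts)}
_PLANT_KEYS = {f.name for f in dataclasses.fields(synthgen.PlantedEnrichments)}


def config_from_dict(raw: dict[str, Any]) -> PipelineConfig:
    """Build a config with defaults filled in; unknown keys are rejected."""
    raw = dict(raw or {})
    if "synthetic" not in raw:
        raise ConfigError("config requires a 'synthetic' study section")
    synth_raw = raw.pop("synthetic") or {}
    unknown = set(raw) - _SIMPLE_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if not isinstance(synth_raw, dict):
        raise ConfigError("'synthetic' must be a mapping")
    synth_raw = dict(synth_raw)
    cc_raw = synth_raw.pop("class_counts", {}) or {}
    plant_raw = synth_raw.pop("planted", {}) or {}
    for name, sub, allowed in (("synthetic", synth_raw, _SYNTH_KEYS),
                               ("class_counts", cc_raw, _CLASS_KEYS),
                               ("planted", plant_raw, _PLANT_KEYS)):
        bad = set(sub) - allowed
        if bad:
            raise ConfigError(f"unknown {name} key(s): {', '.join(sorted(bad))}")
    if "dye_bias_coefficients" in synth_raw:
        synth_raw["dye_bias_coefficients"] = tuple(
            float(v) for v in synth_raw["dye_bias_coefficients"])
    synth = synthgen.SyntheticStudyConfig(
        class_counts=synthgen.ClassCounts(**cc_raw),
        planted=synthgen.PlantedEnrichments(**plant_raw),
        **synth_raw)
    cfg = PipelineConfig(synthetic=synth, **raw)
    # the pipeline seed drives the simulation too
    cfg.synthetic = dataclasses.replace(cfg.synthetic, seed=stage_seed(cfg.seed, 0))
    return cfg


def validate_config(path: str | os.PathLike) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a key-value document")
    return config_from_dict(raw)


def config_to_dict(cfg: PipelineConfig) -> dict:
    out = {k: getattr(cfg, k) for k in sorted(_SIMPLE_KEYS)}
    synth = dataclasses.asdict(cfg.synthetic)
    synth["dye_bias_coefficients"] = list(synth["dye_bias_coefficients"])
    out["synthetic"] = synth
    return out


def stage_seed(seed: int, stage_index: int) -> int:
    """Deterministic per-stage child seed: seed + stage index."""
    return seed + stage_index


def _json_default(obj):
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    raise TypeError(f"not serializable: {obj!r}")


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_de_table(de: diffexp.DEResult, path: str) -> None:
    cols = ["gene_id", "logFC_dauer_vs_exit", "logFC_dauer_vs_mix",
            "s_g_sq", "d_g", "t_mod", "p", "fdr", "call"]
    de.table[cols].to_csv(path, sep="\t", index=False, float_format="%.8g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the summary dict (also written to disk)."""
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    summary: dict[str, Any] = {"config": config_to_dict(cfg)}

    # ---- stage 0: simulate -------------------------------------------------
    log.info("stage simulate: generating synthetic study")
    study = synthgen.generate_study(cfg.synthetic)
    synth_dir = os.path.join(outdir, "synth")
    os.makedirs(synth_dir, exist_ok=True)
    for scan in study.scans:
        arrayio.write_scan_table(scan, os.path.join(synth_dir, f"{scan.array_id}.tsv"))
    for sp in SPECIES:
        arrayio.write_probe_annotation(
            study.probes[sp], os.path.join(synth_dir, f"probes_{sp}.tsv"))
    arrayio.write_hit_table(study.hits_ab, os.path.join(synth_dir, "hits_ab.tsv"))
    arrayio.write_hit_table(study.hits_ba, os.path.join(synth_dir, "hits_ba.tsv"))
    arrayio.write_annotation_bundle(study.bundle, os.path.join(synth_dir, "annotations"))
    with open(os.path.join(synth_dir, "ground_truth.json"), "w", encoding="utf-8") as fh:
        json.dump(_round_floats(synthgen.truth_to_json_dict(study.truth)), fh,
                  sort_keys=True)

    # ---- stage 1: normalize ------------------------------------------------
    log.info("stage normalize: %d arrays", len(study.scans))
    norm_dir = os.path.join(outdir, "normalized")
    os.makedirs(norm_dir, exist_ok=True)
    normalized: list[normalize.NormalizedArray] = []
    diagnostics = []
    for scan in study.scans:
        arr = normalize.normalize_scan(
            scan, study.probes[scan.species], spike_weight=cfg.spike_weight,
            span=cfg.span, iterations=cfg.loess_iterations)
        normalized.append(arr)
        arr.data.to_csv(os.path.join(norm_dir, f"{arr.array_id}.tsv"),
                        sep="\t", index=False, float_format="%.8g")
        diagnostics.append((arr.array_id, arr.spike_anchor_offset))
    pd.DataFrame(diagnostics, columns=["array_id", "spike_median_offset"]).to_csv(
        os.path.join(norm_dir, "diagnostics.tsv"), sep="\t", index=False,
        float_format="%.8g")

    # ---- stage 2: differential expression ----------------------------------
    de: dict[str, diffexp.DEResult] = {}
    for sp in SPECIES:
        log.info("stage diffexp: species %s", sp)
        de[sp] = diffexp.run_diffexp(normalized, study.probes[sp], sp,
                                     fdr_threshold=cfg.fdr_threshold)
        write_de_table(de[sp], os.path.join(outdir, f"de_{sp}.tsv"))
    summary["table1"] = {sp: de[sp].summary for sp in SPECIES}

    # ---- stage 3: orthologs ------------------------------------------------
    log.info("stage orthologs: reciprocal best hits")
    pairs = orthomap.find_orthologs(study.hits_ab, study.hits_ba,
                                    min_bits=cfg.min_bits)
    genes_a = set(de[SPECIES[0]].table["gene_id"])
    genes_b = set(de[SPECIES[1]].table["gene_id"])
    pairs = orthomap.restrict_to_arrays(pairs, genes_a, genes_b)
    orthomap.write_pairs(pairs, os.path.join(outdir, "pairs.tsv"))
    summary["n_ortholog_pairs"] = len(pairs)

    # ---- stage 4: cross-species comparison ---------------------------------
    log.info("stage compare: %d pairs", len(pairs))
    cmp = xcompare.classify_orthologs(de[SPECIES[0]], de[SPECIES[1]], pairs,
                                      fdr_threshold=cfg.fdr_threshold)
    cmp.table.to_csv(os.path.join(outdir, "comparison.tsv"), sep="\t",
                     index=False, float_format="%.8g")
    fisher = xcompare.overlap_fisher(cmp)
    corr = xcompare.correlation_report(cmp)
    summary["class_counts"] = cmp.class_counts()
    summary["quadrant_counts"] = cmp.quadrant_counts()
    summary["overlap_fisher"] = {
        "a": fisher.a, "b": fisher.b, "c": fisher.c, "d": fisher.d,
        "odds_ratio": fisher.odds_ratio, "p": fisher.p,
    }
    summary["correlations"] = corr.as_dict()

    # ---- stage 5: enrichment layers ----------------------------------------
    log.info("stage enrich: annotation layers")
    enrich_dir = os.path.join(outdir, "enrich")
    os.makedirs(enrich_dir, exist_ok=True)
    bundle = study.bundle
    closed_a = enrich.propagate_to_ancestors(bundle)
    term_names = {t: bundle.term_name(t) for t in bundle.ontology.nodes}
    background = {a for a, _ in pairs}
    t = cmp.table
    class_sets = {
        "class1": set(t.loc[t["class_label"] == "1", "gene_a"]),
        "class2": set(t.loc[t["class_label"] == "2", "gene_a"]),
        "class3": set(t.loc[t["class_label"] == "3", "gene_a"]),
        "class4": set(t.loc[t["class_label"] == "4", "gene_a"]),
    }
    go_tables = {}
    for name, study_set in class_sets.items():
        rows = enrich.term_enrichment(study_set, background, closed_a,
                                      term_names=term_names,
                                      min_term_size=cfg.min_term_size)
        frame = enrich.enrichment_to_frame(rows)
        rel = os.path.join("enrich", f"go_{name}.tsv")
        frame.to_csv(os.path.join(outdir, rel), sep="\t", index=False,
                     float_format="%.6g")
        go_tables[name] = rel
    summary["go_tables"] = go_tables

    # expression clusters: per-species direction sets over the ortholog set
    bundle_b = enrich.transfer_annotations(bundle, pairs)
    b_of = dict(pairs)
    calls_a = de[SPECIES[0]].calls()
    calls_b = de[SPECIES[1]].calls()
    pair_a = [a for a, _ in pairs]
    pair_b = [b_of[a] for a in pair_a]
    direction_sets = {
        "cel_dauer": {g for g in pair_a if calls_a.get(g) == "up"},
        "cel_exit": {g for g in pair_a if calls_a.get(g) == "down"},
        "ppa_dauer": {g for g in pair_b if calls_b.get(g) == "up"},
        "ppa_exit": {g for g in pair_b if calls_b.get(g) == "down"},
    }
    clustered_a = {g for members in bundle.clusters.values() for g in members}
    clustered_b = {g for members in bundle_b.clusters.values() for g in members}
    bg_a = set(pair_a) & clustered_a
    bg_b = set(pair_b) & clustered_b
    clusters_for_column = {"cel_dauer": bundle.clusters, "cel_exit": bundle.clusters,
                           "ppa_dauer": bundle_b.clusters, "ppa_exit": bundle_b.clusters}
    background_for_column = {"cel_dauer": bg_a, "cel_exit": bg_a,
                             "ppa_dauer": bg_b, "ppa_exit": bg_b}
    cluster_scores = enrich.cluster_enrichment(direction_sets, clusters_for_column,
                                               background_for_column,
                                               fdr_threshold=cfg.fdr_threshold)
    cluster_scores.to_csv(os.path.join(enrich_dir, "cluster_scores.tsv"),
                          sep="\t", float_format="%.6g")

    # protein-family profiles
    fam_table, fam_r = enrich.pfam_family_profile(
        de[SPECIES[0]], de[SPECIES[1]], bundle.gene2domain, study.gene2domain_b,
        min_members=cfg.min_family_members)
    fam_table.to_csv(os.path.join(enrich_dir, "family_foldchange.tsv"),
                     sep="\t", index=False, float_format="%.6g")
    summary["family_r"] = fam_r
    summary["n_families"] = int(len(fam_table))

    # pathway tabulation
    kegg = enrich.kegg_tabulate(de[SPECIES[0]], de[SPECIES[1]],
                                bundle.pathway2gene, pairs)
    kegg.to_csv(os.path.join(enrich_dir, "pathway_tabulation.tsv"),
                sep="\t", index=False)

    # pioneer-gene shift test on the species-B fold changes
    pioneers_on_array = bundle.pioneer_genes & genes_b
    summary["pioneer_ks"] = None
    if len(pioneers_on_array) >= 20:
        report, cdf = enrich.subset_shift_test(de[SPECIES[1]].logfc(),
                                               pioneers_on_array)
        cdf.to_csv(os.path.join(enrich_dir, "pioneer_cdf.tsv"), sep="\t",
                   index=False, float_format="%.6g")
        summary["pioneer_ks"] = {"D": report.D, "p": report.p,
                                 "direction": report.direction,
                                 "n_subset": report.n_subset,
                                 "n_complement": report.n_complement}

    summary = _round_floats(summary)
    with open(os.path.join(outdir, "summary.json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1, default=_json_default)
        fh.write("\n")
    log.info("pipeline complete: %s", outdir)
    return summary
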