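"""Pipeline configuration, stage orchestration, and run manifests.

Stages run in the order of the underlying study design: synthetic-data
generation (optional), transcript quality filtering, host/symbiont
partitioning, expression profiling / differential expression, and symbiont
clade typing.  Every stage writes plain-text outputs plus an entry in a run
manifest (parameters and SHA-256 checksums of each output), so two runs with
the same configuration can be verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import clades as cl
from . import dge as dg
from . import io as hio
from . import partition as pt
from . import seqfilter as sf
from . import synthio as sy

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


_DEFAULTS: dict[str, dict[str, Any]] = {
    "simulate": {},  # SynthConfig field overrides
    "filter": {
        "min_codons": 100,
        "min_fpkm": 0.5,
        "cluster_identity": 0.9,
        "run_clustering": False,
    },
    "partition": {"gc_cutoff": "auto", "evalue_cutoff": 1e-10},
    "dge": {
        "min_cpm": 1.0,
        "min_samples": 2,
        "alpha": 0.01,
        "min_fc": 2.0,
        "mds_top": 500,
        "mds_dims": 2,
        "prior_count": 2.0,
    },
    "clades": {
        "dominance_threshold": 0.8,
        "evalue_cutoff": 1e-10,
        "min_len_frac": 0.5,
    },
}

_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    ("filter", "min_codons"): (1, 10_000),
    ("filter", "min_fpkm"): (0, np.inf),
    ("filter", "cluster_identity"): (1e-9, 1.0),
    ("partition", "evalue_cutoff"): (0, 1),
    ("dge", "min_cpm"): (0, np.inf),
    ("dge", "min_samples"): (0, 1000),
    ("dge", "alpha"): (0, 1),
    ("dge", "min_fc"): (1, np.inf),
    ("dge", "mds_top"): (1, np.inf),
    ("dge", "mds_dims"): (1, 100),
    ("dge", "prior_count"): (0, np.inf),
    ("clades", "dominance_threshold"): (0.5, 1.0),
    ("clades", "evalue_cutoff"): (0, 1),
    ("clades", "min_len_frac"): (0, 1),
}


def load_config(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Load and validate a pipeline configuration (YAML file or mapping).

    Unknown keys are rejected; thresholds must fall in their documented
    ranges.  Missing sections and keys take the documented defaults.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    known_top = set(_DEFAULTS) | {"seed"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown configuration sections: {sorted(unknown)}")
    cfg: dict[str, Any] = {"seed": int(raw.get("seed", 0))}
    synth_fields = set(sy.SynthConfig.__dataclass_fields__)
    for section, defaults in _DEFAULTS.items():
        given = raw.get(section) or {}
        if not isinstance(given, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        if section == "simulate":
            bad = set(given) - synth_fields
        else:
            bad = set(given) - set(defaults)
        if bad:
            raise ConfigError(f"unknown keys in {section!r}: {sorted(bad)}")
        merged = {**defaults, **given}
        for key, value in merged.items():
            rng = _RANGES.get((section, key))
            if rng is not None and not (rng[0] <= float(value) <= rng[1]):
                raise ConfigError(
                    f"{section}.{key} = {value} outside allowed range {rng}"
                )
        cfg[section] = merged
    gc = cfg["partition"]["gc_cutoff"]
    if gc != "auto" and not (0.0 < float(gc) < 1.0):
        raise ConfigError("partition.gc_cutoff must be 'auto' or a fraction in (0, 1)")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> dict:
    """Run all stages on a synthetic dataset and write a run manifest.

    Returns the manifest dict; also written as ``manifest.json`` (sorted
    keys, no timestamps, so identical configs give identical bytes).
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": cfg, "stages": {}}

    def record(stage: str, paths: Mapping[str, Path], params: Mapping[str, Any]) -> None:
        manifest["stages"][stage] = {
            "parameters": {k: v for k, v in params.items()},
            "outputs": {k: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                        for k, p in sorted(paths.items())},
        }

    # --- simulate -----------------------------------------------------------
    logger.info("stage simulate: generating synthetic holobiont dataset")
    scfg = sy.SynthConfig(**{**cfg["simulate"], "seed": cfg["seed"]})
    sim_dir = out / "simulate"
    sim_paths = sy.write_dataset(scfg, sim_dir)
    record("simulate", sim_paths, asdict(scfg))

    # --- filter -------------------------------------------------------------
    fprm = cfg["filter"]
    logger.info("stage filter: ORF classification and pooled-FPKM filter")
    records = hio.read_fasta(sim_paths["transcripts"])
    fpkm_df = hio.read_matrix_tsv(sim_paths["fpkm"])
    for rec in records:
        sf.classify_orf(rec, min_codons=int(fprm["min_codons"]))
    orf_kept = {r.id for r in records if r.orf_class is not sf.OrfClass.NONE}
    expr_kept = set(
        sf.expression_filter(
            fpkm_df.to_numpy(), list(fpkm_df.index), cutoff=float(fprm["min_fpkm"])
        )
    )
    kept = [r for r in records if r.id in orf_kept and r.id in expr_kept]
    filt_dir = out / "filter"
    filt_dir.mkdir(exist_ok=True)
    fpaths: dict[str, Path] = {}
    fpaths["qf_fasta"] = filt_dir / "quality_filtered.fasta"
    hio.write_fasta(kept, fpaths["qf_fasta"])
    orf_table = pd.DataFrame(
        {
            "orf_class": [r.orf_class.value for r in records],
            "kept_orf": [r.id in orf_kept for r in records],
            "kept_fpkm": [r.id in expr_kept for r in records],
        },
        index=pd.Index([r.id for r in records], name="transcript_id"),
    )
    fpaths["filter_table"] = filt_dir / "filter_table.tsv"
    orf_table.to_csv(fpaths["filter_table"], sep="\t")
    stats_all = sf.assembly_stats(records)
    stats_kept = sf.assembly_stats(kept)
    fpaths["stats"] = filt_dir / "assembly_stats.tsv"
    pd.DataFrame([asdict(stats_all), asdict(stats_kept)],
                 index=["assembly", "quality_filtered"]).to_csv(
        fpaths["stats"], sep="\t", float_format="%.6g"
    )
    record("filter", fpaths, fprm)
    logger.info("filter kept %d of %d transcripts", len(kept), len(records))

    # --- partition ----------------------------------------------------------
    pprm = cfg["partition"]
    logger.info("stage partition: three-evidence host/symbiont classification")
    evidence = pt.ingest_homology(
        hio.read_evidence_tsv(sim_paths["evidence"]),
        evalue_cutoff=float(pprm["evalue_cutoff"]),
    )
    gc_by_tid = {r.id: r.gc_fraction for r in kept}
    ev_kept = evidence[evidence["query_id"].isin(gc_by_tid)]
    coral_ids = set(
        ev_kept.loc[
            (ev_kept["taxon_group"] == "cnidaria")
            | (ev_kept["method"] == "rbh_coral"),
            "query_id",
        ]
    )
    symb_ids = set(
        ev_kept.loc[
            ev_kept["taxon_group"].isin(pt.SYMBIONT_GROUPS)
            | (ev_kept["method"] == "rbh_symbiont"),
            "query_id",
        ]
    )
    if pprm["gc_cutoff"] == "auto":
        cutoff = pt.estimate_gc_cutoff(
            list(gc_by_tid.values()),
            [gc_by_tid[t] for t in coral_ids - symb_ids],
            [gc_by_tid[t] for t in symb_ids],
            method="valley",
        )
    else:
        cutoff = pt.GcCutoff(cutoff=float(pprm["gc_cutoff"]), method="fixed")
    results = pt.partition_transcripts(gc_by_tid, ev_kept, cutoff)
    part_dir = out / "partition"
    part_dir.mkdir(exist_ok=True)
    ppaths: dict[str, Path] = {"partition_table": part_dir / "partition.tsv"}
    results.to_csv(ppaths["partition_table"], sep="\t", float_format="%.6g")
    coral_records = [r for r in kept if results.loc[r.id, "label"] == "coral"]
    ppaths["coral_fasta"] = part_dir / "coral.fasta"
    hio.write_fasta(coral_records, ppaths["coral_fasta"])
    record(
        "partition",
        ppaths,
        {**pprm, "estimated_cutoff": round(cutoff.cutoff, 6), "cutoff_method": cutoff.method},
    )
    logger.info(
        "partition: %d coral / %d non-coral at GC cutoff %.4f",
        len(coral_records), len(kept) - len(coral_records), cutoff.cutoff,
    )

    # --- dge ----------------------------------------------------------------
    dprm = cfg["dge"]
    logger.info("stage dge: CPM filter, TMM, MDS and pairwise exact tests")
    counts = hio.read_matrix_tsv(sim_paths["counts"], integer=True)
    meta = hio.read_sample_metadata(sim_paths["samples"])
    groups = meta.loc[counts.columns, "tissue"].to_numpy()
    lib_sizes = counts.sum(axis=0).to_numpy(float)
    kept_counts = dg.cpm_filter(
        counts, min_cpm=float(dprm["min_cpm"]), min_samples=int(dprm["min_samples"]),
        lib_sizes=lib_sizes,
    )
    factors = dg.tmm_factors(kept_counts, lib_sizes=lib_sizes)
    lc = dg.log_cpm(kept_counts, lib_sizes, factors.to_numpy(),
                    prior_count=float(dprm["prior_count"]))
    D = dg.leading_logfc_distance_matrix(lc, top=int(dprm["mds_top"]))
    emb = dg.classical_mds(D, k=int(dprm["mds_dims"]))
    phi = dg.estimate_common_dispersion(
        kept_counts, groups, lib_sizes, factors.to_numpy()
    )
    dge_dir = out / "dge"
    dge_dir.mkdir(exist_ok=True)
    dpaths: dict[str, Path] = {}
    dpaths["mds"] = dge_dir / "mds_coordinates.tsv"
    emb.coordinates.to_csv(dpaths["mds"], sep="\t", float_format="%.6g")
    dpaths["tmm"] = dge_dir / "tmm_factors.tsv"
    factors.to_csv(dpaths["tmm"], sep="\t", float_format="%.6g")
    contrast_results: dict[tuple[str, str], dg.ContrastResult] = {}
    tissues = list(dict.fromkeys(groups))
    for i in range(len(tissues)):
        for j in range(i + 1, len(tissues)):
            a, b = tissues[i], tissues[j]
            res = dg.contrast_table(
                kept_counts, groups, a, b, phi, lib_sizes, factors.to_numpy(),
                alpha=float(dprm["alpha"]), min_fold_change=float(dprm["min_fc"]),
                prior_count=float(dprm["prior_count"]),
            )
            contrast_results[(a, b)] = res
            p = dge_dir / f"dge_{a}_vs_{b}.tsv"
            res.table.to_csv(p, sep="\t", float_format="%.6g")
            dpaths[f"dge_{a}_vs_{b}"] = p
    sets, union, venn = dg.call_degs(contrast_results)
    dpaths["venn"] = dge_dir / "deg_overlap.tsv"
    pd.DataFrame(
        {"region": list(venn), "n_genes": list(venn.values())}
    ).to_csv(dpaths["venn"], sep="\t", index=False)
    record("dge", dpaths, {**dprm, "common_dispersion": round(float(phi), 6),
                           "n_genes_tested": int(kept_counts.shape[0]),
                           "n_deg_union": len(union)})
    logger.info("dge: phi=%.4f, %d DEGs in union", phi, len(union))

    # --- clades -------------------------------------------------------------
    cprm = cfg["clades"]
    logger.info("stage clades: JC distances, NJ trees and clade composition")
    mfpkm = pd.read_csv(sim_paths["marker_fpkm"], sep="\t")
    clade_dir = out / "clades"
    clade_dir.mkdir(exist_ok=True)
    cpaths: dict[str, Path] = {}
    per_marker_calls: dict[str, list[cl.CladeCall]] = {}
    for marker in cl.MARKERS:
        aln = {r.id: r.sequence for r in hio.read_fasta(sim_paths[f"markers_{marker}"])}
        D = cl.jc_distance_matrix(aln)
        tree = cl.neighbor_joining(D)
        tpath = clade_dir / f"{marker}.nwk"
        tpath.write_text(tree + "\n")
        cpaths[f"tree_{marker}"] = tpath
        refs = {t: t.split("_", 1)[1] for t in aln if t.startswith("ref_")}
        queries = [t for t in aln if not t.startswith("ref_")]
        assignments = cl.assign_clade(tree, refs, queries)
        sub = mfpkm[mfpkm["marker"] == marker]
        fpkm_of = dict(zip(sub["transcript_id"], sub["fpkm"]))
        colony_of = dict(zip(sub["transcript_id"], sub["colony"]))
        calls = cl.clade_composition(
            assignments, fpkm_of, colony_of,
            dominance_threshold=float(cprm["dominance_threshold"]),
        )
        per_marker_calls[marker] = calls
        cpath = clade_dir / f"clade_calls_{marker}.tsv"
        pd.DataFrame(
            [
                {"colony": c.colony, "dominant": c.dominant,
                 **{f"prop_{k}": round(v, 6) for k, v in c.proportions.items()}}
                for c in calls
            ]
        ).to_csv(cpath, sep="\t", index=False)
        cpaths[f"calls_{marker}"] = cpath
    consensus = cl.consensus_calls(per_marker_calls)
    cpaths["consensus"] = clade_dir / "clade_calls_consensus.tsv"
    pd.Series(consensus, name="dominant_clade").rename_axis("colony").sort_index().to_csv(
        cpaths["consensus"], sep="\t"
    )
    record("clades", cpaths, cprm)
    logger.info("clades: consensus calls for %d colonies", len(consensus))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["manifest_path"] = str(manifest_path)
    return manifest
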