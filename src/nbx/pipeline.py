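"""End-to-end orchestration of the hypoxia/prognosis gene-discovery study.

Stages, in dependency order:

1. differential expression per dataset (cohort survivor models, cell-line
   hypoxia mixed models, or ingested external DE tables), dual-criterion
   DEG selection;
2. k-way signature intersection with direction-consistency accounting and
   the Monte-Carlo overlap null; the candidate genes are exactly the
   direction-consistent members of the all-datasets intersection;
3. survival: sliding-window cutpoint scan over all genes per cohort with
   pooled genes x windows q-correction, univariate and multivariate Cox
   fits for candidates, and the DEG-prognosis permutation test;
4. optional qPCR 2^-ddCt validation and promoter-peak annotation.

Every stage writes plain TSV/JSON artifacts before the next stage reads
its in-memory results, and a run manifest records thresholds, seeds and
input checksums. Per-stage RNG seeds are derived deterministically from
the master seed by CRC-hashing the stage name, so stages are reproducible
in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import (
    DEGTable,
    ExpressionDataset,
    read_bed,
    read_clinical_tsv,
    read_expression_tsv,
    read_feature_map_tsv,
)
from .diffexpr import build_deg_table, ingest_external_deg_table
from .integrate import (
    SignatureSet,
    annotate_genes_with_peaks,
    intersect_signatures,
    permutation_overlap_test,
)
from .qpcr import quantify_plate
from .survival import cox_scan, deg_survival_permutation, scan_all_genes

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "run_study",
           "stage_seed"]

log = logging.getLogger(__name__)

_DEFAULT_THRESHOLDS = {
    "fdr_max": 0.01,
    "fc_decile": 0.10,
    "fc_decile_scope": "universe",
    "min_fraction": 0.02,
    "prognostic_fdr": 0.01,
    "ora_q": 0.05,
    "promoter_window": 2000,
}
_DEFAULT_PERMUTATIONS = {"n_permutations": 100_000, "seed": 0}
_KNOWN_TOP_KEYS = {"datasets", "thresholds", "permutations", "outdir",
                   "log_level", "qpcr", "peaks"}
_KNOWN_DATASET_KEYS = {"id", "type", "expression", "clinical", "feature_map",
                       "path", "column_map", "universe_size", "survival"}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    datasets: list[dict] = field(default_factory=list)
    thresholds: dict = field(default_factory=lambda: dict(_DEFAULT_THRESHOLDS))
    permutations: dict = field(default_factory=lambda: dict(_DEFAULT_PERMUTATIONS))
    outdir: str = "nbx_out"
    log_level: str = "INFO"
    qpcr: dict | None = None
    peaks: dict | None = None


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and normalize a YAML pipeline config.

    Defaults are filled in (DEG FDR < 0.01, top/bottom 10% fold-change
    decile, 2% survival window fraction, 100,000 permutations); unknown
    keys and out-of-range thresholds are rejected with the offending key
    named.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - _KNOWN_TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    thresholds = dict(_DEFAULT_THRESHOLDS)
    thresholds.update(raw.get("thresholds") or {})
    unknown = set(thresholds) - set(_DEFAULT_THRESHOLDS)
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    for key in ("fdr_max", "prognostic_fdr", "ora_q"):
        if not (0 < thresholds[key] <= 1):
            raise ValueError(f"threshold {key} out of range: {thresholds[key]}")
    if not (0 < thresholds["fc_decile"] < 0.5):
        raise ValueError(f"threshold fc_decile out of range: {thresholds['fc_decile']}")
    if not (0 < thresholds["min_fraction"] < 0.5):
        raise ValueError(
            f"threshold min_fraction out of range: {thresholds['min_fraction']}"
        )

    permutations = dict(_DEFAULT_PERMUTATIONS)
    permutations.update(raw.get("permutations") or {})
    if permutations["n_permutations"] < 1:
        raise ValueError("permutations.n_permutations must be >= 1")

    datasets = raw.get("datasets") or []
    for entry in datasets:
        unknown = set(entry) - _KNOWN_DATASET_KEYS
        if unknown:
            raise ValueError(f"unknown dataset keys: {sorted(unknown)}")
        if entry.get("type") not in ("cohort", "cellline", "external_deg"):
            raise ValueError(
                f"dataset {entry.get('id')!r}: type must be cohort, cellline "
                f"or external_deg"
            )
    return PipelineConfig(
        datasets=datasets,
        thresholds=thresholds,
        permutations=permutations,
        outdir=raw.get("outdir", "nbx_out"),
        log_level=raw.get("log_level", "INFO"),
        qpcr=raw.get("qpcr"),
        peaks=raw.get("peaks"),
    )


def _load_dataset(entry: dict) -> ExpressionDataset:
    for key in ("expression", "clinical"):
        if key not in entry:
            raise ValueError(f"dataset {entry.get('id')!r} missing {key!r} path")
        if not Path(entry[key]).exists():
            raise FileNotFoundError(
                f"dataset {entry.get('id')!r}: {key} path {entry[key]} not found"
            )
    matrix = read_expression_tsv(entry["expression"])
    ann = read_clinical_tsv(entry["clinical"])
    fmap = (
        read_feature_map_tsv(entry["feature_map"])
        if entry.get("feature_map")
        else None
    )
    return ExpressionDataset(
        matrix, ann, feature_map=fmap, dataset_id=entry.get("id", "dataset")
    )


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_study(
    deg_tables: dict[str, DEGTable],
    cohorts: dict[str, ExpressionDataset],
    thresholds: dict | None = None,
    n_permutations: int = 100_000,
    seed: int = 0,
    outdir: str | Path | None = None,
    qpcr_table: pd.DataFrame | None = None,
    gene_bed: pd.DataFrame | None = None,
    peak_bed: pd.DataFrame | None = None,
    scan_genes: list[str] | None = None,
) -> dict:
    """Integration + survival + validation stages on prepared DEG tables.

    ``deg_tables`` holds one DEGTable per dataset (order defines the
    intersection); ``cohorts`` maps cohort IDs (a subset of the dataset
    IDs) to expression datasets with survival annotations. ``scan_genes``
    optionally restricts the cutpoint scan (the q pool) to a gene subset.

    Returns a dict with the overlap report, permutation result, candidate
    report DataFrame, per-cohort scan summaries, Cox tables and optional
    qPCR / peak tables.
    """
    th = dict(_DEFAULT_THRESHOLDS)
    th.update(thresholds or {})
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- intersection & permutation null -------------------------------
    sigs = [SignatureSet.from_deg_table(t) for t in deg_tables.values()]
    overlap = intersect_signatures(sigs)
    perm = permutation_overlap_test(
        set_sizes=[len(s.genes) for s in sigs],
        universes=[s.universe for s in sigs],
        observed=overlap.n_shared,
        n_permutations=n_permutations,
        seed=stage_seed(seed, "overlap_permutation"),
    )
    candidates = sorted(overlap.consistent_genes)
    log.info(
        "%d shared genes, %d direction-consistent candidates",
        overlap.n_shared,
        len(candidates),
    )
    if out is not None:
        (out / "overlap.json").write_text(
            json.dumps(
                {
                    "member_sets": overlap.member_sets,
                    "n_shared": overlap.n_shared,
                    "shared_genes": sorted(overlap.shared_genes),
                    "n_direction_consistent": overlap.n_direction_consistent,
                    "candidates": candidates,
                    "permutation": perm.summary(),
                },
                indent=1,
            )
        )

    # --- survival stage -------------------------------------------------
    scans: dict[str, pd.DataFrame] = {}
    cox_uni: dict[str, pd.DataFrame] = {}
    cox_multi: dict[str, pd.DataFrame] = {}
    for cid, data in cohorts.items():
        scans[cid] = scan_all_genes(
            data, min_fraction=th["min_fraction"], genes=scan_genes
        )
        if out is not None:
            scans[cid].to_csv(out / f"scan_{cid}.tsv", sep="\t", index=False)
        if candidates:
            present = [g for g in candidates if g in data.matrix.index]
            covars = [
                c for c in ("mycn", "stage", "age")
                if c in data.sample_annotations.columns
            ]
            cox_uni[cid] = cox_scan(data, genes=present)
            cox_multi[cid] = cox_scan(data, genes=present, covariates=covars)
            if out is not None:
                merged = cox_uni[cid].merge(
                    cox_multi[cid],
                    on="gene",
                    suffixes=("_uni", "_multi"),
                )
                merged.to_csv(out / f"cox_{cid}.tsv", sep="\t", index=False)

    # --- DEG-prognosis permutation test ---------------------------------
    deg_perm = None
    cohort_ids = list(cohorts)
    if len(cohort_ids) >= 2 and candidates:
        c1, c2 = cohort_ids[0], cohort_ids[1]
        prog = tuple(
            set(
                scans[c][scans[c]["min_q"] < th["prognostic_fdr"]]["gene"]
            )
            for c in (c1, c2)
        )
        prog_both = prog[0] & prog[1]
        deg_lists = (
            sorted(deg_tables[c1].genes),
            sorted(deg_tables[c2].genes),
        )
        observed = tuple(
            len([g for g in candidates if g in prog_both]) for _ in range(2)
        )
        draw = tuple(
            min(len(candidates), len(lst)) for lst in deg_lists
        )
        if min(draw) > 0:
            deg_perm = deg_survival_permutation(
                deg_lists,
                prog,
                observed=observed,
                draw_sizes=draw,
                n_permutations=n_permutations,
                seed=stage_seed(seed, "deg_survival_permutation"),
            )

    # --- optional validation stages -------------------------------------
    qpcr_results = (
        quantify_plate(qpcr_table) if qpcr_table is not None else None
    )
    peak_flags = (
        annotate_genes_with_peaks(gene_bed, peak_bed, th["promoter_window"])
        if gene_bed is not None and peak_bed is not None
        else None
    )

    # --- candidate report -----------------------------------------------
    rows = []
    for g in candidates:
        row: dict = {"gene": g, "direction": overlap.directions.get(g, "")}
        for did, table in deg_tables.items():
            row[f"deg_{did}"] = g in table.genes
        for cid in cohorts:
            scan = scans[cid]
            hit = scan[scan["gene"] == g]
            row[f"min_q_{cid}"] = (
                float(hit["min_q"].iloc[0]) if len(hit) else np.nan
            )
            if cid in cox_uni:
                uni = cox_uni[cid].set_index("gene")
                multi = cox_multi[cid].set_index("gene")
                row[f"cox_q_uni_{cid}"] = (
                    float(uni.loc[g, "q"]) if g in uni.index else np.nan
                )
                row[f"cox_q_multi_{cid}"] = (
                    float(multi.loc[g, "q"]) if g in multi.index else np.nan
                )
        if qpcr_results is not None:
            hit = qpcr_results[qpcr_results["gene"] == g]
            if len(hit):
                row["qpcr_log2_fold"] = float(hit["log2_fold"].iloc[0])
                row["qpcr_p"] = float(hit["p"].iloc[0])
        if peak_flags is not None:
            hit = peak_flags[peak_flags["gene"] == g]
            row["peak_flag"] = bool(hit["flagged"].iloc[0]) if len(hit) else False
        rows.append(row)
    report = pd.DataFrame(rows)
    if out is not None:
        report.to_csv(out / "candidate_report.tsv", sep="\t", index=False)

    return {
        "overlap": overlap,
        "overlap_permutation": perm,
        "candidates": candidates,
        "candidate_report": report,
        "scans": scans,
        "cox_univariate": cox_uni,
        "cox_multivariate": cox_multi,
        "deg_survival_permutation": deg_perm,
        "qpcr": qpcr_results,
        "peaks": peak_flags,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow described by a validated config.

    Loads every dataset, runs differential expression, then hands off to
    :func:`run_study`. Writes per-stage artifacts plus a run manifest
    (version, seeds, thresholds, input checksums) under ``config.outdir``.
    """
    if not config.datasets:
        raise ValueError("config lists no datasets")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    seed = int(config.permutations.get("seed", 0))
    n_perm = int(config.permutations.get("n_permutations", 100_000))

    checksums = {}
    deg_tables: dict[str, DEGTable] = {}
    cohorts: dict[str, ExpressionDataset] = {}
    for entry in config.datasets:
        did = entry.get("id") or f"dataset{len(deg_tables)}"
        try:
            if entry["type"] == "external_deg":
                path = entry.get("path")
                if not path or not Path(path).exists():
                    raise FileNotFoundError(
                        f"dataset {did!r}: path {path} not found"
                    )
                checksums[did] = _checksum(path)
                deg_tables[did] = ingest_external_deg_table(
                    path,
                    dataset_id=did,
                    column_map=entry.get("column_map"),
                    universe_size=entry.get("universe_size"),
                    fdr_max=th["fdr_max"],
                    fc_decile=th["fc_decile"],
                )
            else:
                data = _load_dataset(entry)
                checksums[did] = _checksum(entry["expression"])
                kind = "cohort" if entry["type"] == "cohort" else "cellline"
                deg_tables[did] = build_deg_table(
                    data,
                    kind=kind,
                    fdr_max=th["fdr_max"],
                    fc_decile=th["fc_decile"],
                    fc_decile_scope=th["fc_decile_scope"],
                )
                if kind == "cohort" and entry.get("survival", True):
                    cohorts[did] = data
        except Exception as exc:
            raise RuntimeError(
                f"pipeline halted at differential-expression stage for "
                f"dataset {did!r}: {exc}"
            ) from exc
        deg_tables[did].write(out / f"deg_{did}.tsv")

    qpcr_table = None
    if config.qpcr and config.qpcr.get("ct_table"):
        qpcr_table = pd.read_csv(config.qpcr["ct_table"])
        checksums["qpcr"] = _checksum(config.qpcr["ct_table"])
    gene_bed = peak_bed = None
    if config.peaks:
        gene_bed = read_bed(config.peaks["gene_bed"])
        peak_bed = read_bed(config.peaks["peak_bed"])

    result = run_study(
        deg_tables,
        cohorts,
        thresholds=th,
        n_permutations=n_perm,
        seed=seed,
        outdir=out,
        qpcr_table=qpcr_table,
        gene_bed=gene_bed,
        peak_bed=peak_bed,
    )

    manifest = {
        "nbx_version": __version__,
        "master_seed": seed,
        "stage_seeds": {
            s: stage_seed(seed, s)
            for s in ("overlap_permutation", "deg_survival_permutation")
        },
        "n_permutations": n_perm,
        "thresholds": th,
        "input_checksums": checksums,
        "datasets": [e.get("id") for e in config.datasets],
        "n_candidates": len(result["candidates"]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
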