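"""Pipeline orchestration and summary reporting.

Runs the two-step analysis end to end — null-model fit (Step 1), masked and
collapsed set tests per gene (Step 2), gene-level aggregation — and writes
the per-cell TSV, gene-level TSV, Q-Q data and a run manifest.  Also houses
the genomic-control and Q-Q helpers used by the study harnesses.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .aggregation import combine_gene, significance_flag
from .collapsing import WeightScheme, WeightKind
from .null_model import NullModelFit, fit_null_glm, load_null_model
from .set_tests import SetTestResult, run_gene
from .variant_io import (
    Annotation,
    MaskSpec,
    load_gene_dosages,
    parse_group_file,
)

logger = logging.getLogger(__name__)

CHI2_1_MEDIAN = 0.454936423119572  # median of the 1-df chi-square


def lambda_gc(pvals) -> float:
    """Genomic-control inflation factor: the median 1-df chi-square quantile
    of the p-values over the null median 0.4549."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.median(stats.chi2.isf(p, 1)) / CHI2_1_MEDIAN)


def qq_points(pvals) -> list[tuple[float, float]]:
    """(expected, observed) -log10 p pairs for a Q-Q plot, ascending in
    expected; expected_i = -log10((i - 0.5) / n) over the sorted observed."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    obs = -np.log10(np.sort(p)[::-1])  # ascending -log10
    n = p.size
    exp = -np.log10((np.arange(n, 0, -1) - 0.5) / n)
    return list(zip(exp.tolist(), obs.tolist()))


# ---------------------------------------------------------------------------
# manifest


def _file_checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, command: str, config: dict,
                   inputs: list[str | Path], seed: int | None) -> Path:
    """One manifest per output directory: version, command, config hash,
    input checksums, seed, timestamp."""
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "tool": "rvset",
        "version": __version__,
        "command": command,
        "config_hash": cfg_hash,
        "inputs": {str(p): _file_checksum(Path(p)) for p in inputs if Path(p).exists()},
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


# ---------------------------------------------------------------------------
# phenotype / mask parsing helpers shared by CLI and run_pipeline


def read_phenotypes(path, pheno_col: str, covar_cols: list[str] | None):
    """Phenotype/covariate TSV with a header and a sample_id column."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("phenotype TSV must contain a sample_id column")
    if pheno_col not in df.columns:
        raise ValueError(f"phenotype column {pheno_col!r} not in TSV")
    covar_cols = covar_cols or []
    missing = [c for c in covar_cols if c not in df.columns]
    if missing:
        raise ValueError(f"covariate column(s) missing from TSV: {missing}")
    y = df[pheno_col].to_numpy(dtype=float)
    X = df[covar_cols].to_numpy(dtype=float) if covar_cols else None
    return df["sample_id"].astype(str).tolist(), y, X


def parse_mask_arg(annotation_masks: str, max_maf_cutoffs: str) -> list[MaskSpec]:
    """CLI mask grammar: masks separated by ';', annotations by ',' within a
    mask; cutoffs comma-separated.  E.g. ``lof;lof,missense`` x ``0.01,0.001``."""
    cutoffs = [float(x) for x in str(max_maf_cutoffs).split(",") if x]
    groups = [
        frozenset(Annotation(tok) for tok in grp.split(",") if tok)
        for grp in annotation_masks.split(";") if grp
    ]
    return [MaskSpec(g, c) for g in groups for c in cutoffs]


def parse_weights_arg(spec: str, n_variants: int | None = None) -> WeightScheme:
    """``beta:a,b`` (default beta:1,25), ``none`` or a path to a one-column
    weight file aligned with the group-file variant order."""
    if spec.startswith("beta"):
        a, b = (1.0, 25.0)
        if ":" in spec:
            a, b = (float(x) for x in spec.split(":", 1)[1].split(","))
        return WeightScheme(kind=WeightKind.BETA_DEFAULT, beta_a=a, beta_b=b)
    if spec == "none":
        return WeightScheme(kind=WeightKind.NONE)
    w = np.loadtxt(spec, dtype=float, ndmin=1)
    return WeightScheme(kind=WeightKind.USER_WEIGHTS, user_w=w)


# ---------------------------------------------------------------------------
# TSV writers (bit-stable column ordering)

CELL_COLUMNS = [
    "gene", "mask_annotations", "max_maf", "m_markers_pre", "m_markers_post",
    "collapsed", "p_burden", "p_skat", "p_skato", "spa_applied", "method_tail",
    "provenance",
]

GENE_COLUMNS = [
    "gene", "p_cauchy_skato", "p_cauchy_skat", "p_cauchy_burden", "n_cells",
    "fallback_minp", "best_mask", "best_max_maf", "significant",
]


def cells_to_frame(cells: list[SetTestResult]) -> pd.DataFrame:
    rows = [
        {
            "gene": c.gene_id,
            "mask_annotations": c.mask.label(),
            "max_maf": c.mask.max_maf,
            "m_markers_pre": c.m_markers_pre,
            "m_markers_post": c.m_markers,
            "collapsed": c.collapsed,
            "p_burden": c.p_burden,
            "p_skat": c.p_skat,
            "p_skato": c.p_skato,
            "spa_applied": c.spa_applied,
            "method_tail": c.method_tail,
            "provenance": ";".join(c.provenance),
        }
        for c in cells
    ]
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def genes_to_frame(per_gene: dict[str, list[SetTestResult]],
                   threshold: float = 2.5e-6) -> pd.DataFrame:
    rows = []
    for gene, cells in per_gene.items():
        if not cells:
            continue
        combined = {t: combine_gene(cells, t) for t in ("skato", "skat", "burden")}
        gr = combined["skato"]
        rows.append({
            "gene": gene,
            "p_cauchy_skato": combined["skato"].p_combined,
            "p_cauchy_skat": combined["skat"].p_combined,
            "p_cauchy_burden": combined["burden"].p_combined,
            "n_cells": gr.n_cells,
            "fallback_minp": gr.fallback_minp,
            "best_mask": gr.best_cell[0],
            "best_max_maf": gr.best_cell[1],
            "significant": significance_flag(gr, threshold),
        })
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_step2(
    fit: NullModelFit,
    vcf_path,
    group_file,
    masks: list[MaskSpec],
    scheme: WeightScheme,
    mac_threshold: float,
) -> dict[str, list[SetTestResult]]:
    """Step 2 over every gene in the group file; failing genes are logged and
    skipped, aborting if more than 10% fail."""
    groups = parse_group_file(group_file)
    if not groups:
        raise ValueError(f"group file {group_file} contains no genes")
    per_gene: dict[str, list[SetTestResult]] = {}
    failures = 0
    for gene, items in groups.items():
        try:
            gvs = load_gene_dosages(
                vcf_path, fit.sample_ids,
                [v for v, _ in items], [a for _, a in items], gene_id=gene,
            )
            cells = run_gene(fit, gvs, masks, scheme, mac_threshold)
            if cells:
                per_gene[gene] = cells
        except Exception:
            failures += 1
            logger.exception("gene %s failed; skipped", gene)
    if failures > 0.1 * len(groups):
        raise RuntimeError(f"{failures}/{len(groups)} genes failed; aborting")
    for gene, cells in per_gene.items():
        for c in cells:
            logger.info("gene %s cell (%s, %g): markers %d -> %d",
                        gene, c.mask.label(), c.mask.max_maf,
                        c.m_markers_pre, c.m_markers)
    return per_gene


def run_pipeline(config: dict) -> Path:
    """Full step1 -> step2 -> aggregate run from a config mapping.

    Required keys: pheno, pheno_col, vcf, group_file, out.  Optional:
    covar_cols (list), trait_type, offset_covariates (bool), model (reuse a
    Step 1 archive), max_maf_cutoffs, annotation_masks, mac_collapse_threshold,
    weights, significance_threshold, seed."""
    out_dir = Path(config["out"])
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.get("model"):
        fit = load_null_model(config["model"])
    else:
        sample_ids, y, X = read_phenotypes(
            config["pheno"], config["pheno_col"], config.get("covar_cols"))
        fit = fit_null_glm(
            y, X, config.get("trait_type", "binary"),
            offset_mode=bool(config.get("offset_covariates", False)),
            sample_ids=sample_ids,
        )

    masks = parse_mask_arg(
        config.get("annotation_masks", "lof;lof,missense;lof,missense,synonymous"),
        config.get("max_maf_cutoffs", "0.01,0.001,0.0001"),
    )
    scheme = parse_weights_arg(config.get("weights", "beta:1,25"))
    per_gene = run_step2(
        fit, config["vcf"], config["group_file"], masks, scheme,
        float(config.get("mac_collapse_threshold", 10.0)),
    )

    all_cells = [c for cells in per_gene.values() for c in cells]
    cells_to_frame(all_cells).to_csv(out_dir / "cells.tsv", sep="\t", index=False)
    gene_df = genes_to_frame(per_gene, float(config.get("significance_threshold", 2.5e-6)))
    gene_df.to_csv(out_dir / "genes.tsv", sep="\t", index=False)

    if len(gene_df):
        pts = qq_points(gene_df["p_cauchy_skato"].to_numpy())
        pd.DataFrame(pts, columns=["expected", "observed"]).to_csv(
            out_dir / "qq.tsv", sep="\t", index=False)
    write_manifest(
        out_dir, command="run_pipeline", config=config,
        inputs=[config.get("pheno", ""), config["vcf"], config["group_file"]],
        seed=config.get("seed"),
    )
    return out_dir
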