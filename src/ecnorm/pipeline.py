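"""End-to-end workflow: normalize -> test -> select -> in-silico validate.

``run_pipeline`` wires the whole analysis together and writes every
intermediate as CSV plus a machine-readable run manifest, so a run is
fully reproducible from its output directory alone.  ``validate_inputs``
performs the same input checks as a dry run, reporting problems instead of
raising.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .diffexp import DispersionEstimates, estimate_dispersions, nb_wald_test
from .errors import EcnormError, ValidationError
from .insilico import RECAPITULATION_RULE, compare_ecs, evaluate_ratio, normalization_ratio
from .io import (CountMatrix, SampleMetadata, read_count_matrix, read_metadata,
                 write_results_csv)
from .normalization import estimate_size_factors, normalize_counts
from .selection import SelectionThresholds, select_degs, select_ecs, stability_report
from .viz import plot_heatmap, plot_ratio_boxplot, plot_volcano

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

logger = logging.getLogger("ecnorm")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    counts: str
    metadata: str
    outdir: str
    group_col: str = "group"
    reference: str | None = None
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    zero_policy: str = "exclude"
    shrink: bool = True
    pseudo_reference: bool = False
    strict_counts: bool = True
    top_n_biomarkers: int = 5
    top_n_ecs: int = 3
    heatmap_top_n: int = 20
    make_plots: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = self.thresholds.to_dict()
        return d


def validate_inputs(cfg: PipelineConfig) -> list[dict]:
    """Dry-run validation; returns a list of problem records (empty = OK)."""
    problems: list[dict] = []

    def add(kind: str, message: str) -> None:
        problems.append({"kind": kind, "message": message})

    cm = meta = None
    if not Path(cfg.counts).exists():
        add("file-not-found", f"count matrix file not found: {cfg.counts}")
    else:
        try:
            cm = read_count_matrix(cfg.counts, strict=cfg.strict_counts)
        except EcnormError as exc:
            add("bad-count-matrix", str(exc))
    if not Path(cfg.metadata).exists():
        add("file-not-found", f"metadata file not found: {cfg.metadata}")
    else:
        try:
            meta = read_metadata(cfg.metadata, group_col=cfg.group_col,
                                 reference=cfg.reference)
        except EcnormError as exc:
            add("bad-design", str(exc))
    if cm is not None and meta is not None:
        try:
            meta.aligned_to(cm.sample_ids)
        except EcnormError as exc:
            add("sample-mismatch", str(exc))
    if cfg.zero_policy not in ("exclude", "pseudocount"):
        add("bad-config", f"unknown zero policy {cfg.zero_policy!r}")
    return problems


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis and write the output bundle.

    Outputs: size_factors.csv, normalized_counts.csv, de_table.csv,
    deg_list.csv, ec_list.csv, insilico_ratios.csv, insilico_summary.csv,
    plots (when enabled and applicable) and run_manifest.json.  Raises on
    the first failing stage; all outputs written so far are retained.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    notes: list[str] = []

    logger.info("reading inputs")
    cm = read_count_matrix(cfg.counts, strict=cfg.strict_counts)
    meta = read_metadata(cfg.metadata, group_col=cfg.group_col,
                         reference=cfg.reference).aligned_to(cm.sample_ids)

    logger.info("estimating size factors (median-of-ratios)")
    sf = estimate_size_factors(cm, pseudo_reference=cfg.pseudo_reference)
    sf_table = pd.DataFrame({"sample_id": list(sf.sample_ids),
                             "size_factor": sf.factors})
    outputs["size_factors"] = outdir / "size_factors.csv"
    write_results_csv(sf_table, outputs["size_factors"])

    nm = normalize_counts(cm, sf)
    norm_table = pd.DataFrame(nm.values, index=list(nm.gene_ids),
                              columns=list(nm.sample_ids))
    norm_table.index.name = "gene_id"
    outputs["normalized_counts"] = outdir / "normalized_counts.csv"
    norm_table.to_csv(outputs["normalized_counts"])

    logger.info("negative-binomial differential expression")
    disp = estimate_dispersions(cm, sf, meta, shrink=cfg.shrink)
    res = nb_wald_test(cm, sf, disp, meta)
    de_table = res.copy()
    de_table["alpha"] = disp.alpha
    de_table["alpha_raw"] = disp.alpha_raw
    de_table["alpha_trend"] = disp.alpha_trend
    outputs["de_table"] = outdir / "de_table.csv"
    write_results_csv(de_table, outputs["de_table"])

    logger.info("selecting biomarkers and endogenous controls")
    degs = select_degs(res, cfg.thresholds)
    outputs["deg_list"] = outdir / "deg_list.csv"
    write_results_csv(degs, outputs["deg_list"])

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ecs = select_ecs(res, disp, cfg.thresholds)
    for w in caught:
        logger.warning(str(w.message))
        notes.append(str(w.message))
    report = stability_report(ecs)
    outputs["ec_list"] = outdir / "ec_list.csv"
    write_results_csv(report, outputs["ec_list"])

    top_bm = list(degs["gene_id"].head(cfg.top_n_biomarkers))
    top_ec = list(ecs["gene_id"].head(cfg.top_n_ecs))
    if top_bm and top_ec:
        logger.info("in-silico qPCR/ddPCR normalization (%d biomarkers x %d ECs)",
                    len(top_bm), len(top_ec))
        summary = compare_ecs(cm, meta, top_bm, top_ec, de=res,
                              zero_policy=cfg.zero_policy)
        outputs["insilico_summary"] = outdir / "insilico_summary.csv"
        with open(outputs["insilico_summary"], "w", encoding="utf-8") as fh:
            fh.write(f"# {RECAPITULATION_RULE}\n")
            summary.to_csv(fh, index=False)
        long_rows = []
        for bm in top_bm:
            for ec in top_ec:
                rc = evaluate_ratio(
                    normalization_ratio(cm, bm, ec, zero_policy=cfg.zero_policy),
                    meta)
                for smp, grp, ratio in zip(rc.sample_ids, rc.groups, rc.ratios):
                    long_rows.append({"biomarker": bm, "ec": ec, "sample": smp,
                                      "group": grp, "ratio": ratio})
        outputs["insilico_ratios"] = outdir / "insilico_ratios.csv"
        write_results_csv(pd.DataFrame(long_rows), outputs["insilico_ratios"])
    else:
        msg = "in-silico step skipped: empty biomarker or EC list"
        logger.warning(msg)
        notes.append(msg)

    if cfg.make_plots:
        logger.info("rendering plots")
        outputs["volcano"] = outdir / "volcano.png"
        plot_volcano(res, outputs["volcano"], p_threshold=cfg.thresholds.deg_p_max,
                     lfc_threshold=cfg.thresholds.deg_lfc_min)
        heat_genes = list(degs["gene_id"].head(cfg.heatmap_top_n))
        if len(heat_genes) >= 2:
            outputs["heatmap"] = outdir / "heatmap.png"
            plot_heatmap(nm, meta, heat_genes, outputs["heatmap"])
        if top_bm and top_ec:
            rc = evaluate_ratio(
                normalization_ratio(cm, top_bm[0], top_ec[0],
                                    zero_policy=cfg.zero_policy), meta)
            outputs["ratio_boxplot"] = outdir / "ratio_boxplot.png"
            plot_ratio_boxplot(rc, outputs["ratio_boxplot"])

    manifest = {
        "package": "ecnorm",
        "version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "outputs": sorted(str(p.name) for p in outputs.values()),
        "notes": notes,
        "recapitulation_rule": RECAPITULATION_RULE,
    }
    outputs["manifest"] = outdir / "run_manifest.json"
    with open(outputs["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("done: %d output files in %s", len(outputs), outdir)
    return outputs
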