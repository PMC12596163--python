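"""Biomarker (DEG) thresholds and endogenous-control stability filtering.

Two candidate lists are derived from the differential-expression table:

* **DEGs** — genes with Wald p <= ``deg_p_max`` (default 0.05) and
  |log2FC| >= ``deg_lfc_min``, ranked by significance then effect size;
* **endogenous controls (ECs)** — genes whose expression is stable across
  the two groups: |log2FC| < ``ec_lfc_max`` (default 0.02), Wald
  p >= ``ec_p_min`` (default 0.8, recommended floor 0.6), ranked by NB
  dispersion ascending (lowest dispersion = most stable, rank 1).

Both selections additionally require a mean normalized count of at least
``min_mean_norm`` (default 100): an endogenous control with near-zero
counts is unusable as a PCR reference, and low-count biomarkers are poor
assay candidates.  Filters use raw Wald p-values (the adjusted FDR column
is carried along for reporting).  NA p-values are never selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diffexp import DispersionEstimates
from .errors import ValidationError

__all__ = [
    "SelectionThresholds",
    "select_degs",
    "select_ecs",
    "stability_report",
]


@dataclass(frozen=True)
class SelectionThresholds:
    """Cut-offs for DEG and endogenous-control selection.

    deg_p_max : maximal raw p-value for a DEG (default 0.05)
    deg_lfc_min : minimal |log2FC| for a DEG (default 0, i.e. off)
    ec_p_min : minimal raw p-value for an EC (default 0.8; values down to
        0.6 are a reasonable relaxation for small cohorts)
    ec_lfc_max : strict upper bound on |log2FC| for an EC (default 0.02)
    min_mean_norm : expression floor in mean normalized counts (default 100)
    """

    deg_p_max: float = 0.05
    deg_lfc_min: float = 0.0
    ec_p_min: float = 0.8
    ec_lfc_max: float = 0.02
    min_mean_norm: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 < self.deg_p_max <= 1.0):
            raise ValidationError("deg_p_max must lie in (0, 1]")
        if self.deg_lfc_min < 0:
            raise ValidationError("deg_lfc_min must be >= 0")
        if not (0.0 <= self.ec_p_min < 1.0):
            raise ValidationError("ec_p_min must lie in [0, 1)")
        if self.ec_lfc_max <= 0:
            raise ValidationError("ec_lfc_max must be > 0")
        if self.min_mean_norm < 0:
            raise ValidationError("min_mean_norm must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionThresholds":
        known = {k: float(v) for k, v in d.items() if v is not None}
        bad = set(known) - {f.name for f in
                            cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        if bad:
            raise ValidationError(f"unknown threshold name(s): {sorted(bad)}")
        return cls(**known)


def _require_columns(res: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in res.columns]
    if missing:
        raise ValidationError(f"result table is missing columns: {missing}")


def select_degs(res: pd.DataFrame,
                th: SelectionThresholds = SelectionThresholds()) -> pd.DataFrame:
    """Differentially expressed biomarkers at the given thresholds.

    Keeps genes with pvalue <= deg_p_max, |log2fc| >= deg_lfc_min and
    base_mean >= min_mean_norm; sorted by p-value ascending, ties by
    |log2fc| descending, then gene id.
    """
    _require_columns(res, ("gene_id", "base_mean", "log2fc", "pvalue"))
    p = res["pvalue"].to_numpy(dtype=float)
    lfc = res["log2fc"].to_numpy(dtype=float)
    bm = res["base_mean"].to_numpy(dtype=float)
    keep = (~np.isnan(p)) & (~np.isnan(lfc)) & (p <= th.deg_p_max) \
        & (np.abs(lfc) >= th.deg_lfc_min) & (bm >= th.min_mean_norm)
    out = res.loc[keep].copy()
    out["abs_log2fc"] = out["log2fc"].abs()
    out = out.sort_values(
        by=["pvalue", "abs_log2fc", "gene_id"],
        ascending=[True, False, True], kind="mergesort",
    ).drop(columns="abs_log2fc").reset_index(drop=True)
    return out


def select_ecs(res: pd.DataFrame, disp: DispersionEstimates,
               th: SelectionThresholds = SelectionThresholds()) -> pd.DataFrame:
    """Endogenous-control candidates passing the stability filter.

    Keeps genes with |log2fc| < ec_lfc_max (strict), pvalue >= ec_p_min and
    base_mean >= min_mean_norm, ranked by dispersion ascending
    (``stability_rank`` 1 = most stable; ties by |log2fc| ascending, then
    gene id).  Dispersion is used for ranking only, not as a hard filter.
    """
    _require_columns(res, ("gene_id", "base_mean", "log2fc", "pvalue"))
    if tuple(disp.gene_ids) != tuple(res["gene_id"]):
        raise ValidationError("dispersion estimates are not aligned with the "
                              "result table gene ids")
    p = res["pvalue"].to_numpy(dtype=float)
    lfc = res["log2fc"].to_numpy(dtype=float)
    bm = res["base_mean"].to_numpy(dtype=float)
    keep = (~np.isnan(p)) & (~np.isnan(lfc)) & (np.abs(lfc) < th.ec_lfc_max) \
        & (p >= th.ec_p_min) & (bm >= th.min_mean_norm)
    out = res.loc[keep, ["gene_id", "base_mean", "log2fc", "pvalue", "fdr"
                         ] if "fdr" in res.columns else
                  ["gene_id", "base_mean", "log2fc", "pvalue"]].copy()
    out["alpha"] = np.asarray(disp.alpha)[keep]
    out["abs_log2fc"] = out["log2fc"].abs()
    out = out.sort_values(
        by=["alpha", "abs_log2fc", "gene_id"],
        ascending=[True, True, True], kind="mergesort",
    ).drop(columns="abs_log2fc").reset_index(drop=True)
    out["stability_rank"] = np.arange(1, len(out) + 1)
    if out.empty:
        warnings.warn(
            "no endogenous-control candidate passed the stability filter; "
            "consider relaxing the thresholds (e.g. ec_p_min down to 0.6, "
            "ec_lfc_max up to 0.1)", UserWarning, stacklevel=2,
        )
    return out


def stability_report(ecs: pd.DataFrame) -> pd.DataFrame:
    """Candidate table ordered by stability rank, ready for CSV export."""
    if ecs.empty:
        cols = list(ecs.columns) or ["gene_id", "base_mean", "log2fc",
                                     "pvalue", "alpha", "stability_rank"]
        return pd.DataFrame(columns=cols)
    if "stability_rank" not in ecs.columns:
        raise ValidationError("expected a stability_rank column")
    return ecs.sort_values("stability_rank", kind="mergesort").reset_index(drop=True)
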