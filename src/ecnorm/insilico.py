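"""In-silico qPCR/ddPCR normalization: biomarker/EC count ratios.

Digital PCR readouts are ratios of absolute target counts to an endogenous
control (EC); qPCR delta-Ct readouts are the same quantity on an inverted
log scale.  This module emulates that readout from sequencing counts:
ratio_j = counts[biomarker, j] / counts[ec, j] per sample, compared between
groups with a two-sided Wilcoxon rank-sum (Mann-Whitney) test and annotated
with the usual significance stars (* p<=.05, ** p<=.01, *** p<=.001).

Ratios use raw counts: per-sample size factors cancel in the ratio, so the
readout is normalization-free, exactly as in a ddPCR well.  Samples where
the EC count is zero are dropped (and logged) under the default
``exclude`` policy — mirroring ddPCR practice, where an undetected
reference invalidates the well — or both counts get +0.5 under
``pseudocount``.

A biomarker x EC comparison is said to *recapitulate* the sequencing
result when the ratio test is significant (p <= 0.05) AND the direction of
the ratio difference matches the biomarker's differential-expression
direction (sign of its log2FC).  An EC that is itself differentially
expressed in the same direction cancels the biomarker's signal and fails
this check — the classic failure mode of "universal" controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import CountMatrix, SampleMetadata

__all__ = [
    "RatioComparison",
    "normalization_ratio",
    "evaluate_ratio",
    "wilcoxon_rank_sum",
    "significance_stars",
    "compare_ecs",
    "flip_direction",
    "RECAPITULATION_RULE",
]

RECAPITULATION_RULE = (
    "recapitulated = (wilcoxon_p <= 0.05) and "
    "sign(median ratio difference) == sign(biomarker log2fc)"
)


@dataclass(frozen=True)
class RatioComparison:
    """Per-sample biomarker/EC count ratios with optional test results.

    ``direction`` is the sign of (median ratio in the non-reference group
    minus median ratio in the reference group); it can be flipped with
    :func:`flip_direction` to match the delta-Ct convention, in which lower
    values mean higher expression.
    """

    biomarker_id: str
    ec_id: str
    sample_ids: tuple[str, ...]
    ratios: np.ndarray
    excluded_samples: tuple[str, ...] = ()
    zero_policy: str = "exclude"
    groups: tuple[str, ...] | None = None
    wilcoxon_p: float | None = None
    stars: str | None = None
    direction: int | None = None


def normalization_ratio(cm: CountMatrix, biomarker: str, ec: str,
                        zero_policy: str = "exclude") -> RatioComparison:
    """Per-sample biomarker/EC count ratios (tests left empty).

    ``zero_policy="exclude"`` drops samples with EC count 0 and records
    them; ``"pseudocount"`` adds 0.5 to both counts instead.
    """
    if biomarker == ec:
        raise ValidationError("biomarker and endogenous control must differ")
    if zero_policy not in ("exclude", "pseudocount"):
        raise ValidationError(f"unknown zero policy {zero_policy!r}")
    b = cm.counts[cm.gene_index(biomarker)].astype(float)
    e = cm.counts[cm.gene_index(ec)].astype(float)
    if not (e > 0).any():
        raise ValidationError(
            f"endogenous control {ec!r} has zero counts in every sample"
        )
    if zero_policy == "exclude":
        keep = e > 0
        ratios = b[keep] / e[keep]
        kept_ids = tuple(s for s, k in zip(cm.sample_ids, keep) if k)
        excluded = tuple(s for s, k in zip(cm.sample_ids, keep) if not k)
    else:
        ratios = (b + 0.5) / (e + 0.5)
        kept_ids = cm.sample_ids
        excluded = ()
    return RatioComparison(
        biomarker_id=biomarker, ec_id=ec, sample_ids=kept_ids,
        ratios=ratios, excluded_samples=excluded, zero_policy=zero_policy,
    )


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``mode="exact"`` enumerates the exact null distribution (refused with
    ties: falls back to the approximation with a warning); ``"normal"``
    uses the normal approximation with mid-ranks, tie-corrected variance
    and continuity correction; ``"auto"`` picks exact when
    len(a)+len(b) <= 20 and there are no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must contain at least one value")
    if mode not in ("exact", "normal", "auto"):
        raise ValidationError(f"unknown Wilcoxon mode {mode!r}")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if mode == "auto":
        mode = "exact" if (combined.size <= 20 and not has_ties) else "normal"
    if mode == "exact" and has_ties:
        warnings.warn("ties present: exact Wilcoxon unavailable, using the "
                      "normal approximation", UserWarning, stacklevel=2)
        mode = "normal"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def significance_stars(p: float) -> str:
    """Star label for a p-value: *** <= .001, ** <= .01, * <= .05, else ns."""
    p = float(p)
    if not (0.0 <= p <= 1.0) or np.isnan(p):
        raise ValidationError(f"p-value outside [0, 1]: {p!r}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def evaluate_ratio(rc: RatioComparison, meta: SampleMetadata,
                   mode: str = "auto") -> RatioComparison:
    """Attach group labels, Wilcoxon p, stars and direction to ratios."""
    lookup = dict(zip(meta.sample_ids, meta.group))
    missing = [s for s in rc.sample_ids if s not in lookup]
    if missing:
        raise ValidationError(f"samples absent from metadata: {missing}")
    groups = tuple(lookup[s] for s in rc.sample_ids)
    ref, other = meta.levels
    in_ref = np.asarray([g == ref for g in groups])
    a = rc.ratios[in_ref]
    b = rc.ratios[~in_ref]
    if a.size == 0 or b.size == 0:
        raise ValidationError(
            f"group emptied by zero-count exclusion for EC {rc.ec_id!r}; "
            "consider zero_policy='pseudocount'"
        )
    p = wilcoxon_rank_sum(a, b, mode=mode)
    direction = int(np.sign(np.median(b) - np.median(a)))
    return replace(rc, groups=groups, wilcoxon_p=p,
                   stars=significance_stars(p), direction=direction)


def flip_direction(rc: RatioComparison) -> RatioComparison:
    """Negate the effect direction (delta-Ct convention helper)."""
    d = None if rc.direction is None else -rc.direction
    return replace(rc, direction=d)


def compare_ecs(cm: CountMatrix, meta: SampleMetadata, biomarkers, ecs,
                de: pd.DataFrame | None = None, zero_policy: str = "exclude",
                mode: str = "auto") -> pd.DataFrame:
    """Full biomarker x EC grid of ratio comparisons.

    When a differential-expression table ``de`` (with ``gene_id`` and
    ``log2fc`` columns) is supplied, a ``recapitulated`` column marks the
    pairs whose ratio test is significant (p <= 0.05) with a direction
    matching the biomarker's DE direction — see ``RECAPITULATION_RULE``.
    """
    meta = meta.aligned_to(cm.sample_ids)
    lfc_of: dict[str, float] = {}
    if de is not None:
        lfc_of = dict(zip(de["gene_id"], de["log2fc"].astype(float)))
    rows = []
    for bm in biomarkers:
        for ec in ecs:
            rc = normalization_ratio(cm, bm, ec, zero_policy=zero_policy)
            rc = evaluate_ratio(rc, meta, mode=mode)
            de_lfc = lfc_of.get(bm, np.nan)
            if de is not None and np.isfinite(de_lfc):
                recap = bool(rc.wilcoxon_p <= 0.05
                             and rc.direction == np.sign(de_lfc)
                             and rc.direction != 0)
            else:
                recap = np.nan
            rows.append({
                "biomarker": bm,
                "ec": ec,
                "n_used": len(rc.sample_ids),
                "n_excluded": len(rc.excluded_samples),
                "wilcoxon_p": rc.wilcoxon_p,
                "stars": rc.stars,
                "direction": rc.direction,
                "de_log2fc": de_lfc,
                "recapitulated": recap,
            })
    return pd.DataFrame(rows)
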