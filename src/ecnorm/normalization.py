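"""Median-of-ratios size factors and count normalization.

The median-of-ratios scheme corrects for library size and compositional
bias: a pseudo-reference expression level is built for each gene as the
geometric mean of its counts across samples, and each sample's size factor
is the median over reference genes of the ratio count / pseudo-reference.
Only genes with strictly positive counts in every sample enter the
reference set (the geometric mean of any row containing a zero is zero).
Factors are rescaled to geometric mean 1 so normalized counts stay on the
raw-count scale, which the downstream expression floor (mean normalized
count >= 100) presumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, ValidationError
from .io import CountMatrix

__all__ = [
    "SizeFactors",
    "NormalizedMatrix",
    "estimate_size_factors",
    "normalize_counts",
    "mean_normalized_count",
]


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample positive scaling constants, geometric mean 1."""

    sample_ids: tuple[str, ...]
    factors: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        f = np.asarray(self.factors, dtype=float)
        object.__setattr__(self, "factors", f)
        if len(self.sample_ids) != f.shape[0]:
            raise ValidationError("size factor count does not match sample ids")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValidationError("size factors must be positive and finite")


@dataclass(frozen=True)
class NormalizedMatrix:
    """Size-factor-scaled counts (counts[i, j] / factor[j])."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None


def estimate_size_factors(cm: CountMatrix,
                          pseudo_reference: bool = False) -> SizeFactors:
    """Median-of-ratios size factors.

    For sample j, factor_j = median over reference genes i of
    counts[i, j] / geomean_i, where geomean_i is gene i's geometric mean
    across samples and the reference set is the genes with all-positive
    counts.  The even-count median is the arithmetic midpoint of the two
    central ratios.  Factors are rescaled to geometric mean 1.

    Parameters
    ----------
    pseudo_reference
        When True, a pseudocount of 1 is added to every cell for the
        purpose of this estimation (reference construction), allowing
        matrices in which every gene has at least one zero.  Normalized
        counts themselves are never pseudocounted.
    """
    counts = cm.counts.astype(float)
    if pseudo_reference:
        ref = counts + 1.0
    else:
        mask = (counts > 0).all(axis=1)
        if not mask.any():
            raise EstimationError(
                "median-of-ratios reference set is empty: every gene has at "
                "least one zero count. Filter low-count genes or use the "
                "pseudo-reference fallback (adds 1 to all counts for "
                "reference construction only)."
            )
        ref = counts[mask]
    log_gm = np.log(ref).mean(axis=1)
    ratios = ref / np.exp(log_gm)[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return SizeFactors(sample_ids=cm.sample_ids, factors=factors)


def normalize_counts(cm: CountMatrix, sf: SizeFactors) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor (gene order kept)."""
    if tuple(sf.sample_ids) != tuple(cm.sample_ids):
        raise ValidationError(
            "size factor samples do not match count-matrix samples: "
            f"{list(sf.sample_ids)} vs {list(cm.sample_ids)}"
        )
    values = cm.counts.astype(float) / sf.factors[None, :]
    return NormalizedMatrix(gene_ids=cm.gene_ids, sample_ids=cm.sample_ids,
                            values=values)


def mean_normalized_count(nm: NormalizedMatrix, gene: str) -> float:
    """Arithmetic mean of a gene's normalized counts over all samples."""
    i = nm.gene_index(gene)
    return float(nm.values[i].mean())
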