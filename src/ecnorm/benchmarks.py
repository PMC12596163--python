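"""Self-validation scenarios on synthetic data with known truth.

Each function simulates a dataset whose generating parameters are known,
runs the relevant pipeline stage, and returns the measured quantity
(recovery error, empirical error rate, power, ...).  They are used both by
the test suite and by ``scripts/acceptance.py``; every scenario takes an
explicit seed so results are reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import estimate_dispersions, nb_wald_test
from .insilico import wilcoxon_rank_sum
from .io import CountMatrix, SampleMetadata
from .normalization import estimate_size_factors
from .selection import SelectionThresholds, select_ecs
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "size_factor_recovery_cv",
    "size_factor_oracle_error",
    "null_calibration",
    "log2fc_recovery",
    "planted_ec_recovery",
    "wilcoxon_exact_error",
    "ratio_detection_power",
    "brute_force_size_factors",
    "brute_force_wilcoxon_p",
]


# --- independent oracles -------------------------------------------------

def brute_force_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios by direct per-sample loops (reference oracle).

    Reference genes are rows with all-positive counts; each sample's
    factor is the plain median of count/geometric-mean ratios over those
    genes, rescaled to geometric mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    ref_rows = [i for i in range(counts.shape[0]) if (counts[i] > 0).all()]
    if not ref_rows:
        raise ValueError("empty reference set")
    factors = []
    for j in range(counts.shape[1]):
        ratios = []
        for i in ref_rows:
            gm = float(np.exp(np.mean(np.log(counts[i]))))
            ratios.append(counts[i, j] / gm)
        factors.append(float(np.median(ratios)))
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def brute_force_wilcoxon_p(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    For tie-free data, counts the fraction of C(n, |a|) assignments whose
    rank sum is at least as extreme (two-sided, by min tail doubled and
    capped at 1) as the observed one.
    """
    a = list(a)
    b = list(b)
    combined = sorted(a + b)
    rank = {v: i + 1 for i, v in enumerate(combined)}
    obs = sum(rank[v] for v in a)
    n, na = len(combined), len(a)
    sums = [sum(c) for c in itertools.combinations(range(1, n + 1), na)]
    total = len(sums)
    ge = sum(s >= obs for s in sums)
    le = sum(s <= obs for s in sums)
    return min(1.0, 2.0 * min(ge, le) / total)


# --- scenarios -----------------------------------------------------------

def size_factor_recovery_cv(seed: int, n_genes: int = 2000,
                            n_per_group: tuple[int, int] = (20, 20)) -> float:
    """CV (%) of estimated/true size-factor ratios on a no-DE matrix."""
    cfg = SimulationConfig(n_genes=n_genes, n_per_group=n_per_group,
                           frac_de=0.0, n_stable=0, dispersion=0.1,
                           size_factor_range=(0.5, 2.0), seed=seed)
    cm, _meta, truth = simulate_dataset(cfg)
    sf = estimate_size_factors(cm)
    ratio = sf.factors / truth.samples["true_size_factor"].to_numpy()
    return float(100.0 * ratio.std(ddof=1) / ratio.mean())


def size_factor_oracle_error(seed: int, n_matrices: int = 100) -> float:
    """Max |estimated - brute-force| factor over random all-positive matrices."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        g = int(rng.integers(10, 40))
        n = int(rng.integers(3, 9))
        counts = rng.integers(1, 2000, size=(g, n)).astype(np.int64)
        cm = CountMatrix(
            gene_ids=tuple(f"g{i}" for i in range(g)),
            sample_ids=tuple(f"s{j}" for j in range(n)),
            counts=counts,
        )
        est = estimate_size_factors(cm).factors
        oracle = brute_force_size_factors(counts)
        worst = max(worst, float(np.max(np.abs(est - oracle))))
    return worst


def _run_de(cfg: SimulationConfig, shrink: bool = True):
    cm, meta, truth = simulate_dataset(cfg)
    sf = estimate_size_factors(cm)
    disp = estimate_dispersions(cm, sf, meta, shrink=shrink)
    res = nb_wald_test(cm, sf, disp, meta)
    return cm, meta, truth, disp, res


def null_calibration(seed: int, n_genes: int = 2000,
                     n_per_group: tuple[int, int] = (20, 20)
                     ) -> tuple[float, float]:
    """(rejection rate at p<=0.05, KS distance from U(0,1)) under the null."""
    cfg = SimulationConfig(n_genes=n_genes, n_per_group=n_per_group,
                           frac_de=0.0, n_stable=0, dispersion=0.1,
                           mean_range=(50.0, 5000.0), seed=seed)
    _cm, _meta, _truth, _disp, res = _run_de(cfg)
    p = res["pvalue"].dropna().to_numpy()
    rate = float((p <= 0.05).mean())
    ks = float(stats.kstest(p, "uniform").statistic)
    return rate, ks


def log2fc_recovery(seed: int, n_genes: int = 200, lfc: float = 1.0,
                    mu: float = 200.0, alpha: float = 0.05,
                    n_per_group: tuple[int, int] = (50, 50)) -> float:
    """Mean estimated log2FC over ``n_genes`` genes planted at +``lfc``.

    The planted genes sit among an equal number of down-regulated genes and
    a majority of nulls (the generator's symmetric-DE default), so
    median-of-ratios size factors are not confounded by composition.
    """
    total = 10 * n_genes
    cfg = SimulationConfig(n_genes=total, n_per_group=n_per_group,
                           frac_de=2 * n_genes / total, lfc=lfc,
                           lfc_signs="both", n_stable=0,
                           dispersion=alpha, mean_range=(mu, mu),
                           size_factor_range=(0.5, 2.0), seed=seed)
    _cm, _meta, truth, _disp, res = _run_de(cfg)
    up = truth.genes["true_lfc"].to_numpy() == lfc
    assert int(up.sum()) == n_genes
    return float(res.loc[up, "log2fc"].mean())


def planted_ec_recovery(seed: int, top_n: int = 20,
                        th: SelectionThresholds = SelectionThresholds()
                        ) -> tuple[int, int]:
    """(planted stable genes among the top-n ranked ECs, candidates found)."""
    cfg = SimulationConfig(seed=seed)  # default 2000x40 test bed, 50 stable
    _cm, _meta, truth, disp, res = _run_de(cfg)
    ecs = select_ecs(res, disp, th)
    stable = set(truth.genes.loc[truth.genes["is_stable"], "gene_id"])
    top = list(ecs["gene_id"].head(top_n))
    return sum(g in stable for g in top), len(ecs)


def wilcoxon_exact_error(max_n: int = 8) -> float:
    """Max |exact-mode p - enumeration p| over all tie-free partitions.

    Uses the value sets {1..n} for every total size n <= max_n and every
    split with both groups non-empty.
    """
    worst = 0.0
    for n in range(2, max_n + 1):
        values = list(range(1, n + 1))
        for na in range(1, n):
            for a in itertools.combinations(values, na):
                b = [v for v in values if v not in a]
                p_impl = wilcoxon_rank_sum(np.array(a, float),
                                           np.array(b, float), mode="exact")
                p_oracle = brute_force_wilcoxon_p(a, b)
                worst = max(worst, abs(p_impl - p_oracle))
    return worst


def ratio_detection_power(seed: int, confounded: bool, n_reps: int = 200,
                          n_per_group: tuple[int, int] = (20, 20),
                          lfc: float = 2.0) -> float:
    """Fraction of replicates where the biomarker/EC ratio test fires.

    Each replicate draws a biomarker (planted log2FC = ``lfc``) and an EC:
    either a planted stable gene (alpha 0.01, lfc 0) or a confounded
    control with the same fold change as the biomarker.  Power is the
    fraction of Wilcoxon p <= 0.05 on per-sample count ratios.
    """
    rng = np.random.default_rng(seed)
    n_a, n_b = n_per_group
    n = n_a + n_b
    x = np.concatenate([np.zeros(n_a), np.ones(n_b)])
    hits = 0
    for _ in range(n_reps):
        s = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n))
        bm_mu = s * 200.0 * 2.0 ** (lfc * x)
        ec_lfc = lfc if confounded else 0.0
        ec_alpha = 0.1 if confounded else 0.01
        ec_mu = s * 500.0 * 2.0 ** (ec_lfc * x)
        bm = rng.negative_binomial(10.0, 10.0 / (10.0 + bm_mu))  # alpha 0.1
        r_ec = 1.0 / ec_alpha
        ec = rng.negative_binomial(r_ec, r_ec / (r_ec + ec_mu))
        keep = ec > 0
        ratios = bm[keep] / ec[keep]
        xa = ratios[x[keep] == 0]
        xb = ratios[x[keep] == 1]
        if xa.size == 0 or xb.size == 0:
            continue
        if wilcoxon_rank_sum(xa, xb, mode="normal") <= 0.05:
            hits += 1
    return hits / n_reps
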