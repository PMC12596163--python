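"""Synthetic NB count matrices with known truth.

The generator draws the data the pipeline's model assumes: counts are
negative binomial with Var = mu + alpha * mu^2 and mean
``s_j * q_i * 2^(x_j * lfc_i)`` where ``s_j`` is a per-sample size factor
(log-uniform, rescaled to geometric mean 1), ``q_i`` a baseline expression
level (log-uniform), ``x_j`` the group indicator and ``lfc_i`` the planted
log2 fold change.  Three gene classes can be planted:

* stable genes — candidate endogenous controls: lfc 0, low dispersion,
  fixed moderately-high mean (default 500, a realistic abundance for a
  housekeeping reference);
* DE genes — biomarkers with |lfc| = ``lfc``, split evenly between up- and
  down-regulation by default so size-factor estimation stays unbiased;
* an optional confounded EC — a gene planted with its own fold change that
  emulates a canonical control which is itself differentially expressed.

All randomness flows from a single integer seed through numpy's PCG64
generator, so matrices are bit-reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io import CountMatrix, SampleMetadata, write_count_matrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_dataset",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults give the standard 2000 x 40 test bed."""

    n_genes: int = 2000
    n_per_group: tuple[int, int] = (20, 20)
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    mean_range: tuple[float, float] = (50.0, 5000.0)
    dispersion: float | tuple[float, float] = 0.1  # alpha, or (a0, a1) for a0+a1/mu
    frac_de: float = 0.05
    lfc: float = 2.0
    lfc_signs: str = "both"  # "both" alternates +/-, "up" plants all positive
    n_stable: int = 50
    stable_alpha: float = 0.01
    stable_mean: float = 500.0
    confounded_ec: tuple[int, float] | None = None
    group_labels: tuple[str, str] = ("control", "disease")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValidationError("n_genes must be >= 2")
        if min(self.n_per_group) < 2:
            raise ValidationError("each group needs at least 2 samples")
        if not (0.0 <= self.frac_de < 1.0):
            raise ValidationError("frac_de must lie in [0, 1)")
        if self.n_stable < 0 or self.n_stable + self.n_de > self.n_genes:
            raise ValidationError("n_stable + number of DE genes exceeds n_genes")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValidationError("size_factor_range must be positive and ordered")
        lo, hi = self.mean_range
        if not (0 < lo <= hi):
            raise ValidationError("mean_range must be positive and ordered")
        if self.lfc_signs not in ("both", "up"):
            raise ValidationError("lfc_signs must be 'both' or 'up'")
        if self.confounded_ec is not None:
            idx, _ = self.confounded_ec
            if not (0 <= int(idx) < self.n_genes):
                raise ValidationError("confounded_ec index out of range")
        if len(set(self.group_labels)) != 2:
            raise ValidationError("group_labels must be two distinct labels")

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de * self.n_genes))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_per_group"] = list(self.n_per_group)
        d["size_factor_range"] = list(self.size_factor_range)
        d["mean_range"] = list(self.mean_range)
        d["group_labels"] = list(self.group_labels)
        if isinstance(self.dispersion, tuple):
            d["dispersion"] = list(self.dispersion)
        if self.confounded_ec is not None:
            d["confounded_ec"] = list(self.confounded_ec)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("n_per_group", "size_factor_range", "mean_range",
                    "group_labels", "confounded_ec"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if isinstance(d.get("dispersion"), list):
            d["dispersion"] = tuple(d["dispersion"])
        return cls(**d)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth: per-gene parameters and per-sample factors/groups."""

    genes: pd.DataFrame    # gene_id, true_mean, true_lfc, true_alpha, is_de, is_stable, is_confounded
    samples: pd.DataFrame  # sample_id, group, true_size_factor


def _gene_alphas(cfg: SimulationConfig, q: np.ndarray) -> np.ndarray:
    if isinstance(cfg.dispersion, tuple):
        a0, a1 = cfg.dispersion
        return np.maximum(a0 + a1 / q, 0.0)
    return np.full(cfg.n_genes, float(cfg.dispersion))


def simulate_dataset(cfg: SimulationConfig
                     ) -> tuple[CountMatrix, SampleMetadata, SimulationTruth]:
    """Draw one dataset; deterministic for a given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n_a, n_b = cfg.n_per_group
    n = n_a + n_b
    g = cfg.n_genes

    lo, hi = cfg.size_factor_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    s = s / np.exp(np.mean(np.log(s)))

    lo, hi = cfg.mean_range
    q = np.exp(rng.uniform(np.log(lo), np.log(hi), size=g))
    alpha = _gene_alphas(cfg, q)
    lfc = np.zeros(g)
    is_stable = np.zeros(g, dtype=bool)
    is_de = np.zeros(g, dtype=bool)
    is_conf = np.zeros(g, dtype=bool)

    ns = cfg.n_stable
    is_stable[:ns] = True
    q[:ns] = cfg.stable_mean
    alpha[:ns] = cfg.stable_alpha

    nd = cfg.n_de
    de_idx = np.arange(ns, ns + nd)
    is_de[de_idx] = True
    if cfg.lfc_signs == "both":
        signs = np.where(np.arange(nd) % 2 == 0, 1.0, -1.0)
    else:
        signs = np.ones(nd)
    lfc[de_idx] = signs * cfg.lfc

    if cfg.confounded_ec is not None:
        idx, conf_lfc = cfg.confounded_ec
        idx = int(idx)
        lfc[idx] = float(conf_lfc)
        is_conf[idx] = True
        is_de[idx] = lfc[idx] != 0
        is_stable[idx] = False

    x = np.concatenate([np.zeros(n_a), np.ones(n_b)])
    mean = s[None, :] * q[:, None] * np.power(2.0, lfc[:, None] * x[None, :])

    counts = np.empty((g, n), dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        counts[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / alpha[~pois]
        m = mean[~pois]
        p = r[:, None] / (r[:, None] + m)
        counts[~pois] = rng.negative_binomial(r[:, None], p)

    width = max(4, len(str(g)))
    gene_ids = tuple(f"gene_{i + 1:0{width}d}" for i in range(g))
    lab_a, lab_b = cfg.group_labels
    sample_ids = tuple([f"{lab_a}_{j + 1:02d}" for j in range(n_a)]
                       + [f"{lab_b}_{j + 1:02d}" for j in range(n_b)])
    groups = tuple([lab_a] * n_a + [lab_b] * n_b)

    cm = CountMatrix(gene_ids=gene_ids, sample_ids=sample_ids, counts=counts)
    meta = SampleMetadata(sample_ids=sample_ids, group=groups,
                          reference=min(cfg.group_labels))
    truth = SimulationTruth(
        genes=pd.DataFrame({
            "gene_id": list(gene_ids),
            "true_mean": q,
            "true_lfc": lfc,
            "true_alpha": alpha,
            "is_de": is_de,
            "is_stable": is_stable,
            "is_confounded": is_conf,
        }),
        samples=pd.DataFrame({
            "sample_id": list(sample_ids),
            "group": list(groups),
            "true_size_factor": s,
        }),
    )
    return cm, meta, truth


def write_fixture_bundle(cfg: SimulationConfig, directory) -> dict[str, Path]:
    """Write counts/metadata/truth CSVs plus the config as YAML.

    The files form a self-describing fixture in the exact formats the
    readers in :mod:`ecnorm.io` expect.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cm, meta, truth = simulate_dataset(cfg)
    paths = {
        "counts": directory / "counts.csv",
        "metadata": directory / "metadata.csv",
        "truth_genes": directory / "truth_genes.csv",
        "truth_samples": directory / "truth_samples.csv",
        "config": directory / "config.yaml",
    }
    write_count_matrix(cm, paths["counts"])
    md = pd.DataFrame({"sample_id": list(meta.sample_ids),
                       "group": list(meta.group)}).set_index("sample_id")
    md.to_csv(paths["metadata"])
    truth.genes.to_csv(paths["truth_genes"], index=False)
    truth.samples.to_csv(paths["truth_samples"], index=False)
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return paths
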