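"""Synthetic genotype/phenotype data in the small-n-large-p regime.

Emulates the structure of genomic-selection data sets: n individuals typed
at p biallelic SNPs coded 0/1/2 (count of the minor allele), with far more
markers than individuals, and an additive phenotype controlled by a genetic
architecture (a few strong QTLs, many weak QTLs, or pure noise) and a
heritability h2 — the fraction of phenotypic variance that is genetic.

Deliberately simple on purpose: SNPs are independent (no linkage
disequilibrium), effects are additive with equal magnitude and random sign,
and there is no population structure. Those simplifications do not touch the
mechanism under study — run-to-run randomness of forests — but they do mean
results here say nothing about confounding or LD in real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = ["SimSpec", "simulate_genotypes", "simulate_phenotype", "simulate_dataset",
           "make_fixture_suite"]

_ARCHITECTURES = ("few_strong", "many_weak", "null")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated genotype/phenotype data set.

    n_individuals, n_snps : data dimensions; n_snps >= n_individuals is the
        default regime.
    maf_range : minor-allele-frequency interval each SNP's frequency is
        drawn from uniformly.
    architecture : "few_strong" (default 5 QTLs, large equal effects),
        "many_weak" (default p/4 QTLs, small equal effects) or "null"
        (no genetic signal; requires h2 = 0).
    n_qtl : override the architecture's default QTL count.
    heritability : target var(genetic) / var(total) in [0, 1].
    task : "regression" returns the continuous phenotype; "classification"
        thresholds it at ``class_threshold`` (a quantile) into two classes.
    """

    n_individuals: int = 100
    n_snps: int = 500
    maf_range: Tuple[float, float] = (0.05, 0.5)
    architecture: str = "few_strong"
    n_qtl: Optional[int] = None
    heritability: float = 0.5
    task: str = "regression"
    class_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 20:
            raise InputError("need at least 20 individuals")
        if self.architecture not in _ARCHITECTURES:
            raise InputError(f"architecture must be one of {_ARCHITECTURES}")
        if not 0.0 <= self.heritability <= 1.0:
            raise InputError("heritability must be in [0, 1]")
        if self.architecture == "null" and self.heritability > 0:
            raise InputError("null architecture implies heritability 0")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise InputError("maf_range must satisfy 0 < low <= high <= 0.5")

    def default_n_qtl(self) -> int:
        if self.architecture == "null":
            return 0
        if self.n_qtl is not None:
            return self.n_qtl
        return 5 if self.architecture == "few_strong" else max(10, self.n_snps // 4)


def simulate_genotypes(spec: SimSpec) -> pd.DataFrame:
    """n x p table of 0/1/2 genotypes, SNP j ~ Binomial(2, f_j) i.i.d. per individual."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    lo, hi = spec.maf_range
    freqs = rng.uniform(lo, hi, size=spec.n_snps)
    geno = rng.binomial(2, freqs, size=(spec.n_individuals, spec.n_snps))
    return pd.DataFrame(
        geno,
        index=[f"ind{i:04d}" for i in range(spec.n_individuals)],
        columns=[f"snp{j:05d}" for j in range(spec.n_snps)],
    )


def simulate_phenotype(genotypes: pd.DataFrame, spec: SimSpec):
    """Additive phenotype y = sum_q beta_q g_q + eps and the true effect vector.

    QTL positions are drawn without replacement; effects have equal magnitude
    and random sign. The noise is scaled so the realised genetic-variance
    fraction equals the target heritability exactly in this sample
    (var(g) / var(y) = h2 up to Monte-Carlo noise in the residual draw).
    Classification thresholds y at the ``class_threshold`` quantile into
    labels "low" / "high".

    Returns (y, truth) where truth records QTL indices and effects.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    G = genotypes.to_numpy(dtype=float)
    n, p = G.shape
    n_qtl = spec.default_n_qtl()
    beta = np.zeros(p)
    if n_qtl > 0:
        qtl = np.sort(rng.choice(p, size=n_qtl, replace=False))
        beta[qtl] = rng.choice([-1.0, 1.0], size=n_qtl)
    else:
        qtl = np.array([], dtype=int)
    g = G @ beta
    var_g = float(np.var(g))
    h2 = spec.heritability
    if h2 == 0.0 or var_g == 0.0:
        g = np.zeros(n)
        eps = rng.normal(0.0, 1.0, size=n)
        y = eps
    elif h2 == 1.0:
        y = g
        eps = np.zeros(n)
    else:
        sigma_e = np.sqrt(var_g * (1.0 - h2) / h2)
        eps = rng.normal(0.0, sigma_e, size=n)
        y = g + eps
    truth = {
        "qtl_indices": qtl.tolist(),
        "qtl_names": [genotypes.columns[j] for j in qtl],
        "beta": beta[qtl].tolist(),
        "var_genetic": var_g,
        "heritability_target": h2,
        "spec": asdict(spec),
    }
    if spec.task == "classification":
        cut = np.quantile(y, spec.class_threshold)
        labels = np.where(y > cut, "high", "low")
        ys = pd.Series(labels, index=genotypes.index, name="phenotype")
    else:
        ys = pd.Series(y, index=genotypes.index, name="phenotype")
    return ys, truth


def simulate_dataset(spec: SimSpec):
    """Convenience: (genotype table, phenotype series, truth record)."""
    X = simulate_genotypes(spec)
    y, truth = simulate_phenotype(X, spec)
    return X, y, truth


_FIXTURES = {
    "regression_few_strong": SimSpec(
        n_individuals=100, n_snps=300, architecture="few_strong",
        heritability=0.6, task="regression", seed=11,
    ),
    "classification_few_strong": SimSpec(
        n_individuals=100, n_snps=300, architecture="few_strong",
        heritability=0.6, task="classification", seed=12,
    ),
    "regression_many_weak": SimSpec(
        n_individuals=100, n_snps=300, architecture="many_weak",
        heritability=0.6, task="regression", seed=13,
    ),
}


def make_fixture_suite(out_dir) -> dict:
    """Write the three standard fixtures (CSV + truth JSON); returns paths.

    Each fixture is a genotype CSV whose last column is the phenotype, plus
    a JSON file recording the simulation spec and true QTL effects so tests
    never have to re-derive them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, spec in _FIXTURES.items():
        X, y, truth = simulate_dataset(spec)
        table = X.copy()
        table["phenotype"] = y
        csv_path = out / f"{name}.csv"
        table.to_csv(csv_path, index_label="id")
        truth_path = out / f"{name}.truth.json"
        truth_path.write_text(json.dumps(truth, indent=1))
        written[name] = {"data": str(csv_path), "truth": str(truth_path)}
    return written
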