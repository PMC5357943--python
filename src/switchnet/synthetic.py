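"""Synthetic expression data with planted modular and switch structure.

A latent-factor model generates what the pipeline assumes real data look
like: one shared factor per co-expression module, member genes loading on
it positively, and planted switch genes loading *negatively* on the mean
of two (or more) foreign modules' factors — so at realistic noise levels a
switch gene correlates negatively with the members of its target modules,
acquires mostly-external links in the thresholded network (high K_pi, low
z_g) and a negative APCC.  The factor model keeps all population
correlations in closed form, which the test oracles exploit:

* two members of the same module: r = c / (c + sigma^2), c = intra_corr;
* a switch gene (targets T) and a member of a module in T at sigma = 0:
  r = -1 / sqrt(|T|), independent of loadings (both profiles are then
  noiseless linear images of the factors).

Expression values are shifted by a positive offset so matrices satisfy the
non-negativity contract without disturbing any correlation.  Survival
times follow an exponential proportional-hazards law tied to a chosen
driver gene, with independent exponential censoring.  Every generator
requires an explicit seed; there is no global random state.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix

__all__ = [
    "SyntheticTruth",
    "generate_modular_expression",
    "generate_paired_tumor_normal",
    "generate_survival",
]


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators, serializable next to the data."""

    modules: dict = field(default_factory=dict)        # gene -> module index
    switch_genes: list = field(default_factory=list)
    switch_targets: dict = field(default_factory=dict)  # switch -> target modules
    de_genes: list = field(default_factory=list)
    hazard_beta: dict = field(default_factory=dict)     # driver gene -> beta
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def generate_modular_expression(
    n_modules: int = 4,
    genes_per_module: int = 50,
    n_samples: int = 100,
    intra_corr: float = 0.8,
    n_switch: int = 10,
    switch_strength: float = 0.8,
    noise_sd: float = 0.3,
    n_target_modules: int = 2,
    offset: float = 10.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Modular expression with planted anti-correlated switch genes.

    Member gene of module m:  x = sqrt(intra_corr) * f_m + noise_sd * eps.
    Switch gene with target modules T (|T| = n_target_modules, all foreign):
    x = -switch_strength * mean(f_m, m in T) + noise_sd * eps.
    Factors f_m and noise are standard normal per sample; ``offset`` shifts
    everything positive.  Deterministic given ``seed``.
    """
    if min(n_modules, genes_per_module, n_samples) <= 0:
        raise ValueError("structural parameters must be positive")
    if not 0.0 < intra_corr <= 1.0:
        raise ValueError("intra_corr must lie in (0, 1]")
    if not 0.0 < switch_strength <= 1.0:
        raise ValueError("switch_strength must lie in (0, 1]")
    if not 2 <= n_target_modules <= n_modules:
        raise ValueError("n_target_modules must lie in [2, n_modules]")
    if n_switch > n_modules * genes_per_module:
        raise ValueError(
            f"n_switch={n_switch} exceeds capacity {n_modules * genes_per_module}"
        )
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_modules, n_samples))
    width = len(str(genes_per_module))
    rows, genes, modules = [], [], {}
    for m in range(n_modules):
        for j in range(genes_per_module):
            gene = f"M{m + 1}_G{j + 1:0{width}d}"
            rows.append(
                np.sqrt(intra_corr) * factors[m]
                + noise_sd * rng.standard_normal(n_samples)
            )
            genes.append(gene)
            modules[gene] = m + 1

    target_pool = list(itertools.combinations(range(n_modules), n_target_modules))
    target_order = rng.permutation(len(target_pool))
    switch_genes, switch_targets = [], {}
    for s in range(n_switch):
        gene = f"SW{s + 1:02d}"
        targets = target_pool[target_order[s % len(target_pool)]]
        rows.append(
            -switch_strength * factors[list(targets)].mean(axis=0)
            + noise_sd * rng.standard_normal(n_samples)
        )
        genes.append(gene)
        switch_genes.append(gene)
        switch_targets[gene] = [t + 1 for t in targets]

    values = pd.DataFrame(
        np.asarray(rows) + offset,
        index=pd.Index(genes, name="gene"),
        columns=[f"S{i + 1:03d}" for i in range(n_samples)],
    )
    if (values.to_numpy() < 0).any():  # astronomically unlikely at offset=10
        values = values.clip(lower=0.0)
    truth = SyntheticTruth(
        modules=modules,
        switch_genes=switch_genes,
        switch_targets=switch_targets,
        params={
            "n_modules": n_modules,
            "genes_per_module": genes_per_module,
            "n_samples": n_samples,
            "intra_corr": intra_corr,
            "n_switch": n_switch,
            "switch_strength": switch_strength,
            "noise_sd": noise_sd,
            "n_target_modules": n_target_modules,
            "offset": offset,
        },
        seed=seed,
    )
    return ExpressionMatrix(values), truth


def generate_paired_tumor_normal(
    base: ExpressionMatrix,
    de_genes,
    log2fc: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Paired tumor/normal matrix: normals are the base samples, tumors are
    copies with ``de_genes`` scaled by 2**log2fc (plus optional noise).

    Base samples are treated as patients; each contributes one normal and
    one matched tumor sample.
    """
    de_genes = list(de_genes)
    unknown = set(de_genes) - set(base.gene_ids)
    if unknown:
        raise ValueError(f"de_genes not in matrix: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    normal = base.values.copy()
    tumor = base.values.copy()
    tumor.loc[de_genes] *= 2.0**log2fc
    if noise_sd > 0:
        tumor = (tumor + rng.standard_normal(tumor.shape) * noise_sd).clip(lower=0.0)
    patients = list(base.sample_ids)
    values = pd.concat(
        [
            normal.set_axis([f"{p}_N" for p in patients], axis=1),
            tumor.set_axis([f"{p}_T" for p in patients], axis=1),
        ],
        axis=1,
    )
    samples = pd.DataFrame(
        {
            "patient_id": patients * 2,
            "condition": ["normal"] * len(patients) + ["tumor"] * len(patients),
        },
        index=pd.Index(list(values.columns), name="sample_id"),
    )
    return ExpressionMatrix(values, samples)


def generate_survival(
    em: ExpressionMatrix,
    driver_gene: str,
    beta: float = 1.0,
    baseline_rate: float = 1e-3,
    censor_rate: float = 5e-4,
    seed: int = 0,
) -> ClinicalTable:
    """Exponential proportional-hazards survival tied to a driver gene.

    Event time ~ Exp(rate = baseline_rate * exp(beta * z)) with z the
    standardized per-patient expression of the driver; censoring is an
    independent Exp(censor_rate) clock (``censor_rate=0`` disables it).
    Times are in days.
    """
    if driver_gene not in em.gene_ids:
        raise KeyError(f"driver gene {driver_gene!r} not in matrix")
    if em.samples is not None:
        expr = em.patient_expression(driver_gene, "tumor")
    else:
        expr = em.values.loc[driver_gene]
    z = (expr - expr.mean()) / expr.std(ddof=0)
    rng = np.random.default_rng(seed)
    rates = baseline_rate * np.exp(beta * z.to_numpy())
    event_times = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        censor_times = rng.exponential(1.0 / censor_rate, size=len(z))
    else:
        censor_times = np.full(len(z), np.inf)
    observed = event_times <= censor_times
    times = np.minimum(event_times, censor_times)
    df = pd.DataFrame(
        {"time_days": times, "event": observed},
        index=pd.Index(z.index, name="patient_id"),
    )
    return ClinicalTable(df)
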