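"""Expression-matrix and clinical-table input, validation and filtering.

The pipeline's substrate is a genes x samples matrix of normalized,
non-negative expression values, optionally annotated with a per-sample
condition (``tumor`` / ``normal``) and a patient identifier that pairs a
tumor sample with its matched normal from the same patient.  Clinical
follow-up (time in days plus an event flag) is kept in a separate
patient-indexed table.

Reading is strict: duplicate identifiers, negative or non-finite values and
malformed clinical records are rejected up front rather than imputed, so
every downstream statistic can assume a clean matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("tumor", "normal")

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "read_expression",
    "read_sample_sheet",
    "read_clinical",
    "filter_low_expression",
    "select_differential",
]


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()].tolist()))
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dups))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with optional sample annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id; finite, >= 0.
    samples : pandas.DataFrame, optional
        Indexed by sample id with columns ``patient_id`` and ``condition``
        (``tumor`` or ``normal``).  Required for differential selection,
        pairing and survival stratification.
    """

    values: pd.DataFrame
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(vals).all():
            bad = self.values.index[~np.isfinite(vals).all(axis=1)]
            raise ValueError(f"non-finite expression values in genes: {list(bad)}")
        if (vals < 0).any():
            bad = self.values.index[(vals < 0).any(axis=1)]
            raise ValueError(f"negative expression values in genes: {list(bad)}")
        if self.samples is not None:
            missing = self.values.columns.difference(self.samples.index)
            if len(missing):
                raise ValueError(f"samples missing from sample sheet: {list(missing)}")
            self.samples = self.samples.loc[self.values.columns]
            bad = set(self.samples["condition"]) - set(CONDITIONS)
            if bad:
                raise ValueError(f"unknown condition labels: {sorted(bad)}")

    # -- basic introspection -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def has_conditions(self) -> bool:
        return self.samples is not None and self.samples["condition"].nunique() == 2

    def condition_samples(self, condition: str) -> list[str]:
        if self.samples is None:
            raise ValueError("no sample annotations attached")
        return list(self.samples.index[self.samples["condition"] == condition])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.samples)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        sub = self.samples.loc[list(samples)] if self.samples is not None else None
        return ExpressionMatrix(self.values[list(samples)], sub)

    def validate_pairing(self) -> None:
        """Require exactly one matched normal for every paired tumor patient."""
        if self.samples is None:
            raise ValueError("no sample annotations attached")
        by_patient = self.samples.groupby("patient_id")["condition"]
        for patient, conds in by_patient:
            conds = list(conds)
            if "tumor" in conds and conds.count("normal") != 1:
                raise ValueError(
                    f"patient {patient!r} has a tumor sample but "
                    f"{conds.count('normal')} matched normals"
                )

    def patient_expression(self, gene: str, condition: str = "tumor") -> pd.Series:
        """Per-patient expression of ``gene`` (mean over that patient's
        samples of the given condition)."""
        cols = self.condition_samples(condition)
        expr = self.values.loc[gene, cols]
        patients = self.samples.loc[cols, "patient_id"]
        return expr.groupby(patients).mean()


@dataclass
class ClinicalTable:
    """Patient follow-up: time (days), event flag and optional subgroups."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "patient ids")
        if "time_days" not in self.data or "event" not in self.data:
            raise ValueError("clinical table requires 'time_days' and 'event' columns")
        if (self.data["time_days"] < 0).any():
            raise ValueError("negative follow-up times")
        ev = self.data["event"]
        if not set(pd.unique(ev)) <= {0, 1, True, False}:
            raise ValueError("event flag must be boolean (0/1)")
        self.data = self.data.assign(event=ev.astype(bool))

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index


# -- readers -----------------------------------------------------------------

def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples matrix (first row sample ids, first column gene ids).

    Genes containing non-numeric entries are rejected (dropped with a
    warning); duplicated identifiers or an empty matrix are hard errors.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0, comment="#")
    if raw.size == 0:
        raise ValueError(f"empty expression matrix in {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.index[numeric.isna().any(axis=1)]
    if len(bad):
        warnings.warn(f"rejected {len(bad)} genes with non-numeric entries: {list(bad)[:10]}")
        numeric = numeric.drop(index=bad)
    if numeric.size == 0:
        raise ValueError(f"no numeric genes left in {path}")
    return ExpressionMatrix(numeric.astype(float))


def read_sample_sheet(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a sample sheet with columns sample_id, patient_id, condition."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), comment="#")
    required = {"sample_id", "patient_id", "condition"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    _check_unique(df["sample_id"], "sample ids")
    return df.set_index("sample_id")


def read_clinical(path: str | Path, sep: str | None = None) -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), comment="#")
    if "patient_id" not in df.columns:
        raise ValueError("clinical table must have a 'patient_id' column")
    return ClinicalTable(df.set_index("patient_id"))


# -- filtering / differential selection --------------------------------------

def filter_low_expression(
    em: ExpressionMatrix, min_value: float, min_fraction: float
) -> ExpressionMatrix:
    """Keep genes expressed at >= ``min_value`` in >= ``min_fraction`` of samples.

    Both bounds are inclusive; a filter that removes every gene raises.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    frac = (em.values >= min_value).mean(axis=1)
    keep = em.gene_ids[frac >= min_fraction]
    if len(keep) == 0:
        raise ValueError(
            "low-expression filter removed every gene; lower min_value or min_fraction"
        )
    return ExpressionMatrix(em.values.loc[keep], em.samples)


def select_differential(
    em: ExpressionMatrix,
    log2fc_threshold: float = 1.0,
    pseudocount: float = 0.05,
) -> pd.DataFrame:
    """Score genes by tumor-vs-normal mean log2 fold change.

    log2FC = log2((mean_tumor + eps) / (mean_normal + eps)) with a pseudocount
    eps guarding against zero means; a gene is selected iff
    ``|log2FC| >= log2fc_threshold``.  Returns a per-gene table
    (mean_tumor, mean_normal, log2fc, selected).
    """
    if em.samples is None:
        raise ValueError("differential selection requires sample annotations")
    for cond in CONDITIONS:
        if len(em.condition_samples(cond)) < 2:
            raise ValueError(f"need >= 2 '{cond}' samples for differential selection")
    mt = em.values[em.condition_samples("tumor")].mean(axis=1)
    mn = em.values[em.condition_samples("normal")].mean(axis=1)
    log2fc = np.log2((mt + pseudocount) / (mn + pseudocount))
    return pd.DataFrame(
        {
            "mean_tumor": mt,
            "mean_normal": mn,
            "log2fc": log2fc,
            "selected": np.abs(log2fc) >= log2fc_threshold,
        }
    )
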