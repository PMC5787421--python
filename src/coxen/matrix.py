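"""Core in-memory containers for expression, drug-activity and phenotype data.

Expression values are assumed to be on a log scale throughout; drug activity
is oriented so that larger values mean a more sensitive cell line (i.e. the
negated log GI50 convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {kind} id {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log-scale expression values.

    Parameters
    ----------
    gene_ids : ordered unique gene identifiers (opaque strings; any
        probe-to-gene mapping must happen upstream).
    sample_ids : ordered unique sample identifiers.
    values : float array of shape ``(len(gene_ids), len(sample_ids))``;
        every entry must be finite.
    system_label : free-text label of the cancer system the data came from
        (e.g. ``"cell_panel"`` or ``"breast_cohort_A"``).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    system_label: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite expression value at gene {self.gene_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        if len(self.sample_ids) < 1:
            raise DataError("expression matrix needs at least one sample")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise DataError(f"genes not present in {self.system_label or 'matrix'}: {missing}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids),
            self.values[idx], self.system_label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, system_label: str = "") -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), system_label)


@dataclass
class DrugActivity:
    """Per-cell-line drug sensitivity, larger = more sensitive (-log GI50)."""

    cell_line_ids: list[str]
    activity: np.ndarray
    drug_name: str = ""

    def __post_init__(self) -> None:
        self.cell_line_ids = [str(c) for c in self.cell_line_ids]
        self.activity = np.asarray(self.activity, dtype=float)
        _check_unique(self.cell_line_ids, "cell line")
        if self.activity.ndim != 1 or len(self.activity) != len(self.cell_line_ids):
            raise DataError("activity length does not match cell_line_ids")
        if not np.all(np.isfinite(self.activity)):
            bad = self.cell_line_ids[int(np.argwhere(~np.isfinite(self.activity))[0][0])]
            raise DataError(f"non-finite activity for cell line {bad!r}")
        if len(self.activity) > 0 and np.ptp(self.activity) == 0:
            raise DataError("all drug-activity values identical")

    def reorder(self, cell_lines: Sequence[str]) -> "DrugActivity":
        pos = {c: i for i, c in enumerate(self.cell_line_ids)}
        missing = [c for c in cell_lines if c not in pos]
        if missing:
            raise DataError(f"cell lines without activity values: {missing}")
        idx = [pos[c] for c in cell_lines]
        return DrugActivity(list(cell_lines), self.activity[idx], self.drug_name)


@dataclass
class PhenotypeTable:
    """Per-sample clinical outcomes: binary response (1 = pathologic complete
    response) and/or survival time with an event indicator (1 = observed)."""

    sample_ids: list[str]
    response: Optional[np.ndarray] = None   # float with NaN for missing
    time: Optional[np.ndarray] = None
    event: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        for name in ("response", "time", "event"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise DataError(f"{name} length does not match sample_ids")
                setattr(self, name, v)
        if self.response is not None:
            vals = self.response[~np.isnan(self.response)]
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise DataError("response must be 0/1 where present")
        if self.event is not None:
            if self.time is None:
                raise DataError("event column requires a time column")
            vals = self.event[~np.isnan(self.event)]
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise DataError("event must be 0/1 where present")
        if self.time is not None:
            vals = self.time[~np.isnan(self.time)]
            if np.any(vals < 0):
                raise DataError("survival times must be nonnegative")

    def subset(self, samples: Sequence[str]) -> "PhenotypeTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise DataError(f"samples without phenotype rows: {missing}")
        idx = np.array([pos[s] for s in samples], dtype=int)
        pick = lambda v: None if v is None else v[idx]
        return PhenotypeTable(list(samples), pick(self.response), pick(self.time), pick(self.event))


def align_by_common_genes(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    genes: Optional[Sequence[str]] = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to their shared genes, in canonical
    (lexicographic) order, leaving samples untouched.

    If `genes` is given, the result is further restricted to those ids.
    """
    common = set(a.gene_ids) & set(b.gene_ids)
    if genes is not None:
        common &= set(str(g) for g in genes)
    ordered = sorted(common)
    if len(ordered) < 2:
        raise DataError("insufficient shared genes (need at least 2)")
    return a.subset_genes(ordered), b.subset_genes(ordered)


def zscore_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sample standard deviation 1."""
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise DataError(f"constant gene cannot be standardized: {m.gene_ids[flat[0]]!r}")
    return replace(m, values=(m.values - mu) / sd)
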