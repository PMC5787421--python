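"""Readers/writers for the TSV interchange formats and the run configuration.

File dialects
-------------
Expression: tab-separated, genes in rows, one header row of sample ids,
first column header ``gene_id``.  Drug activity: columns ``cell_line_id``,
``activity``.  Phenotype: columns ``sample_id``, ``response``, ``time``,
``event`` (empty cell = missing; ``response``/``time``/``event`` columns are
each optional).  Run configuration: YAML or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .matrix import DataError, DrugActivity, ExpressionMatrix, PhenotypeTable


def read_expression_matrix(path, fmt: str = "tsv", system_label: str = "") -> ExpressionMatrix:
    """Load a genes x samples expression TSV into an :class:`ExpressionMatrix`.

    Duplicate ids and non-numeric or missing cells are rejected with errors
    naming the offending row/column.
    """
    if fmt != "tsv":
        raise ValueError(f"unsupported format {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    genes = [str(g) for g in raw.index]
    samples = [str(s) for s in raw.columns]
    dup_g = raw.index[raw.index.duplicated()]
    if len(dup_g):
        raise DataError(f"duplicate gene id {dup_g[0]!r} in {path.name}")
    dup_s = raw.columns[raw.columns.duplicated()]
    if len(dup_s):
        raise DataError(f"duplicate sample id {dup_s[0]!r} in {path.name}")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            cell = raw[col].iloc[bad[0]]
            raise DataError(
                f"non-numeric cell {cell!r} at gene {genes[bad[0]]!r}, "
                f"sample {col!r} in {path.name}"
            )
        # numpy's string parser is correctly rounded (exact round-trip)
        values[:, j] = raw[col].to_numpy().astype(np.float64)
    label = system_label or path.stem
    return ExpressionMatrix(genes, samples, values, label)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write a matrix in the expression TSV dialect (lossless round-trip:
    floats are printed with ``repr`` precision)."""
    df = m.to_frame()
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=None)


def read_drug_activity(path, drug_name: str = "") -> DrugActivity:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    for col in ("cell_line_id", "activity"):
        if col not in df.columns:
            raise DataError(f"drug-activity file {path.name} lacks column {col!r}")
    act = pd.to_numeric(df["activity"], errors="coerce")
    bad = np.flatnonzero(act.isna().to_numpy())
    if bad.size:
        raise DataError(
            f"non-numeric activity for cell line {df['cell_line_id'].iloc[bad[0]]!r} in {path.name}"
        )
    return DrugActivity(list(df["cell_line_id"].astype(str)), act.to_numpy(dtype=float),
                        drug_name or path.stem)


def write_drug_activity(act: DrugActivity, path) -> None:
    pd.DataFrame({"cell_line_id": act.cell_line_ids, "activity": act.activity}).to_csv(
        path, sep="\t", index=False)


def read_phenotype_table(path) -> PhenotypeTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise DataError(f"phenotype file {path.name} lacks column 'sample_id'")
    cols = {}
    for col in ("response", "time", "event"):
        if col in df.columns:
            cols[col] = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        else:
            cols[col] = None
    return PhenotypeTable(list(df["sample_id"].astype(str)), cols["response"],
                          cols["time"], cols["event"])


def write_phenotype_table(p: PhenotypeTable, path) -> None:
    data: dict = {"sample_id": p.sample_ids}
    for name in ("response", "time", "event"):
        v = getattr(p, name)
        if v is not None:
            data[name] = v
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


@dataclass
class CohortSpec:
    """One patient cohort and its role in the pipeline.

    Roles: ``original_coxen`` (original-type co-expression reference),
    ``original_evaluation`` (original-type cohort used for model selection
    and threshold fixing), ``candidate_coxen`` (new-type co-expression set,
    gated and used in the three-way triage), ``validation`` (held out until
    the final prospective validation step).
    """

    name: str
    expression: str
    role: str
    phenotype: Optional[str] = None
    cancer_type: str = ""

    _ROLES = ("original_coxen", "original_evaluation", "candidate_coxen", "validation")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"cohort {self.name!r}: unknown role {self.role!r}")


@dataclass
class RunConfig:
    """All tunables of the pipeline, with the published defaults where the
    method states one (discovery FDR 0.05, three-way FDR 0.2, gate alpha
    0.025 one-sided, 98th-percentile permutation cut-off)."""

    cell_expression: str = ""
    drug_activity: str = ""
    cohorts: list[CohortSpec] = field(default_factory=list)
    output_dir: str = "coxen_out"
    drug_name: str = "drug"

    discovery_method: str = "correlation"      # or "ttest"
    discovery_fdr: float = 0.05
    lower_frac: float = 1.0 / 3.0              # resistant cut for the t-test route
    upper_frac: float = 2.0 / 3.0              # sensitive cut

    threeway_fdr: float = 0.2
    n_permutations: int = 500
    null_percentile: float = 98.0
    coxen_selection: str = "pvalue_bh"         # or "percentile_cut"
    diagonal_mode: str = "excluded"
    gate_alpha: float = 0.025

    grid_start: int = 4
    grid_step: int = 4
    variance_frac: float = 0.8
    min_model_genes: int = 4

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.discovery_fdr < 1 and 0 < self.threeway_fdr < 1):
            raise ValueError("FDR levels must lie in (0,1)")
        if not (0 < self.gate_alpha < 0.5):
            raise ValueError("gate alpha must lie in (0, 0.5)")
        if not (0 < self.null_percentile < 100):
            raise ValueError("null percentile must lie in (0,100)")
        if self.n_permutations < 100:
            raise ValueError("null too coarse: need at least 100 permutations")
        self.cohorts = [c if isinstance(c, CohortSpec) else CohortSpec(**c)
                        for c in self.cohorts]


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    data = asdict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
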