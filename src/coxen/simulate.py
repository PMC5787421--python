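"""Synthetic multi-system datasets with planted concordant co-expression.

Two latent factors per system drive the expression structure.  The primary
drug-sensitivity factor f (standard normal per sample) is loaded by the
concordant genes (s_i * lambda * f plus unit noise, sign s_i fixed per gene
across systems) in every system.  A secondary, independent factor g is
loaded by the pairwise-only genes in exactly two of the three cancer
systems — the cell panel and the new cancer type — while those genes are
pure noise in the original type; null genes are noise everywhere.  (A gene
that merely sat out one system while the others share a single factor
would still show an aligned correlation column there through its sampling
correlation with that factor, so a separate factor is what actually makes
the pairwise-only genes' co-expression discordant in the original-type
pairs.)  Drug activity on the cell panel is f plus a weaker contribution
from g plus Gaussian noise, which is what makes the pairwise-only genes
discoverable as initial biomarkers in the first place; patient response is
Bernoulli with a logistic link in f whose offset
is calibrated to the configured baseline rate; survival is exponential with
a lower hazard for responders, with independent censoring at the configured
rate.  The "unsuitable" cohort is generated like a new-type cohort and then
has its gene identities randomly permuted, destroying cross-system
concordance while leaving every marginal distribution intact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .io import (write_drug_activity, write_expression_matrix, write_phenotype_table,
                 read_drug_activity, read_expression_matrix, read_phenotype_table)
from .matrix import DrugActivity, ExpressionMatrix, PhenotypeTable


@dataclass
class SyntheticConfig:
    """Study conditions for the generator (defaults are the package's
    reference conditions; see docs/methods.md for the rationale)."""

    n_genes: int = 100
    n_concordant: int = 30
    n_pairwise_only: int = 20
    n_cell_lines: int = 60
    n_original_coxen: int = 100
    n_original_eval: int = 100
    n_new_coxen: int = 100
    n_new_validation: int = 80
    n_unsuitable: int = 60
    loading: float = 1.0           # lambda: factor loading of planted genes
    activity_noise: float = 0.5    # sigma_a
    secondary_weight: float = 0.7  # weight of the secondary factor in activity
    response_steepness: float = 2.0
    baseline_response_rate: float = 0.3
    censoring_rate: float = 0.2
    responder_hazard: float = 0.3
    nonresponder_hazard: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_concordant + self.n_pairwise_only > self.n_genes:
            raise ValueError("gene-class counts exceed n_genes")
        for r in (self.baseline_response_rate, self.censoring_rate):
            if not (0.0 < r < 1.0):
                raise ValueError("rates must lie in (0, 1)")
        if self.activity_noise <= 0:
            raise ValueError("activity noise must be positive")

    @property
    def n_null(self) -> int:
        return self.n_genes - self.n_concordant - self.n_pairwise_only


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    phenotype: Optional[PhenotypeTable]
    factor: np.ndarray


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    cell_expression: ExpressionMatrix
    drug_activity: DrugActivity
    cell_factor: np.ndarray
    cohorts: dict                  # name -> SyntheticCohort
    gene_classes: dict             # gene_id -> "concordant"|"pairwise_only"|"null"

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g, c in self.gene_classes.items() if c == cls]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_offset(f: np.ndarray, beta: float, rate: float) -> float:
    """Offset such that the mean response probability over the realized
    factor values equals the configured baseline rate."""
    def gap(c):
        return _logistic(beta * (f - c)).mean() - rate
    lo, hi = f.min() - 20.0, f.max() + 20.0
    return float(brentq(gap, lo, hi))


def _expression(rng, genes, load_f, load_g, n_samples,
                label) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    f = rng.standard_normal(n_samples)
    g = rng.standard_normal(n_samples)
    noise = rng.standard_normal((len(genes), n_samples))
    values = load_f[:, None] * f[None, :] + load_g[:, None] * g[None, :] + noise
    samples = [f"{label}_s{i:03d}" for i in range(n_samples)]
    return ExpressionMatrix(list(genes), samples, values, label), f, g


def _phenotype(rng, cfg: SyntheticConfig, samples, f,
               survival: bool) -> PhenotypeTable:
    offset = _calibrate_offset(f, cfg.response_steepness, cfg.baseline_response_rate)
    prob = _logistic(cfg.response_steepness * (f - offset))
    response = (rng.random(len(f)) < prob).astype(float)
    time = event = None
    if survival:
        rate = np.where(response == 1, cfg.responder_hazard, cfg.nonresponder_hazard)
        t = rng.exponential(1.0 / rate)
        censored = rng.random(len(f)) < cfg.censoring_rate
        time = np.where(censored, rng.random(len(f)) * t, t)
        event = (~censored).astype(float)
    return PhenotypeTable(list(samples), response, time, event)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one complete multi-system dataset under `config`.

    Systems: a cell panel with drug activity; two original-cancer cohorts
    (co-expression reference and evaluation cohort with response); a
    new-cancer co-expression cohort; a new-cancer validation cohort with
    response and survival; and a gene-permuted unsuitable cohort.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    classes = (["concordant"] * cfg.n_concordant
               + ["pairwise_only"] * cfg.n_pairwise_only
               + ["null"] * cfg.n_null)
    perm = rng.permutation(cfg.n_genes)
    gene_classes = {genes[i]: classes[perm[i]] for i in range(cfg.n_genes)}
    signs = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    is_conc = np.array([gene_classes[g] == "concordant" for g in genes])
    is_pair = np.array([gene_classes[g] == "pairwise_only" for g in genes])

    lam = cfg.loading * signs
    load_f = np.where(is_conc, lam, 0.0)                # concordant genes, all systems
    g_on = np.where(is_pair, lam, 0.0)                  # pairwise-only genes
    g_off = np.zeros(cfg.n_genes)

    cell_expr, f_cell, g_cell = _expression(rng, genes, load_f, g_on,
                                            cfg.n_cell_lines, "cell_panel")
    activity = (f_cell + cfg.secondary_weight * g_cell
                + cfg.activity_noise * rng.standard_normal(cfg.n_cell_lines))
    act = DrugActivity(list(cell_expr.sample_ids), activity, "synthetic_drug")

    cohorts: dict[str, SyntheticCohort] = {}

    e, f, _ = _expression(rng, genes, load_f, g_off, cfg.n_original_coxen,
                          "original_coxen")
    cohorts["original_coxen"] = SyntheticCohort(e, None, f)

    e, f, _ = _expression(rng, genes, load_f, g_off, cfg.n_original_eval,
                          "original_eval")
    cohorts["original_eval"] = SyntheticCohort(
        e, _phenotype(rng, cfg, e.sample_ids, f, survival=False), f)

    e, f, _ = _expression(rng, genes, load_f, g_on, cfg.n_new_coxen, "new_coxen")
    cohorts["new_coxen"] = SyntheticCohort(e, None, f)

    e, f, _ = _expression(rng, genes, load_f, g_on, cfg.n_new_validation,
                          "new_validation")
    cohorts["new_validation"] = SyntheticCohort(
        e, _phenotype(rng, cfg, e.sample_ids, f, survival=True), f)

    e, f, _ = _expression(rng, genes, load_f, g_on, cfg.n_unsuitable, "unsuitable")
    scramble = rng.permutation(cfg.n_genes)
    e = ExpressionMatrix(list(e.gene_ids), list(e.sample_ids),
                         e.values[scramble], "unsuitable")
    cohorts["unsuitable"] = SyntheticCohort(
        e, _phenotype(rng, cfg, e.sample_ids, f, survival=True), f)

    return SyntheticDataset(cfg, cell_expr, act, f_cell, cohorts, gene_classes)


def write_fixture(ds: SyntheticDataset, directory) -> dict:
    """Write every table in the TSV dialects plus ground truth and a
    manifest; returns the manifest (also saved as manifest.json)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "seed": ds.config.seed}

    def note(key, path, rows, cols):
        manifest["files"][key] = {"path": path.name, "rows": rows, "columns": cols}

    p = d / "cell_expression.tsv"
    write_expression_matrix(ds.cell_expression, p)
    note("cell_expression", p, ds.cell_expression.n_genes, ds.cell_expression.n_samples)
    p = d / "drug_activity.tsv"
    write_drug_activity(ds.drug_activity, p)
    note("drug_activity", p, len(ds.drug_activity.cell_line_ids), 2)
    for name, cohort in ds.cohorts.items():
        p = d / f"{name}_expression.tsv"
        write_expression_matrix(cohort.expression, p)
        note(f"{name}_expression", p, cohort.expression.n_genes,
             cohort.expression.n_samples)
        if cohort.phenotype is not None:
            p = d / f"{name}_phenotype.tsv"
            write_phenotype_table(cohort.phenotype, p)
            note(f"{name}_phenotype", p, len(cohort.phenotype.sample_ids), 4)
    p = d / "ground_truth.tsv"
    with open(p, "w") as fh:
        fh.write("gene_id\tclass\n")
        for g in ds.cell_expression.gene_ids:
            fh.write(f"{g}\t{ds.gene_classes[g]}\n")
    note("ground_truth", p, len(ds.gene_classes), 2)
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def fixture_run_config(directory, seed: int = 0, **overrides):
    """RunConfig wired to a written fixture's standard file layout, with the
    generator's cohorts mapped to their pipeline roles."""
    from .io import CohortSpec, RunConfig
    d = Path(directory)
    cohorts = [
        CohortSpec("original_coxen", str(d / "original_coxen_expression.tsv"),
                   "original_coxen", cancer_type="original"),
        CohortSpec("original_eval", str(d / "original_eval_expression.tsv"),
                   "original_evaluation", str(d / "original_eval_phenotype.tsv"),
                   cancer_type="original"),
        CohortSpec("new_coxen", str(d / "new_coxen_expression.tsv"),
                   "candidate_coxen", cancer_type="new"),
        CohortSpec("new_validation", str(d / "new_validation_expression.tsv"),
                   "validation", str(d / "new_validation_phenotype.tsv"),
                   cancer_type="new"),
        CohortSpec("unsuitable", str(d / "unsuitable_expression.tsv"),
                   "validation", str(d / "unsuitable_phenotype.tsv"),
                   cancer_type="new"),
    ]
    return RunConfig(cell_expression=str(d / "cell_expression.tsv"),
                     drug_activity=str(d / "drug_activity.tsv"),
                     cohorts=cohorts, seed=seed, **overrides)


def read_fixture(directory) -> dict:
    """Read a written fixture back into in-memory objects keyed like the
    manifest (expression matrices, activity, phenotypes)."""
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    out: dict = {}
    for key, info in manifest["files"].items():
        path = d / info["path"]
        if key == "drug_activity":
            out[key] = read_drug_activity(path)
        elif key.endswith("_phenotype"):
            out[key] = read_phenotype_table(path)
        elif key == "ground_truth":
            classes = {}
            for line in path.read_text().splitlines()[1:]:
                g, c = line.split("\t")
                classes[g] = c
            out[key] = classes
        else:
            label = key.removesuffix("_expression") if key != "cell_expression" else "cell_panel"
            out[key] = read_expression_matrix(path, system_label=label)
    return out
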