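"""Generate a synthetic multi-system dataset and write it as TSV files.

The generator plants one drug-sensitivity latent factor: 30 concordantly
co-expressed biomarker genes (shared across the cell panel, the original
cancer type and a new cancer type), 20 genes co-expressed only in the cell
panel and the new type, and 50 null genes, plus drug activity, binary
response, and survival outcomes driven by the factor.
"""

from coxen import SyntheticConfig, generate, write_fixture

ds = generate(SyntheticConfig(seed=1))
manifest = write_fixture(ds, "scratch/example_fixture")

print(f"cell panel: {ds.cell_expression.n_genes} genes x "
      f"{ds.cell_expression.n_samples} cell lines")
for name, cohort in ds.cohorts.items():
    pheno = "expression only" if cohort.phenotype is None else "with phenotype"
    print(f"cohort {name}: {cohort.expression.n_samples} patients ({pheno})")
print(f"wrote {len(manifest['files'])} files to scratch/example_fixture/")
# Each expression file is a genes x samples TSV; ground_truth.tsv records
# which planted class every gene belongs to.
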