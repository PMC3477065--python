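"""Generate the reference matched-pair cohort and write it to disk.

Nine patients, each with a primary ovarian tumor and a matched peritoneal
metastasis profile; 2,500 genes; 12 CNV segments with exactly three
amplified, three deleted and three copy-neutral patients each; three
metastasis-age groups with decreasing planted divergence; and a 193-gene
prognostic panel with 80% direction concordance.
"""

from pathlib import Path

from paircnv import CohortSpec, generate_cohort
from paircnv.cohort import write_fixture

OUT = Path("results/cohort")

spec = CohortSpec(seed=1)
cohort = generate_cohort(spec)
manifest = write_fixture(OUT, cohort)

print(f"cohort written to {OUT}/ (seed {spec.seed})")
print(f"  patients: {len(cohort.expression.patients)} "
      f"({dict(cohort.truth.group_of_patient.value_counts())})")
print(f"  genes/probes: {spec.n_genes}; CNV records: {len(cohort.cnv)} "
      f"over {spec.n_segments} segments")
print(f"  planted divergent genes per group: "
      f"{dict(zip(spec.group_names, spec.n_de_per_group))}")
print(f"  prognostic panel: {spec.n_prognostic} genes, concordance rate "
      f"{spec.concordance_rate}")
print(f"  files: {', '.join(manifest['files'])}")
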