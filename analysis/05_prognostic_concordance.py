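"""Direction concordance of the prognostic panel in metastasis vs primary.

Each detectable panel gene is classified up or down by the sign of its
mean paired difference; the four good/poor x up/down cells are tested
against equal proportions with a 3-d.f. goodness-of-fit chi-squared. A
significant excess of good-up and poor-down means the metastases sit
closer to the favorable end of the signature than their primaries.
"""

from pathlib import Path

import pandas as pd

from paircnv import read_expression
from paircnv.io_formats import read_probe_bed, read_prognostic
from paircnv.paired_de import paired_differences
from paircnv.plotting import plot_prognostic_heatmap
from paircnv.prognostic import classify_directions, concordance_test

OUT = Path("results")
expr = read_expression(OUT / "cohort/expression.tsv")
probes = read_probe_bed(OUT / "cohort/probes.bed")
prognostic = read_prognostic(OUT / "cohort/prognostic.tsv")

table = classify_directions(expr, probes, prognostic, detectable_only=True)
chi2, dof, p = concordance_test(table, structure="gof4")
chi2_ind, dof_ind, p_ind = concordance_test(table,
                                            structure="independence2x2")

table.directions.to_csv(OUT / "prognostic_directions.tsv", sep="\t",
                        index=False)
pd.DataFrame([{**table.counts, "chi2": chi2, "dof": dof, "p": p}]) \
  .to_csv(OUT / "prognostic_concordance.tsv", sep="\t", index=False)
plot_prognostic_heatmap(table.directions, paired_differences(expr),
                        probes.gene_of(), OUT / "fig_prognostic_heatmap.png")

print(f"{table.n_classified} prognostic genes classified "
      f"({len(table.excluded)} excluded: "
      f"{dict(table.excluded['reason'].value_counts())})")
print(f"  cells: {table.counts}")
print(f"  concordant fraction (good-up + poor-down): "
      f"{table.concordant_fraction:.3f}")
print(f"  goodness-of-fit chi-squared = {chi2:.1f}, {dof} d.f., p = {p:.2e}")
print(f"  (2x2 independence alternative: chi-squared = {chi2_ind:.1f}, "
      f"{dof_ind} d.f., p = {p_ind:.2e})")
print(f"  figure: {OUT}/fig_prognostic_heatmap.png")
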