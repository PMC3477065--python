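"""Direction concordance of prognostic genes in metastasis versus primary.

Given a panel of genes labelled good- or poor-prognosis (e.g. a survival
signature derived from primary tumors), each gene is classified up or down
by the sign of its mean paired difference (metastasis minus primary), and
the four cell counts good-up / good-down / poor-up / poor-down are tested
against the no-preference expectation. A preponderance of good-up and
poor-down indicates metastases whose expression sits closer to the
favorable end of the signature than their matched primaries.

Two test structures are provided because a reported "3 d.f." chi-squared is
only consistent with a four-category goodness-of-fit (equal expected
proportions, dof 3), not with a 2x2 independence test (dof 1); both are
implemented and labelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .io_formats import ExpressionMatrix, PrognosticGeneList, ProbeAnnotation

CELLS = ("good_up", "good_down", "poor_up", "poor_down")


@dataclass
class ConcordanceTable:
    counts: dict[str, int]                 # the four cells
    directions: pd.DataFrame               # gene, label, mean_diff, direction
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_classified(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def concordant_fraction(self) -> float:
        """Fraction of classified genes moving in their label's favorable
        direction (good up, poor down)."""
        conc = self.counts["good_up"] + self.counts["poor_down"]
        return conc / self.n_classified


def classify_directions(expr: ExpressionMatrix, probes: ProbeAnnotation,
                        prognostic: PrognosticGeneList,
                        detectable_only: bool = True,
                        detect_percentile: float = 5.0) -> ConcordanceTable:
    """Classify each prognostic gene up or down in metastasis versus primary.

    Genes absent from the array are excluded and listed; with
    ``detectable_only``, genes whose expression drops below the
    ``detect_percentile``-th percentile of the whole matrix in any sample are
    excluded as undetectable. Multi-probe genes are collapsed by averaging
    probe-level values. Exact zero mean differences are excluded as ties
    rather than assigned a direction.
    """
    from .paired_de import paired_differences

    prognostic.validate()
    gene_of = probes.gene_of()
    diffs = paired_differences(expr)
    gene_diff = diffs.groupby(gene_of.reindex(diffs.index)).mean()
    detect_floor = float(np.percentile(expr.values.to_numpy(),
                                       detect_percentile))
    gene_min = expr.values.groupby(gene_of.reindex(expr.values.index)).mean() \
                          .min(axis=1)

    rows, excluded = [], []
    for gene, label in prognostic.labels.items():
        if gene not in gene_diff.index:
            excluded.append((gene, label, "absent"))
            continue
        if detectable_only and gene_min.loc[gene] < detect_floor:
            excluded.append((gene, label, "undetectable"))
            continue
        md = float(gene_diff.loc[gene].mean())
        if md == 0.0:
            excluded.append((gene, label, "tied"))
            continue
        rows.append((gene, label, md, "up" if md > 0 else "down"))
    if not rows:
        raise ValidationError("no prognostic gene could be classified against "
                              "the expression matrix")
    directions = pd.DataFrame(rows, columns=["gene", "label", "mean_diff",
                                             "direction"])
    counts = {c: 0 for c in CELLS}
    for _, r in directions.iterrows():
        counts[f"{r['label']}_{r['direction']}"] += 1
    return ConcordanceTable(
        counts=counts, directions=directions,
        excluded=pd.DataFrame(excluded, columns=["gene", "label", "reason"]))


def concordance_test(table: ConcordanceTable,
                     structure: str = "gof4") -> tuple[float, int, float]:
    """Chi-squared test of the four direction-by-label cells.

    ``gof4``: goodness-of-fit of the observed cells against equal expected
    proportions (dof 3). ``independence2x2``: standard label x direction
    independence chi-squared without continuity correction (dof 1).
    Returns (chi2, dof, p).
    """
    obs = np.array([table.counts[c] for c in CELLS], dtype=float)
    n = obs.sum()
    if structure == "gof4":
        expected = n / 4.0
        if expected <= 0:
            raise DegenerateInputError("expected counts are zero; use an "
                                       "exact test")
        chi2, p = stats.chisquare(obs)
        return float(chi2), 3, float(p)
    if structure == "independence2x2":
        cont = obs.reshape(2, 2)
        if (cont.sum(axis=0) == 0).any() or (cont.sum(axis=1) == 0).any():
            raise DegenerateInputError("a margin is zero; use an exact test")
        chi2, p, dof, _ = stats.chi2_contingency(cont, correction=False)
        return float(chi2), int(dof), float(p)
    raise ValidationError(f"unknown structure {structure!r}; expected 'gof4' "
                          "or 'independence2x2'")
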