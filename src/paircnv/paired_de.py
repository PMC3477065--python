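"""Paired differential expression of metastasis versus matched primary.

The unit of analysis is the within-patient paired difference: metastasis
log2 expression minus primary log2 expression, the primary tumor being the
baseline. Probes are tested with a two-sided one-sample t-test of the
differences against zero; fold changes use a signed linear convention
(positive = over-expressed in metastasis, magnitude always >= 1) so the
classic "at least 1.5-fold" filter reads the same in both directions.

Two reporting modes mirror common practice on matched cohorts: a global
mode filtering on |fold| >= 1.5 and p < 0.01, and a per-group
("personalized") mode run within metastasis-age groups at |fold| >= 2 and
BH FDR < 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ValidationError
from .io_formats import ExpressionMatrix, sample_id


@dataclass(frozen=True)
class DeThresholds:
    """Reporting thresholds for the two calling modes."""

    min_abs_fold: float = 1.5   # global mode: linear fold cutoff
    max_p: float = 0.01         # global mode: raw p cutoff
    alt_fold: float = 2.0       # group mode: linear fold cutoff
    alt_fdr: float = 0.2        # group mode: BH q cutoff

    def validate(self) -> "DeThresholds":
        if not (self.min_abs_fold > 1 and self.alt_fold > 1):
            raise ValidationError("fold thresholds must exceed 1")
        if not (0 < self.max_p < 1 and 0 < self.alt_fdr < 1):
            raise ValidationError("probability thresholds must lie in (0, 1)")
        return self


def paired_differences(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-patient paired log2 differences (metastasis minus primary).

    Returns a probes x patients frame; raises :class:`PairingError` listing
    any patient without exactly one sample of each tissue.
    """
    patients = expr.require_paired()
    met = expr.values[[sample_id(p, "metastasis") for p in patients]]
    prim = expr.values[[sample_id(p, "primary") for p in patients]]
    diff = pd.DataFrame(met.to_numpy() - prim.to_numpy(),
                        index=expr.values.index,
                        columns=pd.Index(patients, name="patient"))
    return diff


def paired_t_test(differences) -> tuple[float, float, bool]:
    """Two-sided one-sample t-test of paired differences against zero.

    Returns ``(t, p, zero_variance)``. Zero-variance input is a degenerate
    case reported as ``(nan, 1.0, True)`` rather than an error, so constant
    probes stay visible downstream.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1:
        raise ValidationError("paired_t_test expects a 1-D vector")
    if d.size < 2:
        raise DegenerateInputError(f"need at least 2 pairs, got {d.size}")
    if not np.isfinite(d).all():
        raise ValidationError("non-finite paired differences")
    if np.ptp(d) == 0.0:
        return (float("nan"), 1.0, True)
    res = stats.ttest_1samp(d, 0.0)
    return (float(res.statistic), float(res.pvalue), False)


def signed_fold_change(mean_log2_diff):
    """Signed linear fold change of a mean log2 difference.

    ``d >= 0`` maps to ``2**d`` and ``d < 0`` to ``-2**(-d)``, so the
    magnitude is always >= 1 and the sign marks the direction (positive =
    over-expressed in metastasis). Vectorized over array input.
    """
    d = np.asarray(mean_log2_diff, dtype=float)
    fold = np.where(d >= 0, np.exp2(d), -np.exp2(-d))
    return float(fold) if np.isscalar(mean_log2_diff) else fold


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(differences: pd.DataFrame) -> pd.DataFrame:
    """Per-probe paired statistics over a probes x patients difference frame.

    Columns: mean_diff, fold_change, t, p, q, n_pairs, zero_variance.
    """
    n = differences.shape[1]
    if n < 2:
        raise DegenerateInputError(f"need at least 2 pairs, got {n}")
    x = differences.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("non-finite paired differences")
    mean = x.mean(axis=1)
    flat = np.ptp(x, axis=1) == 0.0
    t = np.full(x.shape[0], np.nan)
    p = np.ones(x.shape[0])
    if (~flat).any():
        res = stats.ttest_1samp(x[~flat], 0.0, axis=1)
        t[~flat] = res.statistic
        p[~flat] = res.pvalue
    out = pd.DataFrame({
        "mean_diff": mean,
        "fold_change": signed_fold_change(mean),
        "t": t,
        "p": p,
        "q": bh_adjust(p),
        "n_pairs": n,
        "zero_variance": flat,
    }, index=differences.index)
    return out


def call_de(results: pd.DataFrame, thresholds: DeThresholds = DeThresholds(),
            mode: str = "global") -> pd.DataFrame:
    """Filter a :func:`de_table` to called probes with an up/down direction.

    ``global`` mode applies |fold| >= min_abs_fold and p < max_p; ``group``
    mode applies |fold| >= alt_fold and q < alt_fdr.
    """
    thresholds.validate()
    if mode == "global":
        keep = ((results["fold_change"].abs() >= thresholds.min_abs_fold)
                & (results["p"] < thresholds.max_p))
    elif mode == "group":
        keep = ((results["fold_change"].abs() >= thresholds.alt_fold)
                & (results["q"] < thresholds.alt_fdr))
    else:
        raise ValidationError(f"unknown mode {mode!r}; expected 'global' or "
                              "'group'")
    called = results[keep & ~results["zero_variance"]].copy()
    called["direction"] = np.where(called["mean_diff"] > 0, "up", "down")
    return called


def group_de(expr: ExpressionMatrix, groups: pd.Series,
             thresholds: DeThresholds = DeThresholds(),
             mode: str = "group") -> dict[str, dict[str, pd.DataFrame]]:
    """Run the paired test within each patient group separately.

    ``groups`` maps patient -> group label. Returns per group the full
    statistics table and the called subset.
    """
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for gname in dict.fromkeys(groups):
        members = groups.index[groups == gname]
        sub = expr.subset_patients(members)
        table = de_table(paired_differences(sub))
        out[str(gname)] = {"table": table,
                           "calls": call_de(table, thresholds, mode=mode)}
    return out
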