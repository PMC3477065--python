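"""Probe-to-CNV encompassment mapping and the stratified expression contrast.

A probe is assigned a patient's CNV state only when its interval is fully
encompassed by one of that patient's segments (or by the exact union of
abutting same-state segments); partial overlap leaves the probe "normal"
for that patient. Per probe, patients are then stratified by state
(amplified / deleted / normal) and the metastasis-minus-primary paired
differences are summarized within each stratum and pooled over all
patients. Pooling attenuates dosage effects: the pooled mean is exactly the
n-weighted average of stratum means, which is how a 1.5-fold dosage shift
carried by a third of patients averages below common selection thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import CnvConflictError, ValidationError
from .io_formats import (AMPLIFIED, DELETED, NORMAL, CnvSegmentSet,
                         ProbeAnnotation)
from .paired_de import paired_t_test

STATES = (AMPLIFIED, DELETED, NORMAL)
_PREFIX = {AMPLIFIED: "amp", DELETED: "del", NORMAL: "norm"}


@dataclass
class CnvStateTable:
    """Per-probe, per-patient CNV state with the covering segment id.

    Only probes encompassed by a segment for at least one patient appear;
    all other probes are implicitly normal for every patient.
    """

    states: pd.DataFrame       # probes x patients, values in STATES
    segment_ids: pd.DataFrame  # probes x patients, "" where normal

    @property
    def probes(self) -> pd.Index:
        return self.states.index

    @property
    def patients(self) -> list[str]:
        return list(self.states.columns)


def _merged_trees(cnv: CnvSegmentSet) -> dict[tuple[str, str], IntervalTree]:
    """One interval tree per (patient, chrom); abutting same-state segments
    of a patient are merged so a probe spanning their shared boundary still
    counts as encompassed."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    df = cnv.records.sort_values(["patient", "chrom", "state", "start"])
    for (patient, chrom, state), grp in df.groupby(["patient", "chrom", "state"],
                                                   sort=False):
        merged: list[list] = []
        for _, row in grp.iterrows():
            seg_id = f"{patient}:{chrom}:{row['start']}-{row['end']}"
            if merged and row["start"] == merged[-1][1]:
                merged[-1][1] = row["end"]
                merged[-1][2].append(seg_id)
            else:
                merged.append([row["start"], row["end"], [seg_id]])
        tree = trees.setdefault((patient, chrom), IntervalTree())
        for start, end, ids in merged:
            tree.addi(start, end, (state, "+".join(ids)))
    return trees


def assign_states(probes: ProbeAnnotation, cnv: CnvSegmentSet,
                  patients=None) -> CnvStateTable:
    """Assign each (probe, patient) its CNV state by full encompassment.

    ``patients`` optionally fixes the column set (e.g. all cohort patients,
    including those without any segment); defaults to the patients present
    in the CNV records. Conflicting fully-covering segments of opposite
    state raise :class:`CnvConflictError`.
    """
    probes.validate()
    cnv.validate()
    if patients is None:
        patients = cnv.patients
    patients = list(patients)
    unknown = set(cnv.records["patient"]) - set(patients)
    if unknown:
        raise ValidationError(f"CNV records for patients outside the cohort: "
                              f"{sorted(unknown)}")
    trees = _merged_trees(cnv)

    pt = probes.table
    state = pd.DataFrame(NORMAL, index=pt.index, columns=patients, dtype=object)
    seg = pd.DataFrame("", index=pt.index, columns=patients, dtype=object)
    for probe_id, row in pt.iterrows():
        for patient in patients:
            tree = trees.get((patient, row["chrom"]))
            if tree is None:
                continue
            covering = sorted(
                (iv for iv in tree.overlap(row["start"], row["end"])
                 if iv.begin <= row["start"] and row["end"] <= iv.end),
                key=lambda iv: (iv.begin, iv.end))
            if not covering:
                continue
            found = {iv.data[0] for iv in covering}
            if len(found) > 1:
                records = [f"{patient} {row['chrom']}:{iv.begin}-{iv.end} "
                           f"{iv.data[0]}" for iv in covering]
                raise CnvConflictError(
                    f"probe {probe_id!r} fully covered by segments of "
                    f"opposite state for patient {patient}: {records}")
            iv = covering[0]
            state.loc[probe_id, patient] = iv.data[0]
            seg.loc[probe_id, patient] = iv.data[1]
    keep = (state != NORMAL).any(axis=1)
    return CnvStateTable(state[keep], seg[keep])


def stratified_contrast(differences: pd.DataFrame, states: CnvStateTable,
                        min_patients: int = 3) -> pd.DataFrame:
    """Paired-difference statistics per CNV stratum and pooled, per probe.

    For each probe in the state table: within each state stratum with
    n >= min_patients, the mean paired difference and paired-t p; strata
    below min_patients are flagged untested (statistics still reported where
    computable). Pooled statistics ignore state and use all patients.
    """
    missing = states.probes.difference(differences.index)
    if len(missing):
        raise ValidationError(f"no paired differences for probes "
                              f"{list(missing[:5])}")
    patients = states.patients
    extra = set(patients) - set(differences.columns)
    if extra:
        raise ValidationError(f"no paired differences for patients {sorted(extra)}")
    diffs = differences.loc[states.probes, patients]

    rows = []
    for probe in states.probes:
        d = diffs.loc[probe].to_numpy(dtype=float)
        st = states.states.loc[probe].to_numpy()
        rec: dict = {"probe": probe}
        for s in STATES:
            pre = _PREFIX[s]
            sel = d[st == s]
            n = sel.size
            rec[f"{pre}_n"] = n
            rec[f"{pre}_tested"] = n >= min_patients
            rec[f"{pre}_mean"] = sel.mean() if n else np.nan
            if n >= 2 and np.ptp(sel) > 0:
                t, p, _ = paired_t_test(sel)
            elif n >= 2:
                t, p = np.nan, 1.0
            else:
                t, p = np.nan, np.nan
            rec[f"{pre}_t"] = t
            rec[f"{pre}_p"] = p
        t, p, _ = paired_t_test(d) if np.ptp(d) > 0 else (np.nan, 1.0, True)
        rec.update(pooled_n=d.size, pooled_mean=d.mean(), pooled_t=t,
                   pooled_p=p)
        rows.append(rec)
    columns = ["probe"]
    for pre in ("amp", "del", "norm"):
        columns += [f"{pre}_n", f"{pre}_tested", f"{pre}_mean", f"{pre}_t",
                    f"{pre}_p"]
    columns += ["pooled_n", "pooled_mean", "pooled_t", "pooled_p"]
    return pd.DataFrame(rows, columns=columns).set_index("probe")


def separation_summary(contrast: pd.DataFrame, differences: pd.DataFrame,
                       states: CnvStateTable,
                       min_abs_log2: float = 0.4) -> tuple[pd.DataFrame,
                                                           pd.DataFrame]:
    """Category means of paired differences, separated versus pooled.

    Restricts to CNV strata whose within-stratum mean difference clears
    ``min_abs_log2`` (0.4 log2 = 1.32-fold, the magnitude a single-allele
    dosage shift is expected to approach) and reports four categories:
    ``amp_separated`` and ``del_separated`` (stratified means of the selected
    genes), ``no_separation`` (pooled means of those same genes, i.e. without
    separating patients by CNV), and ``no_cnv`` (pooled means of genes outside
    every CNV). Returns (summary, per-gene detail).
    """
    detail_rows = []
    for s, pre in ((AMPLIFIED, "amp"), (DELETED, "del")):
        sub = contrast[contrast[f"{pre}_tested"]
                       & (contrast[f"{pre}_mean"].abs() >= min_abs_log2)]
        for probe, row in sub.iterrows():
            detail_rows.append((probe, f"{pre}_separated", row[f"{pre}_mean"],
                                row[f"{pre}_n"], row["pooled_mean"]))
    detail = pd.DataFrame(detail_rows, columns=["probe", "category",
                                                "stratum_mean", "stratum_n",
                                                "pooled_mean"])
    if detail.empty:
        warnings.warn("no CNV gene cleared the separation threshold; "
                      "summary is empty")
    no_cnv_probes = differences.index.difference(states.probes)
    no_cnv_means = differences.loc[no_cnv_probes].mean(axis=1)

    rows = []
    for cat in ("amp_separated", "del_separated"):
        vals = detail.loc[detail["category"] == cat, "stratum_mean"]
        rows.append((cat, len(vals), vals.mean() if len(vals) else np.nan))
    pooled = detail.drop_duplicates("probe")["pooled_mean"]
    rows.append(("no_separation", len(pooled),
                 pooled.mean() if len(pooled) else np.nan))
    rows.append(("no_cnv", len(no_cnv_means),
                 no_cnv_means.mean() if len(no_cnv_means) else np.nan))
    summary = pd.DataFrame(rows, columns=["category", "n_genes", "mean_diff"])
    return summary, detail


def aggregate_by_segment(contrast: pd.DataFrame,
                         states: CnvStateTable) -> pd.DataFrame:
    """Segment-level view: mean of the probe-level stratum statistics over
    all probes a segment covers (per state)."""
    rows = []
    for s, pre in ((AMPLIFIED, "amp"), (DELETED, "del")):
        mask = states.states == s
        ids = states.segment_ids.where(mask, "")
        long = ids.stack()
        long = long[long != ""]
        for seg_id, grp in long.groupby(long.values):
            probes = grp.index.get_level_values(0).unique()
            sub = contrast.loc[probes]
            rows.append((seg_id, s, len(probes),
                         sub[f"{pre}_mean"].mean(), sub[f"{pre}_p"].mean()))
    return pd.DataFrame(rows, columns=["segment", "state", "n_probes",
                                       "mean_of_stratum_means",
                                       "mean_of_stratum_p"])
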