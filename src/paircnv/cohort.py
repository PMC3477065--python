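"""Synthetic matched primary/metastasis cohorts with planted CNV dosage effects.

The generator emulates a matched-pair ovarian cancer cohort: for each patient
one primary tumor and one peritoneal metastasis expression profile on the
log2 scale, CNV segments whose metastasis-versus-primary copy difference
multiplicatively scales expression (copy ``c`` against a diploid baseline
shifts log2 expression by ``log2(c/2)``, so a single-allele gain is a
1.5-fold change), patient-specific CNV heterogeneity, metastasis-age
subgroups with decreasing numbers of truly shifted genes (early >> mid >>
late), and a prognostic-direction signal (good-prognosis genes tend up,
poor-prognosis genes tend down in the metastasis).

Every planted signal is recorded in a :class:`GroundTruth` so downstream
stages can be scored against a known answer.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (AMPLIFIED, DELETED, NORMAL, CnvSegmentSet,
                         ExpressionMatrix, PrognosticGeneList, ProbeAnnotation,
                         sample_id, write_cnv_bed, write_expression,
                         write_probe_bed, write_prognostic)

GROUP_NAMES = ("early", "mid", "late")

#: log2 shift assigned to a homozygous (copy 0) deletion instead of -inf
ZERO_COPY_LOG2 = -10.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic matched-pair cohort.

    Defaults describe the reference cohort used throughout the test-suite:
    9 patients in three metastasis-age groups of 3, 2,500 genes on one
    synthetic chromosome, 12 CNV segments of 30 genes each with exactly
    one third of patients amplified (copy 3) and one third deleted (copy 1)
    per segment, Gaussian log2 noise of 0.2, planted group divergence of
    (600, 250, 80) genes at 1 log2 unit, and a 193-gene prognostic panel
    with 80% direction concordance at 0.5 log2 units.
    """

    n_patients: int = 9
    n_genes: int = 2500
    n_segments: int = 12
    genes_per_segment: int = 30
    genome_length: int = 120_000_000
    dosage_base_copy: int = 2
    amplified_copy: int = 3
    deleted_copy: int = 1
    noise_sd: float = 0.2
    frac_amp: float = 1 / 3
    frac_del: float = 1 / 3
    group_sizes: tuple[int, ...] = (3, 3, 3)
    n_de_per_group: tuple[int, ...] = (600, 250, 80)
    de_effect: float = 1.0
    n_prognostic: int = 193
    prognostic_effect: float = 0.5
    concordance_rate: float = 0.8
    baseline_range: tuple[float, float] = (5.0, 12.0)
    probe_length: int = 2000
    chrom: str = "chrS"
    seed: int = 0

    def validate(self) -> "CohortSpec":
        for name in ("n_patients", "n_genes", "n_segments", "genes_per_segment",
                     "genome_length", "probe_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"invariant violated: {name} must be positive")
        if any(g <= 0 for g in self.group_sizes):
            raise ValidationError("invariant violated: group_sizes entries must "
                                  "be positive")
        if sum(self.group_sizes) != self.n_patients:
            raise ValidationError("invariant violated: group_sizes must sum to "
                                  f"n_patients ({sum(self.group_sizes)} != "
                                  f"{self.n_patients})")
        if len(self.group_sizes) != len(self.n_de_per_group):
            raise ValidationError("invariant violated: group_sizes and "
                                  "n_de_per_group must have equal length")
        if len(self.group_sizes) > len(GROUP_NAMES):
            raise ValidationError(f"invariant violated: at most "
                                  f"{len(GROUP_NAMES)} groups are supported")
        if any(n < 0 for n in self.n_de_per_group):
            raise ValidationError("invariant violated: n_de_per_group entries "
                                  "must be non-negative")
        if any(a < b for a, b in zip(self.n_de_per_group,
                                     self.n_de_per_group[1:])):
            raise ValidationError("invariant violated: n_de_per_group must be "
                                  "non-increasing from early to late")
        if not (0 <= self.frac_amp and 0 <= self.frac_del
                and self.frac_amp + self.frac_del <= 1):
            raise ValidationError("invariant violated: frac_amp + frac_del "
                                  "must be <= 1 with both non-negative")
        if self.noise_sd < 0:
            raise ValidationError("invariant violated: noise_sd must be >= 0")
        if not 0 <= self.concordance_rate <= 1:
            raise ValidationError("invariant violated: concordance_rate must "
                                  "be in [0, 1]")
        if self.dosage_base_copy < 1:
            raise ValidationError("invariant violated: dosage_base_copy >= 1")
        if not self.amplified_copy > self.dosage_base_copy:
            raise ValidationError("invariant violated: amplified_copy must "
                                  "exceed dosage_base_copy")
        if not 0 <= self.deleted_copy < self.dosage_base_copy:
            raise ValidationError("invariant violated: deleted_copy must be "
                                  "below dosage_base_copy")
        budget = (self.n_segments * self.genes_per_segment
                  + sum(self.n_de_per_group) + self.n_prognostic)
        if budget > self.n_genes:
            raise ValidationError(f"invariant violated: planted genes ({budget}) "
                                  f"exceed n_genes ({self.n_genes})")
        spacing = self.genome_length // (self.n_genes + 1)
        if self.probe_length >= spacing:
            raise ValidationError("invariant violated: probe_length must be "
                                  "smaller than the inter-gene spacing")
        return self

    @property
    def group_names(self) -> tuple[str, ...]:
        return GROUP_NAMES[:len(self.group_sizes)]


@dataclass
class GroundTruth:
    """Planted signals of a synthetic cohort, the oracle for recovery tests."""

    cnv_state: pd.DataFrame          # probes x patients, {amplified,deleted,normal}
    de_effects: pd.DataFrame         # probe, gene, group, effect (signed log2)
    prognostic: pd.DataFrame         # gene, label, direction (+1/-1), effect
    group_of_patient: pd.Series      # patient -> group name

    def true_de_genes(self, group: str) -> pd.DataFrame:
        return self.de_effects[self.de_effects["group"] == group]


@dataclass
class Cohort:
    spec: CohortSpec
    expression: ExpressionMatrix
    cnv: CnvSegmentSet
    probes: ProbeAnnotation
    truth: GroundTruth

    @property
    def prognostic_list(self) -> PrognosticGeneList:
        labels = pd.Series(self.truth.prognostic["label"].to_numpy(),
                           index=pd.Index(self.truth.prognostic["gene"],
                                          name="gene"), name="label")
        return PrognosticGeneList(labels).validate()


def dosage_log2_shift(copy_number: int, base_copy: int = 2) -> float:
    """log2 expression shift of copy ``c`` against the diploid baseline.

    Copy 0 is capped at :data:`ZERO_COPY_LOG2` instead of -inf.
    """
    if copy_number == 0:
        return ZERO_COPY_LOG2
    return math.log2(copy_number / base_copy)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a matched-pair cohort with planted dosage, group and
    prognostic effects. Deterministic for a fixed ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    patients = [f"OV{i + 1:02d}" for i in range(spec.n_patients)]
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    probe_ids = [f"PS{i:04d}_at" for i in range(spec.n_genes)]

    # probe layout: evenly spaced on one synthetic chromosome
    spacing = spec.genome_length // (spec.n_genes + 1)
    starts = (np.arange(spec.n_genes) + 1) * spacing
    probes = ProbeAnnotation(pd.DataFrame(
        {"chrom": spec.chrom, "start": starts,
         "end": starts + spec.probe_length, "gene": genes},
        index=pd.Index(probe_ids, name="probe_id"))).validate()

    # metastasis-age groups, patient-major
    group_of_patient = pd.Series(
        np.repeat(list(spec.group_names), list(spec.group_sizes)),
        index=pd.Index(patients, name="patient"), name="group")

    # ---- CNV segments: disjoint runs of consecutive genes ------------------
    taken = np.zeros(spec.n_genes, dtype=bool)
    seg_first: list[int] = []
    gps = spec.genes_per_segment
    while len(seg_first) < spec.n_segments:
        cand = int(rng.integers(0, spec.n_genes - gps + 1))
        lo = max(cand - 1, 0)
        hi = min(cand + gps + 1, spec.n_genes)  # keep a one-gene gap
        if not taken[lo:hi].any():
            taken[cand:cand + gps] = True
            seg_first.append(cand)
    seg_first.sort()

    n_amp = round(spec.frac_amp * spec.n_patients)
    n_del = round(spec.frac_del * spec.n_patients)
    margin = spacing // 4
    cnv_rows = []
    dosage = np.zeros((spec.n_genes, spec.n_patients))
    state = np.full((spec.n_genes, spec.n_patients), NORMAL, dtype=object)
    for si, first in enumerate(seg_first):
        gene_idx = np.arange(first, first + gps)
        seg_start = int(starts[first] - margin)
        seg_end = int(starts[gene_idx[-1]] + spec.probe_length + margin)
        perm = rng.permutation(spec.n_patients)
        for pi in perm[:n_amp]:
            cnv_rows.append((patients[pi], spec.chrom, seg_start, seg_end,
                             spec.amplified_copy, AMPLIFIED))
            state[gene_idx, pi] = AMPLIFIED
            dosage[gene_idx, pi] = dosage_log2_shift(spec.amplified_copy,
                                                     spec.dosage_base_copy)
        for pi in perm[n_amp:n_amp + n_del]:
            cnv_rows.append((patients[pi], spec.chrom, seg_start, seg_end,
                             spec.deleted_copy, DELETED))
            state[gene_idx, pi] = DELETED
            dosage[gene_idx, pi] = dosage_log2_shift(spec.deleted_copy,
                                                     spec.dosage_base_copy)
    cnv = CnvSegmentSet(pd.DataFrame(
        cnv_rows, columns=list(CnvSegmentSet.COLUMNS))).validate()
    cnv_gene_mask = taken

    # ---- planted prognostic panel and per-group divergent genes ------------
    free = np.flatnonzero(~cnv_gene_mask)
    free = rng.permutation(free)
    cursor = 0

    prog_idx = free[cursor:cursor + spec.n_prognostic]
    cursor += spec.n_prognostic
    n_good = spec.n_prognostic // 2 + spec.n_prognostic % 2
    prog_labels = np.array(["good"] * n_good
                           + ["poor"] * (spec.n_prognostic - n_good))
    rng.shuffle(prog_labels)
    concordant = rng.random(spec.n_prognostic) < spec.concordance_rate
    prog_dir = np.where((prog_labels == "good") == concordant, 1, -1)
    prog_shift = np.zeros(spec.n_genes)
    prog_shift[prog_idx] = prog_dir * spec.prognostic_effect
    prognostic = pd.DataFrame({
        "gene": [genes[i] for i in prog_idx],
        "label": prog_labels,
        "direction": prog_dir,
        "effect": prog_dir * spec.prognostic_effect,
    })

    de_rows = []
    de_shift = np.zeros((spec.n_genes, spec.n_patients))
    pat_group = np.repeat(np.arange(len(spec.group_sizes)),
                          list(spec.group_sizes))
    for gi, (gname, nde) in enumerate(zip(spec.group_names,
                                          spec.n_de_per_group)):
        idx = free[cursor:cursor + nde]
        cursor += nde
        signs = rng.choice([-1.0, 1.0], size=nde)
        members = np.flatnonzero(pat_group == gi)
        for g, s in zip(idx, signs):
            de_shift[g, members] = s * spec.de_effect
            de_rows.append((probe_ids[g], genes[g], gname, s * spec.de_effect))
    de_effects = pd.DataFrame(de_rows,
                              columns=["probe", "gene", "group", "effect"])

    # ---- expression: baseline + planted shifts + Gaussian log2 noise -------
    baseline = rng.uniform(*spec.baseline_range, spec.n_genes)
    sample_ids, meta_rows = [], []
    values = np.empty((spec.n_genes, 2 * spec.n_patients))
    for pi, patient in enumerate(patients):
        mu_primary = baseline
        mu_met = baseline + dosage[:, pi] + de_shift[:, pi] + prog_shift
        for tissue, mu in (("primary", mu_primary), ("metastasis", mu_met)):
            col = len(sample_ids)
            noise = (rng.normal(0.0, spec.noise_sd, spec.n_genes)
                     if spec.noise_sd > 0 else 0.0)
            values[:, col] = mu + noise
            sid = sample_id(patient, tissue)
            sample_ids.append(sid)
            meta_rows.append((patient, tissue))

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                     columns=sample_ids),
        pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample"),
                     columns=["patient", "tissue"])).validate()

    encompassed = cnv_gene_mask
    truth = GroundTruth(
        cnv_state=pd.DataFrame(state[encompassed],
                               index=pd.Index(np.array(probe_ids)[encompassed],
                                              name="probe_id"),
                               columns=patients),
        de_effects=de_effects,
        prognostic=prognostic,
        group_of_patient=group_of_patient,
    )
    return Cohort(spec, expr, cnv, probes, truth)


# ---------------------------------------------------------------------------
# fixture files

FIXTURE_FILES = ("expression.tsv", "cnv_segments.bed", "probes.bed",
                 "ground_truth.tsv", "prognostic.tsv")


def write_fixture(dir_path, cohort: Cohort) -> dict:
    """Write a cohort as its five on-disk artifacts plus a JSON manifest.

    Files: expression TSV, CNV BED, probe BED, ground-truth TSV (long form)
    and the prognostic gene list. Returns the manifest dict, which echoes the
    spec and seed.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, d / "expression.tsv")
    write_cnv_bed(cohort.cnv, d / "cnv_segments.bed")
    write_probe_bed(cohort.probes, d / "probes.bed")
    _write_ground_truth(cohort.truth, d / "ground_truth.tsv")
    write_prognostic(cohort.prognostic_list, d / "prognostic.tsv")
    manifest = {
        "seed": cohort.spec.seed,
        "spec": dataclasses.asdict(cohort.spec),
        "files": list(FIXTURE_FILES),
    }
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _write_ground_truth(truth: GroundTruth, path) -> None:
    rows = []
    for probe, row in truth.cnv_state.iterrows():
        for patient, st in row.items():
            if st != NORMAL:
                rows.append(("cnv_state", probe, patient, st))
    for _, r in truth.de_effects.iterrows():
        rows.append(("de_gene", r["probe"], r["group"], repr(float(r["effect"]))))
    for _, r in truth.prognostic.iterrows():
        rows.append(("prognostic", r["gene"], r["label"], str(int(r["direction"]))))
    for patient, group in truth.group_of_patient.items():
        rows.append(("patient_group", patient, group, ""))
    pd.DataFrame(rows, columns=["record", "key", "subkey", "value"]).to_csv(
        path, sep="\t", index=False)


def read_ground_truth(path, cnv_probes=None, patients=None) -> GroundTruth:
    """Reconstruct a :class:`GroundTruth` written by :func:`write_fixture`.

    ``cnv_probes`` and ``patients`` fix the state-table axes; when omitted
    they are inferred from the recorded non-normal states.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    st = df[df["record"] == "cnv_state"]
    if patients is None:
        patients = sorted(st["subkey"].unique())
    if cnv_probes is None:
        cnv_probes = sorted(st["key"].unique())
    state = pd.DataFrame(NORMAL, index=pd.Index(cnv_probes, name="probe_id"),
                         columns=list(patients), dtype=object)
    for _, r in st.iterrows():
        state.loc[r["key"], r["subkey"]] = r["value"]
    de = df[df["record"] == "de_gene"]
    de_effects = pd.DataFrame({
        "probe": de["key"].to_numpy(),
        "gene": [p.replace("PS", "G").replace("_at", "") for p in de["key"]],
        "group": de["subkey"].to_numpy(),
        "effect": [float(v) for v in de["value"]],
    })
    pr = df[df["record"] == "prognostic"]
    prognostic = pd.DataFrame({
        "gene": pr["key"].to_numpy(), "label": pr["subkey"].to_numpy(),
        "direction": [int(v) for v in pr["value"]],
        "effect": np.nan,
    })
    pg = df[df["record"] == "patient_group"]
    group_of_patient = pd.Series(pg["subkey"].to_numpy(),
                                 index=pd.Index(pg["key"], name="patient"),
                                 name="group")
    return GroundTruth(state, de_effects, prognostic, group_of_patient)
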