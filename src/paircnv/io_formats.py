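"""Readers and writers for every on-disk format the pipeline touches.

All genomic intervals are BED-convention 0-based half-open. Strand is ignored
throughout: copy-number dosage acts on expression irrespective of strand.
Sample identifiers encode patient and tissue as ``<PATIENT>_Ov`` (primary
ovarian tumor) and ``<PATIENT>_Pe`` (peritoneal metastasis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, PairingError, ValidationError

TISSUE_CODES = {"Ov": "primary", "Pe": "metastasis"}
CODE_OF_TISSUE = {v: k for k, v in TISSUE_CODES.items()}

AMPLIFIED = "amplified"
DELETED = "deleted"
NORMAL = "normal"

_FLOAT_FMT = "%.10g"


def sample_id(patient: str, tissue: str) -> str:
    """Canonical sample identifier for a patient/tissue combination."""
    try:
        return f"{patient}_{CODE_OF_TISSUE[tissue]}"
    except KeyError:
        raise ValidationError(f"unknown tissue {tissue!r}; expected one of "
                              f"{sorted(CODE_OF_TISSUE)}") from None


def parse_sample_id(sid: str, *, path=None, line=None) -> tuple[str, str]:
    """Split ``PATIENT_Ov``/``PATIENT_Pe`` into (patient, tissue)."""
    patient, sep, code = sid.rpartition("_")
    if not sep or code not in TISSUE_CODES or not patient:
        raise ParseError(
            f"sample id {sid!r} does not match <PATIENT>_Ov or <PATIENT>_Pe",
            path=path, line=line)
    return patient, TISSUE_CODES[code]


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression, probe sets x samples, with sample metadata.

    ``values`` is indexed by probe id with one column per sample id;
    ``sample_meta`` is indexed by sample id with columns ``patient`` and
    ``tissue`` (``primary`` or ``metastasis``).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def validate(self) -> "ExpressionMatrix":
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate probe IDs: {list(dups[:5])}")
        if not np.isfinite(self.values.to_numpy()).all():
            bad = self.values.index[~np.isfinite(self.values).all(axis=1)]
            raise ValidationError(f"non-finite expression values at probes "
                                  f"{list(bad[:5])}")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValidationError("sample columns and sample_meta disagree")
        bad_tissue = set(self.sample_meta["tissue"]) - set(TISSUE_CODES.values())
        if bad_tissue:
            raise ValidationError(f"unknown tissue labels: {sorted(bad_tissue)}")
        return self

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["patient"]))

    def samples_of(self, tissue: str) -> pd.DataFrame:
        return self.sample_meta[self.sample_meta["tissue"] == tissue]

    def require_paired(self) -> list[str]:
        """Return patients, erroring unless each has exactly one sample per tissue."""
        counts = self.sample_meta.groupby(["patient", "tissue"]).size()
        bad = []
        for p in self.patients:
            for t in ("primary", "metastasis"):
                if counts.get((p, t), 0) != 1:
                    bad.append(p)
                    break
        if bad:
            raise PairingError(f"patients without exactly one primary and one "
                               f"metastasis sample: {bad}")
        return self.patients

    def subset_patients(self, patients) -> "ExpressionMatrix":
        keep = self.sample_meta["patient"].isin(list(patients))
        meta = self.sample_meta[keep]
        return ExpressionMatrix(self.values[meta.index], meta.copy())


@dataclass
class CnvSegmentSet:
    """Per-patient CNV segments; normal copy state is the absence of a record.

    The state of a record is the sign of the metastasis-versus-primary copy
    difference: a gain in the metastasis is ``amplified``, a loss ``deleted``.
    """

    records: pd.DataFrame  # patient, chrom, start, end, copy_number, state

    COLUMNS = ("patient", "chrom", "start", "end", "copy_number", "state")

    def validate(self) -> "CnvSegmentSet":
        df = self.records
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"CNV records missing columns {sorted(missing)}")
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValidationError(f"CNV segment with start >= end at row {bad}")
        if (df["copy_number"] == 2).any():
            raise ValidationError("copy_number 2 records are not allowed; "
                                  "normal state is the absence of a record")
        amp_ok = (df["state"] != AMPLIFIED) | (df["copy_number"] > 2)
        del_ok = (df["state"] != DELETED) | (df["copy_number"] < 2)
        known = df["state"].isin([AMPLIFIED, DELETED])
        if not (amp_ok & del_ok & known).all():
            bad = df[~(amp_ok & del_ok & known)]
            raise ValidationError(
                f"state inconsistent with copy_number at rows {list(bad.index[:5])}")
        return self

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.records["patient"]))


@dataclass
class ProbeAnnotation:
    """Genomic coordinates and gene symbol for every probe set."""

    table: pd.DataFrame  # index probe_id; chrom, start, end, gene

    def validate(self) -> "ProbeAnnotation":
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique()
            raise ValidationError(f"duplicate probe IDs: {list(dups[:5])}")
        if (self.table["start"] >= self.table["end"]).any():
            bad = self.table.index[self.table["start"] >= self.table["end"]][0]
            raise ValidationError(f"probe {bad!r} has start >= end")
        return self

    def gene_of(self) -> pd.Series:
        return self.table["gene"]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> member gene symbols."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def validate(self) -> "GeneSetCollection":
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if any((not isinstance(m, str)) or not m for m in members):
                raise ValidationError(f"gene set {name!r} has empty member symbols")
        return self

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PrognosticGeneList:
    """Gene symbol -> prognosis label (``good`` or ``poor``)."""

    labels: pd.Series  # index gene, values in {good, poor}

    def validate(self) -> "PrognosticGeneList":
        if self.labels.index.duplicated().any():
            dups = self.labels.index[self.labels.index.duplicated()].unique()
            raise ValidationError(f"duplicate prognostic genes: {list(dups[:5])}")
        bad = set(self.labels.unique()) - {"good", "poor"}
        if bad:
            raise ValidationError(f"prognostic labels must be good/poor, got {sorted(bad)}")
        return self


# ---------------------------------------------------------------------------
# Expression TSV

def read_expression(path) -> ExpressionMatrix:
    """Read a tab-separated probe x sample log2 expression matrix.

    First column is ``probe_id``; remaining header fields are sample IDs in
    the ``<PATIENT>_Ov`` / ``<PATIENT>_Pe`` convention.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        line = int(np.where(df.index == dup)[0][-1]) + 2
        raise ParseError(f"duplicate probe ID {dup!r}", path=path, line=line)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            row = int(np.where(coerced.isna() & df[col].notna())[0][0])
            raise ParseError(f"non-numeric expression value {df[col].iloc[row]!r} "
                             f"in sample {col!r}", path=path, line=row + 2)
    meta = pd.DataFrame(
        [parse_sample_id(s, path=path, line=1) for s in df.columns],
        index=pd.Index(df.columns, name="sample"),
        columns=["patient", "tissue"],
    )
    return ExpressionMatrix(df.astype(float), meta).validate()


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.rename_axis("probe_id").to_csv(path, sep="\t",
                                               float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# BED-like files

def read_cnv_bed(path) -> CnvSegmentSet:
    """Read CNV segment calls: chrom, start, end, patient, copy_number, state."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "patient", "copy_number",
                            "state"],
                     dtype={"chrom": str, "patient": str, "state": str})
    for i, row in df.iterrows():
        line = int(i) + 1
        try:
            start, end = int(row["start"]), int(row["end"])
            copy = int(row["copy_number"])
        except (TypeError, ValueError):
            raise ParseError("malformed coordinates or copy number",
                             path=path, line=line) from None
        if start >= end:
            raise ParseError(f"start {start} >= end {end}", path=path, line=line)
        if copy == 2:
            raise ParseError("copy_number 2 is not a CNV record", path=path,
                             line=line)
        if row["state"] not in (AMPLIFIED, DELETED):
            raise ParseError(f"unknown CNV state {row['state']!r}", path=path,
                             line=line)
        if (row["state"] == AMPLIFIED) != (copy > 2):
            raise ParseError(f"state {row['state']!r} inconsistent with "
                             f"copy_number {copy}", path=path, line=line)
    df = df.astype({"start": int, "end": int, "copy_number": int})
    return CnvSegmentSet(df[["patient", "chrom", "start", "end",
                             "copy_number", "state"]]).validate()


def write_cnv_bed(cnv: CnvSegmentSet, path) -> None:
    out = cnv.records[["chrom", "start", "end", "patient", "copy_number",
                       "state"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_probe_bed(path) -> ProbeAnnotation:
    """Read probe coordinates: chrom, start, end, name where name=probe_id;gene."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str, "name": str})
    probe_ids, genes = [], []
    for i, row in df.iterrows():
        line = int(i) + 1
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError):
            raise ParseError("malformed coordinates", path=path,
                             line=line) from None
        if start >= end:
            raise ParseError(f"start {start} >= end {end}", path=path, line=line)
        pid, sep, gene = str(row["name"]).partition(";")
        if not sep or not pid or not gene:
            raise ParseError(f"probe name {row['name']!r} is not 'probe_id;gene'",
                             path=path, line=line)
        probe_ids.append(pid)
        genes.append(gene)
    table = pd.DataFrame({"chrom": df["chrom"].astype(str).to_numpy(),
                          "start": df["start"].astype(int).to_numpy(),
                          "end": df["end"].astype(int).to_numpy(),
                          "gene": genes},
                         index=pd.Index(probe_ids, name="probe_id"))
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        line = int(np.where(table.index == dup)[0][-1]) + 1
        raise ParseError(f"duplicate probe ID {dup!r}", path=path, line=line)
    return ProbeAnnotation(table).validate()


def write_probe_bed(probes: ProbeAnnotation, path) -> None:
    t = probes.table
    out = pd.DataFrame({"chrom": t["chrom"], "start": t["start"],
                        "end": t["end"],
                        "name": [f"{p};{g}" for p, g in zip(t.index, t["gene"])]})
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) < 3:
                raise ParseError("GMT line needs name, description and at "
                                 "least one member", path=path, line=lineno)
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"gene set {name!r} is empty", path=path,
                                 line=lineno)
            if name in sets:
                raise ParseError(f"duplicate gene set {name!r}", path=path,
                                 line=lineno)
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions).validate()


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Prognostic gene list

def read_prognostic(path) -> PrognosticGeneList:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene", "label"]:
        raise ParseError("prognostic TSV must have header 'gene\\tlabel'",
                         path=path, line=1)
    for i, label in enumerate(df["label"]):
        if label not in ("good", "poor"):
            raise ParseError(f"label {label!r} is not good/poor", path=path,
                             line=i + 2)
    labels = pd.Series(df["label"].to_numpy(),
                       index=pd.Index(df["gene"], name="gene"), name="label")
    if labels.index.duplicated().any():
        dup = labels.index[labels.index.duplicated()][0]
        raise ParseError(f"duplicate prognostic gene {dup!r}", path=path)
    return PrognosticGeneList(labels).validate()


def write_prognostic(prog: PrognosticGeneList, path) -> None:
    prog.labels.rename_axis("gene").to_frame().to_csv(path, sep="\t")
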