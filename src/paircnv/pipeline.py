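"""End-to-end orchestration: cohort -> DE -> CNV -> PCA -> prognosis -> enrichment.

A run is described by a flat :class:`RunConfig`; every stage writes its TSV
outputs under the run directory and records row counts in a JSON manifest.
All randomness flows from the single top-level seed, fanned out per stage,
so a rerun with the same configuration is bit-identical apart from the
manifest timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, generate_cohort, write_fixture
from .cnv_integration import (aggregate_by_segment, assign_states,
                              separation_summary, stratified_contrast)
from .enrichment import enrich, make_synthetic_collection
from .errors import PairCnvError, ValidationError
from .io_formats import (read_cnv_bed, read_expression, read_gmt,
                         read_probe_bed, read_prognostic, write_gmt)
from .paired_de import DeThresholds, call_de, de_table, group_de, \
    paired_differences
from .paired_pca import (assign_groups, divergence_per_patient, name_groups,
                         pca_of_differences)
from .prognostic import CELLS, classify_directions, concordance_test

STAGES = ("de", "cnv", "pca", "group_de", "prognosis", "enrich")


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    synthetic: bool = True
    # input paths (required when synthetic=False)
    expression_path: str | None = None
    cnv_path: str | None = None
    probe_path: str | None = None
    prognostic_path: str | None = None
    gmt_path: str | None = None
    # thresholds
    min_abs_fold: float = 1.5
    max_p: float = 0.01
    alt_fold: float = 2.0
    alt_fdr: float = 0.2
    min_patients: int = 3
    min_abs_log2: float = 0.4
    detect_percentile: float = 5.0
    enrich_q: float = 0.25
    k_groups: int = 3
    stages: tuple[str, ...] = STAGES
    cohort: CohortSpec | None = None  # synthetic-mode override

    def validate(self) -> "RunConfig":
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}")
        self.thresholds.validate()
        if not self.synthetic:
            for name in ("expression_path", "cnv_path", "probe_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValidationError(f"{name} is required when "
                                          "synthetic=False")
                if not Path(p).exists():
                    raise ValidationError(f"{name} does not exist: {p}")
        return self

    @property
    def thresholds(self) -> DeThresholds:
        return DeThresholds(self.min_abs_fold, self.max_p, self.alt_fold,
                            self.alt_fdr)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "cohort"},
        "stages": {},
        "input_hashes": {},
    }
    truth = None
    current = None  # name of the stage being run, for error reporting
    try:
        # ---- input load / simulate (not itself a counted stage) ----------
        if config.synthetic:
            spec = config.cohort or CohortSpec(seed=config.seed)
            cohort = generate_cohort(spec)
            write_fixture(out / "cohort", cohort)
            expr, cnv, probes = cohort.expression, cohort.cnv, cohort.probes
            prognostic = cohort.prognostic_list
            truth = cohort.truth
        else:
            expr = read_expression(config.expression_path)
            cnv = read_cnv_bed(config.cnv_path)
            probes = read_probe_bed(config.probe_path)
            prognostic = (read_prognostic(config.prognostic_path)
                          if config.prognostic_path else None)
            for name in ("expression_path", "cnv_path", "probe_path",
                         "prognostic_path", "gmt_path"):
                p = getattr(config, name)
                if p:
                    manifest["input_hashes"][name] = _hash_file(p)
        gene_of = probes.gene_of()
        diffs = paired_differences(expr)
        de_calls = None
        groups = None

        if "de" in config.stages:
            current = "de"
            table = de_table(diffs)
            de_calls = call_de(table, config.thresholds, mode="global")
            de_out = table.join(gene_of.rename("gene")) \
                          .rename_axis("probe_id")
            de_out.to_csv(out / "paired_de.tsv", sep="\t")
            de_calls.join(gene_of.rename("gene")).rename_axis("probe_id") \
                    .to_csv(out / "paired_de_calls.tsv", sep="\t")
            _mark(manifest, "de", rows=len(table),
                  outputs=["paired_de.tsv", "paired_de_calls.tsv"],
                  called=len(de_calls))

        if "cnv" in config.stages:
            current = "cnv"
            states = assign_states(probes, cnv, patients=expr.patients)
            contrast = stratified_contrast(diffs, states,
                                           config.min_patients)
            summary, detail = separation_summary(contrast, diffs, states,
                                                 config.min_abs_log2)
            segments = aggregate_by_segment(contrast, states)
            states.states.rename_axis("probe_id") \
                  .to_csv(out / "cnv_states.tsv", sep="\t")
            contrast.to_csv(out / "cnv_contrast.tsv", sep="\t")
            summary.to_csv(out / "cnv_separation_summary.tsv", sep="\t",
                           index=False)
            segments.to_csv(out / "cnv_segment_summary.tsv", sep="\t",
                            index=False)
            _mark(manifest, "cnv", rows=len(contrast),
                  outputs=["cnv_states.tsv", "cnv_contrast.tsv",
                           "cnv_separation_summary.tsv",
                           "cnv_segment_summary.tsv"])

        if "pca" in config.stages:
            current = "pca"
            pca = pca_of_differences(diffs, n_components=min(3,
                                                             len(expr.patients)))
            assignment = assign_groups(pca.scores, k=config.k_groups,
                                       seed=config.seed)
            groups = name_groups(assignment,
                                 divergence_per_patient(diffs))
            scores = pca.scores.copy()
            scores["group"] = groups
            scores.to_csv(out / "pca_scores.tsv", sep="\t")
            groups.rename_axis("patient").to_frame() \
                  .to_csv(out / "pca_groups.tsv", sep="\t")
            _mark(manifest, "pca", rows=len(scores),
                  outputs=["pca_scores.tsv", "pca_groups.tsv"],
                  explained=[round(float(v), 4)
                             for v in pca.explained_variance_ratio],
                  degenerate=assignment.degenerate)

        if "group_de" in config.stages:
            current = "group_de"
            if groups is None:
                raise ValidationError("group_de requires the pca stage")
            per_group = group_de(expr, groups, config.thresholds,
                                 mode="group")
            counts = {}
            for gname, res in per_group.items():
                res["calls"].join(gene_of.rename("gene")) \
                    .rename_axis("probe_id") \
                    .to_csv(out / f"group_de_{gname}.tsv", sep="\t")
                counts[gname] = {
                    "up": int((res["calls"]["direction"] == "up").sum()),
                    "down": int((res["calls"]["direction"] == "down").sum()),
                }
            _mark(manifest, "group_de", rows=sum(len(r["calls"])
                                                 for r in per_group.values()),
                  outputs=[f"group_de_{g}.tsv" for g in per_group],
                  calls=counts)

        if "prognosis" in config.stages:
            current = "prognosis"
            if prognostic is None:
                raise ValidationError("prognosis stage requires a prognostic "
                                      "gene list")
            table = classify_directions(expr, probes, prognostic,
                                        detect_percentile=config.detect_percentile)
            chi2, dof, p = concordance_test(table, "gof4")
            table.directions.to_csv(out / "prognostic_directions.tsv",
                                    sep="\t", index=False)
            pd.DataFrame([{**table.counts, "chi2": chi2, "dof": dof, "p": p,
                           "concordant_fraction": table.concordant_fraction}]
                         ).to_csv(out / "prognostic_concordance.tsv",
                                  sep="\t", index=False)
            _mark(manifest, "prognosis", rows=table.n_classified,
                  outputs=["prognostic_directions.tsv",
                           "prognostic_concordance.tsv"],
                  chi2=round(chi2, 3), dof=dof, p=float(p))

        if "enrich" in config.stages:
            current = "enrich"
            if de_calls is None:
                raise ValidationError("enrich stage requires the de stage")
            background = sorted(set(gene_of))
            de_genes = sorted(set(gene_of.reindex(de_calls.index)))
            if config.gmt_path:
                collection = read_gmt(config.gmt_path)
            elif truth is not None:
                planted = {g: list(truth.true_de_genes(g)["gene"])
                           for g in dict.fromkeys(truth.de_effects["group"])}
                planted["prognostic_panel"] = list(truth.prognostic["gene"])
                collection = make_synthetic_collection(
                    background, np.random.default_rng(config.seed + 1),
                    planted=planted)
                write_gmt(collection, out / "gene_sets.gmt")
            else:
                raise ValidationError("enrich stage requires a GMT file when "
                                      "no synthetic ground truth is available")
            result = enrich(de_genes, background, collection)
            result.to_csv(out / "enrichment.tsv", sep="\t")
            _mark(manifest, "enrich", rows=len(result),
                  outputs=["enrichment.tsv"],
                  significant=int((result["bh_q"] < config.enrich_q).sum()))
    except PairCnvError as exc:
        if current is not None:
            manifest["stages"][current] = {"status": "failed",
                                           "error": str(exc)}
            _write_manifest(manifest, out)
            raise PairCnvError(f"stage {current!r} failed: {exc}") from exc
        raise
    _write_manifest(manifest, out)
    return manifest


def _mark(manifest: dict, stage: str, **info) -> None:
    manifest["stages"][stage] = {"status": "complete", **info}


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
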