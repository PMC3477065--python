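"""Encompassment mapping, stratified contrasts, attenuation by averaging."""

import numpy as np
import pandas as pd
import pytest

from paircnv import CnvConflictError, CohortSpec, generate_cohort
from paircnv.cnv_integration import (CnvStateTable, aggregate_by_segment,
                                     assign_states, separation_summary,
                                     stratified_contrast)
from paircnv.io_formats import CnvSegmentSet, ProbeAnnotation
from paircnv.paired_de import paired_differences


def _probes(rows):
    return ProbeAnnotation(pd.DataFrame(
        [r[1:] for r in rows], columns=["chrom", "start", "end", "gene"],
        index=pd.Index([r[0] for r in rows], name="probe_id"))).validate()


def _cnv(rows):
    return CnvSegmentSet(pd.DataFrame(
        rows, columns=list(CnvSegmentSet.COLUMNS))).validate()


class TestAssignStates:
    def test_full_encompassment_required(self):
        probes = _probes([("inside", "chr1", 100, 200, "G1"),
                          ("straddles", "chr1", 40, 200, "G2")])
        cnv = _cnv([("P1", "chr1", 50, 500, 3, "amplified")])
        table = assign_states(probes, cnv, patients=["P1", "P2"])
        assert table.states.loc["inside", "P1"] == "amplified"
        assert table.states.loc["inside", "P2"] == "normal"
        # overlapping-but-not-contained probe never enters the table
        assert "straddles" not in table.states.index

    def test_abutting_same_state_segments_form_a_union(self):
        probes = _probes([("spanning", "chr1", 180, 260, "G1"),
                          ("gapped", "chr1", 580, 660, "G2")])
        cnv = _cnv([("P1", "chr1", 100, 200, 3, "amplified"),
                    ("P1", "chr1", 200, 300, 3, "amplified"),
                    ("P1", "chr1", 500, 600, 3, "amplified"),
                    ("P1", "chr1", 610, 700, 3, "amplified")])
        table = assign_states(probes, cnv, patients=["P1"])
        assert table.states.loc["spanning", "P1"] == "amplified"
        assert "gapped" not in table.states.index  # segments do not abut

    def test_conflicting_covering_states_raise(self):
        probes = _probes([("p", "chr1", 100, 200, "G1")])
        cnv = _cnv([("P1", "chr1", 50, 500, 3, "amplified"),
                    ("P1", "chr1", 80, 300, 1, "deleted")])
        with pytest.raises(CnvConflictError, match="P1"):
            assign_states(probes, cnv, patients=["P1"])

    def test_record_order_is_irrelevant(self, small_cohort):
        patients = small_cohort.expression.patients
        base = assign_states(small_cohort.probes, small_cohort.cnv,
                             patients=patients)
        rng = np.random.default_rng(2)
        shuffled = CnvSegmentSet(small_cohort.cnv.records
                                 .sample(frac=1, random_state=3)
                                 .reset_index(drop=True))
        again = assign_states(small_cohort.probes, shuffled,
                              patients=patients)
        assert base.states.equals(again.states)

    def test_recovers_generator_ground_truth(self, default_cohort):
        table = assign_states(default_cohort.probes, default_cohort.cnv,
                              patients=default_cohort.expression.patients)
        assert table.states.sort_index().equals(
            default_cohort.truth.cnv_state.sort_index())


class TestStratifiedContrast:
    def test_understaffed_stratum_flagged_untested(self):
        states = CnvStateTable(
            states=pd.DataFrame([["amplified", "amplified", "normal",
                                  "normal", "normal"]], index=["p"],
                                columns=list("ABCDE")),
            segment_ids=pd.DataFrame([["s", "s", "", "", ""]], index=["p"],
                                     columns=list("ABCDE")))
        diffs = pd.DataFrame([[0.5, 0.7, 0.0, 0.1, -0.1]], index=["p"],
                             columns=list("ABCDE"))
        contrast = stratified_contrast(diffs, states, min_patients=3)
        assert not contrast.loc["p", "amp_tested"]
        assert contrast.loc["p", "norm_tested"]
        assert contrast.loc["p", "amp_n"] == 2

    def test_noise_free_amplified_stratum_hits_dosage_mean(self):
        cohort = generate_cohort(CohortSpec(seed=2, noise_sd=0.0, n_genes=300,
                                            n_segments=2, genes_per_segment=10,
                                            n_de_per_group=(20, 10, 5),
                                            n_prognostic=10))
        diffs = paired_differences(cohort.expression)
        states = assign_states(cohort.probes, cohort.cnv,
                               patients=cohort.expression.patients)
        contrast = stratified_contrast(diffs, states)
        assert np.allclose(contrast["amp_mean"], np.log2(1.5), atol=1e-12)
        assert np.allclose(contrast["del_mean"], -1.0, atol=1e-12)

    def test_attenuation_identity_on_random_genes(self):
        """The pooled mean equals the n-weighted average of stratum means,
        exactly, on 1,000 random genes with random stratifications."""
        rng = np.random.default_rng(9)
        n_genes, patients = 1000, list("ABCDEFGHI")
        diffs = pd.DataFrame(rng.normal(0, 1, (n_genes, 9)),
                             index=[f"p{i}" for i in range(n_genes)],
                             columns=patients)
        st = rng.choice(["amplified", "deleted", "normal"], (n_genes, 9),
                        p=[0.3, 0.3, 0.4])
        st[rng.random(n_genes) < 0.1, :] = "normal"
        st[:, 0][st[:, 0] == "normal"] = "amplified"  # keep every probe in table
        states = CnvStateTable(
            states=pd.DataFrame(st, index=diffs.index, columns=patients),
            segment_ids=pd.DataFrame("", index=diffs.index, columns=patients))
        contrast = stratified_contrast(diffs, states, min_patients=1)
        weighted = (
            contrast["amp_mean"].fillna(0) * contrast["amp_n"]
            + contrast["del_mean"].fillna(0) * contrast["del_n"]
            + contrast["norm_mean"].fillna(0) * contrast["norm_n"]
        ) / contrast["pooled_n"]
        assert np.abs(weighted - contrast["pooled_mean"]).max() < 1e-12


class TestSeparationSummary:
    def test_pooling_attenuates_below_selection(self):
        """3 amplified patients at +0.585 pooled with 6 normal at 0 average
        to 0.195 — below the 0.4 log2 selection."""
        patients = list("ABCDEFGHI")
        row = [0.585] * 3 + [0.0] * 6
        diffs = pd.DataFrame([row], index=["p"], columns=patients)
        states = CnvStateTable(
            states=pd.DataFrame([["amplified"] * 3 + ["normal"] * 6],
                                index=["p"], columns=patients),
            segment_ids=pd.DataFrame([["s"] * 3 + [""] * 6], index=["p"],
                                     columns=patients))
        contrast = stratified_contrast(diffs, states)
        assert contrast.loc["p", "pooled_mean"] == pytest.approx(0.195)
        summary, detail = separation_summary(contrast, diffs, states,
                                             min_abs_log2=0.4)
        assert detail.loc[0, "category"] == "amp_separated"
        assert detail.loc[0, "pooled_mean"] < 0.4  # attenuated to exclusion

    def test_threshold_zero_selects_every_cnv_gene(self, small_cohort):
        diffs = paired_differences(small_cohort.expression)
        states = assign_states(small_cohort.probes, small_cohort.cnv,
                               patients=small_cohort.expression.patients)
        contrast = stratified_contrast(diffs, states)
        _, detail = separation_summary(contrast, diffs, states,
                                       min_abs_log2=0.0)
        assert set(detail["probe"]) == set(states.probes)

    def test_empty_selection_warns(self):
        patients = list("ABC")
        diffs = pd.DataFrame([[0.01, 0.0, 0.02]], index=["p"],
                             columns=patients)
        states = CnvStateTable(
            states=pd.DataFrame([["amplified"] * 3], index=["p"],
                                columns=patients),
            segment_ids=pd.DataFrame([["s"] * 3], index=["p"],
                                     columns=patients))
        contrast = stratified_contrast(diffs, states)
        with pytest.warns(UserWarning, match="empty"):
            summary, detail = separation_summary(contrast, diffs, states)
        assert detail.empty

    def test_no_cnv_mean_near_zero(self, default_cohort):
        diffs = paired_differences(default_cohort.expression)
        states = assign_states(default_cohort.probes, default_cohort.cnv,
                               patients=default_cohort.expression.patients)
        contrast = stratified_contrast(diffs, states)
        summary, _ = separation_summary(contrast, diffs, states)
        no_cnv = summary.set_index("category").loc["no_cnv"]
        assert no_cnv["n_genes"] >= 2000
        assert abs(no_cnv["mean_diff"]) < 0.05


def test_amp_stratum_calibration_over_replicates():
    """Across 100 seeded replicates, the aggregate amplified-stratum mean
    sits within 3 SEM of log2(1.5)."""
    means = []
    for seed in range(100):
        cohort = generate_cohort(CohortSpec(
            seed=seed, n_genes=200, n_segments=2, genes_per_segment=10,
            n_de_per_group=(20, 10, 5), n_prognostic=10))
        diffs = paired_differences(cohort.expression)
        states = assign_states(cohort.probes, cohort.cnv,
                               patients=cohort.expression.patients)
        contrast = stratified_contrast(diffs, states)
        means.append(float(contrast["amp_mean"].mean()))
    means = np.array(means)
    sem = means.std(ddof=1) / np.sqrt(len(means))
    assert abs(means.mean() - np.log2(1.5)) < 3 * sem


def test_segment_aggregation_covers_all_probes(small_cohort):
    diffs = paired_differences(small_cohort.expression)
    states = assign_states(small_cohort.probes, small_cohort.cnv,
                           patients=small_cohort.expression.patients)
    contrast = stratified_contrast(diffs, states)
    seg = aggregate_by_segment(contrast, states)
    assert (seg["n_probes"] == small_cohort.spec.genes_per_segment).all()
    assert set(seg["state"]) == {"amplified", "deleted"}
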