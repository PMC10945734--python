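"""RRO computation, its count filters, differential RRO, and group summaries."""

import numpy as np
import pandas as pd
import pytest

import ribote
from ribote.annotation import (
    GenomeAnnotation,
    StartCodonClass,
    Transcript,
    UorfRecord,
    UorfSource,
)
from ribote.design import Assay, Condition, Genotype, SampleDesign
from ribote.quant import CountTable
from ribote.uorf import compute_rro, delta_rro, group_te_summary


def _uorf_annotation():
    u = UorfRecord("u1", "tx1", 10, 40, StartCodonClass.AUG, UorfSource.functional)
    return GenomeAnnotation([Transcript("tx1", 600, 100, 400, [u])])


def _table(uorf_counts, cds_counts):
    """CountTable with one gene/uORF over len(counts) RPF samples."""
    samples = [
        SampleDesign(f"s{j}", Genotype.WT, Condition.untreated, j + 1, Assay.RPF)
        for j in range(len(uorf_counts))
    ]
    ids = [s.sample_id for s in samples]
    return CountTable(
        pd.DataFrame([cds_counts], index=["tx1"], columns=ids),
        samples,
        pd.DataFrame([uorf_counts], index=["u1"], columns=ids),
    )


class TestComputeRRO:
    def test_rro_is_count_ratio(self):
        rro = compute_rro(_table([10], [100]), _uorf_annotation())
        assert rro.rro.loc["u1", "s0"] == 0.1
        assert rro.summary.loc["u1", "filter_status"] == "pass"

    def test_low_uorf_filter_below_mean_two(self):
        rro = compute_rro(_table([2, 1], [100, 100]), _uorf_annotation())
        assert rro.summary.loc["u1", "mean_uorf_rpf"] == 1.5
        assert rro.summary.loc["u1", "filter_status"] == "low_uorf"

    def test_low_cds_filter_below_mean_32(self):
        rro = compute_rro(_table([5, 5], [32, 31]), _uorf_annotation())
        assert rro.summary.loc["u1", "mean_cds_rpf"] == 31.5
        assert rro.summary.loc["u1", "filter_status"] == "low_cds"

    def test_boundary_means_pass(self):
        rro = compute_rro(_table([2, 2], [32, 32]), _uorf_annotation())
        assert rro.summary.loc["u1", "filter_status"] == "pass"

    def test_low_uorf_takes_precedence(self):
        rro = compute_rro(_table([1, 1], [10, 10]), _uorf_annotation())
        assert rro.summary.loc["u1", "filter_status"] == "low_uorf"

    def test_statuses_exhaustive_and_exclusive(self, noiseless_counts, small_annotation):
        counts, _ = noiseless_counts
        rro = compute_rro(counts, small_annotation)
        assert set(rro.summary["filter_status"]) <= {"pass", "low_uorf", "low_cds"}
        assert rro.summary["filter_status"].notna().all()

    def test_rro_invariant_to_library_rescale(self):
        a = compute_rro(_table([10, 20], [100, 200]), _uorf_annotation())
        b = compute_rro(_table([30, 60], [300, 600]), _uorf_annotation())
        assert np.allclose(a.rro.to_numpy(), b.rro.to_numpy())

    def test_missing_region_counts_rejected(self):
        t = _table([10], [100])
        t.region_counts = None
        with pytest.raises(ValueError, match="region counts"):
            compute_rro(t, _uorf_annotation())


class TestDeltaRRO:
    def _factorial_counts(self, annotation, rro_by_genotype, seed=30):
        genes = pd.Index(annotation.transcript_ids)
        uorfs = pd.Index([u.uorf_id for u in annotation.uorfs()])
        design = ribote.factorial_design()
        truth_wt = ribote.SimulationTruth.build(
            annotation, base_mean_rna=2000.0, dispersion=0.0,
            true_rro=rro_by_genotype["WT"],
        )
        truth_mut = ribote.SimulationTruth.build(
            annotation, base_mean_rna=2000.0, dispersion=0.0,
            true_rro=rro_by_genotype["eIF2AD"],
        )
        wt = ribote.simulate_counts(
            annotation, [d for d in design if d.genotype == Genotype.WT], truth_wt, seed=seed
        )
        mut = ribote.simulate_counts(
            annotation, [d for d in design if d.genotype == Genotype.eIF2AD], truth_mut, seed=seed
        )
        counts = pd.concat([wt.counts, mut.counts], axis=1)
        region = pd.concat([wt.region_counts, mut.region_counts], axis=1)
        samples = wt.samples + mut.samples
        return CountTable(counts[[s.sample_id for s in samples]], samples,
                          region[[s.sample_id for s in samples if s.assay == Assay.RPF]])

    def test_noiseless_halved_rro_gives_minus_one(self, small_annotation):
        counts = self._factorial_counts(
            small_annotation, {"WT": 0.4, "eIF2AD": 0.2}
        )
        spec = ribote.standard_contrasts()[0]  # mutant vs WT under SM
        res = delta_rro(counts, small_annotation, spec)
        assert np.allclose(res.tested["log2_effect"], -1.0, atol=0.02)

    def test_identical_genotypes_give_zero_effect(self, small_annotation):
        counts = self._factorial_counts(small_annotation, {"WT": 0.3, "eIF2AD": 0.3})
        res = delta_rro(counts, small_annotation, ribote.standard_contrasts()[0])
        assert np.allclose(res.tested["log2_effect"], 0.0, atol=0.02)

    def test_spiked_simulation_controls_fdr_at_loose_threshold(self):
        """Differential RRO with 200 truly halved uORFs among ~900: at the
        loose q < 0.5 threshold the observed false-discovery proportion stays
        consistent with the nominal level (Clopper-Pearson 95% CI)."""
        import scipy.stats

        ann = ribote.simulate_annotation(600, 1.0, seed=31)
        uorfs = pd.Index([u.uorf_id for u in ann.uorfs()])
        true_down = set(uorfs[:200])
        mut_rro = pd.Series(0.3, index=uorfs)
        mut_rro[list(true_down)] = 0.15
        counts = self._factorial_counts_noisy(ann, wt_rro=pd.Series(0.3, index=uorfs),
                                              mut_rro=mut_rro, dispersion=0.05, seed=32)
        res = delta_rro(counts, ann, ribote.standard_contrasts()[0])
        calls = set(res.tested.index[res.tested["q"] < 0.5])
        assert len(calls) > 20  # the spike is detectable at this depth
        n_false = len(calls - true_down)
        ci = scipy.stats.binomtest(n_false, len(calls)).proportion_ci(0.95, method="exact")
        assert ci.low <= 0.5

    def _factorial_counts_noisy(self, annotation, wt_rro, mut_rro, dispersion, seed):
        design = ribote.factorial_design()
        truth_wt = ribote.SimulationTruth.build(
            annotation, base_mean_rna=2000.0, dispersion=dispersion, true_rro=wt_rro
        )
        truth_mut = ribote.SimulationTruth.build(
            annotation, base_mean_rna=2000.0, dispersion=dispersion, true_rro=mut_rro
        )
        wt = ribote.simulate_counts(
            annotation, [d for d in design if d.genotype == Genotype.WT], truth_wt, seed=seed
        )
        mut = ribote.simulate_counts(
            annotation, [d for d in design if d.genotype == Genotype.eIF2AD],
            truth_mut, seed=seed + 1,
        )
        counts = pd.concat([wt.counts, mut.counts], axis=1)
        region = pd.concat([wt.region_counts, mut.region_counts], axis=1)
        samples = wt.samples + mut.samples
        return CountTable(counts[[s.sample_id for s in samples]], samples,
                          region[[s.sample_id for s in samples if s.assay == Assay.RPF]])


class TestGroupSummary:
    def _result_from_effects(self, effects):
        table = pd.DataFrame(
            {
                "log2_effect": effects,
                "se": 0.1,
                "p": 0.5,
                "q": 0.5,
                "status": "tested",
            },
            index=[f"g{i}" for i in range(len(effects))],
        )
        return ribote.ContrastResult(ribote.standard_contrasts()[0], table)

    def test_group_equal_to_background_not_significant(self):
        rng = np.random.default_rng(33)
        effects = rng.normal(0, 1, 400)
        res = self._result_from_effects(effects)
        group = {f"g{i}" for i in range(400)}
        (summary,) = group_te_summary(res, {"all": group})
        assert summary.n == 400
        assert summary.mannwhitney_p > 0.9
        assert abs(summary.median_log2_effect - np.median(effects)) < 1e-12

    def test_shifted_group_highly_significant(self):
        rng = np.random.default_rng(34)
        effects = np.concatenate([rng.normal(0, 1, 900), rng.normal(1, 1, 100) + 1])
        res = self._result_from_effects(effects)
        group = {f"g{i}" for i in range(900, 1000)}
        (summary,) = group_te_summary(res, {"shifted": group})
        assert summary.mannwhitney_p < 1e-10

    def test_single_gene_group_reports_exact_tail(self):
        effects = np.arange(11) / 10.0
        res = self._result_from_effects(effects)
        (summary,) = group_te_summary(res, {"one": {"g10"}})
        assert summary.n == 1
        assert 0 < summary.mannwhitney_p <= 1

    def test_empty_group_rejected(self):
        res = self._result_from_effects(np.zeros(5))
        with pytest.raises(ValueError, match="no tested genes"):
            group_te_summary(res, {"none": set()})
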