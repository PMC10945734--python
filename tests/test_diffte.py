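"""Size factors, BH FDR, and the NB interaction model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ribote
from ribote.design import Assay, Condition, Genotype, SampleDesign
from ribote.diffte import ContrastSpec, bh_fdr, select_by_fold, size_factors
from ribote.quant import CountTable


def _rpf_table(matrix, gene_prefix="g"):
    n_samples = matrix.shape[1]
    samples = [
        SampleDesign(f"s{j}", Genotype.WT, Condition.untreated, j + 1, Assay.RPF)
        for j in range(n_samples)
    ]
    df = pd.DataFrame(matrix, columns=[s.sample_id for s in samples],
                      index=[f"{gene_prefix}{i}" for i in range(matrix.shape[0])])
    return CountTable(df, samples)


class TestSizeFactors:
    def test_median_of_ratios_hand_oracle(self):
        # genes (2,8) and (4,16): ratios to geometric means give (0.5, 2.0),
        # whose geometric mean is already 1, so rescaling changes nothing
        ct = _rpf_table(np.array([[2, 8], [4, 16]]))
        sf = size_factors(ct, Assay.RPF)
        assert np.allclose(sf.to_numpy(), [0.5, 2.0])

    def test_identical_columns_give_unit_factors(self):
        ct = _rpf_table(np.tile([[3], [7], [11]], (1, 4)))
        assert np.allclose(size_factors(ct, Assay.RPF).to_numpy(), 1.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(1, 500, size=(30, 4))
        base = size_factors(_rpf_table(mat), Assay.RPF).to_numpy()
        perm = size_factors(_rpf_table(mat[rng.permutation(30)]), Assay.RPF).to_numpy()
        assert np.allclose(base, perm)

    def test_matches_pydeseq2_median_of_ratios(self):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(4)
        mat = rng.negative_binomial(10, 0.1, size=(200, 4))
        mat[mat == 0] = 1
        ours = size_factors(_rpf_table(mat), Assay.RPF).to_numpy()
        _, theirs = pydeseq2.deseq2_norm(pd.DataFrame(mat.T))
        theirs = np.asarray(theirs, dtype=float).ravel()
        # pydeseq2 does not rescale to geometric mean 1; compare up to a constant
        assert np.allclose(ours / ours[0], theirs / theirs[0], rtol=1e-8)

    def test_all_zero_containing_genes_rejected(self):
        ct = _rpf_table(np.array([[0, 5], [3, 0]]))
        with pytest.raises(ValueError, match="all-positive"):
            size_factors(ct, Assay.RPF)


class TestBHFDR:
    def test_hand_computed_oracle(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate_inputs(self):
        assert bh_fdr([0.5]) == pytest.approx([0.5])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert bh_fdr([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_permutation_invariant_and_monotone(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        order = np.argsort(p, kind="mergesort")
        # q sorted by p is nondecreasing
        assert np.all(np.diff(q[order]) >= -1e-12)
        # permuting inputs permutes outputs identically
        rng = np.random.default_rng(0)
        perm = rng.permutation(p.size)
        assert np.allclose(bh_fdr(p[perm]), q[perm])

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30), st.data())
    def test_monotone_in_each_pvalue(self, pvals, data):
        p = np.array(pvals)
        i = data.draw(st.integers(0, p.size - 1))
        q = bh_fdr(p)
        p2 = p.copy()
        p2[i] = data.draw(st.floats(float(p[i]), 1.0))
        assert bh_fdr(p2)[i] >= q[i] - 1e-12


class TestDeltaTE:
    def test_noiseless_planted_effect_recovered_exactly(self, noiseless_counts):
        counts, truth = noiseless_counts
        res = ribote.delta_te(counts, ribote.standard_contrasts()[0])
        expected = truth.true_log2_dte(ribote.standard_contrasts()[0])
        tested = res.tested
        # rounding to integer counts at mean 500 perturbs the noiseless limit
        # by < 1e-3; the GLM itself converges to the group ratios exactly
        assert np.allclose(tested["log2_effect"], expected.loc[tested.index], atol=5e-3)
        planted = expected.index[expected != 0]
        assert (res.qvalues.loc[planted] < 1e-6).all()

    def test_identical_counts_give_zero_effect_and_p_one(self):
        samples = []
        cols = {}
        for geno in Genotype:
            for rep in (1, 2):
                for assay in Assay:
                    sid = f"{geno.value}_{rep}_{assay.value}"
                    samples.append(SampleDesign(sid, geno, Condition.SM, rep, assay))
                    cols[sid] = [50, 80]
        ct = CountTable(pd.DataFrame(cols, index=["g0", "g1"]), samples)
        spec = ContrastSpec("mut/wt", (Genotype.eIF2AD, Condition.SM), (Genotype.WT, Condition.SM))
        res = ribote.delta_te(ct, spec)
        assert np.allclose(res.log2_effect, 0.0, atol=1e-8)
        assert np.allclose(res.pvalues, 1.0, atol=1e-6)

    def test_swapping_cells_negates_effects_and_keeps_p(self, noiseless_counts):
        counts, _ = noiseless_counts
        spec = ribote.standard_contrasts()[0]
        a = ribote.delta_te(counts, spec)
        b = ribote.delta_te(counts, spec.swapped())
        assert np.allclose(a.log2_effect, -b.log2_effect, atol=1e-6)
        assert np.allclose(a.pvalues.fillna(-1), b.pvalues.fillna(-1), atol=1e-6)

    def test_too_few_replicates_rejected(self):
        samples, cols = [], {}
        for geno in Genotype:
            for assay in Assay:
                sid = f"{geno.value}_{assay.value}"
                samples.append(SampleDesign(sid, geno, Condition.SM, 1, assay))
                cols[sid] = [5]
        ct = CountTable(pd.DataFrame(cols, index=["g0"]), samples)
        spec = ContrastSpec("m/w", (Genotype.eIF2AD, Condition.SM), (Genotype.WT, Condition.SM))
        with pytest.raises(ValueError, match="replicate"):
            ribote.DifferentialTE(ct, spec)

    def test_zero_rna_genes_marked_excluded(self, small_annotation, design):
        genes = pd.Index(small_annotation.transcript_ids)
        base = pd.Series(200.0, index=genes)
        truth = ribote.SimulationTruth.build(small_annotation, base_mean_rna=base, dispersion=0.0)
        counts = ribote.simulate_counts(small_annotation, design, truth, seed=7)
        rna_cols = [s.sample_id for s in counts.samples if s.assay == Assay.RNA]
        counts.counts.loc[genes[0], rna_cols[0]] = 0
        res = ribote.delta_te(counts, ribote.standard_contrasts()[2])
        assert res.table.loc[genes[0], "status"] == "excluded:zero_rna"
        assert np.isnan(res.table.loc[genes[0], "p"])

    def test_permutation_method_agrees_on_strong_effect(self, noiseless_counts):
        counts, truth = noiseless_counts
        spec = ribote.standard_contrasts()[0]
        res = ribote.delta_te(counts, spec, method="perm")
        planted = truth.log2_te_interaction.index[truth.log2_te_interaction != 0]
        # RNA counts are identical across cells in the noiseless fixture, so the
        # 6 RNA relabelings are degenerate and only the 2 extreme RPF
        # assignments reach |obs|: the attainable minimum is 12/36
        assert np.allclose(res.pvalues.loc[planted], 12 / 36)
        null = truth.log2_te_interaction.index[truth.log2_te_interaction == 0]
        assert np.allclose(res.pvalues.loc[null], 1.0)
        assert np.allclose(
            res.log2_effect, ribote.delta_te(counts, spec).log2_effect, atol=5e-3
        )


class TestSelectByFold:
    def _result(self, effects, qs=None):
        n = len(effects)
        table = pd.DataFrame(
            {
                "log2_effect": effects,
                "se": 0.1,
                "p": 0.01,
                "q": qs if qs is not None else [0.01] * n,
                "status": "tested",
            },
            index=[f"g{i}" for i in range(n)],
        )
        return ribote.ContrastResult(ribote.standard_contrasts()[0], table)

    def test_up_selection_above_threshold(self):
        # log2(1.41) = 0.4957, so both 0.6 and 0.5 clear it; -0.6 does not
        res = self._result([0.6, 0.5, -0.6])
        assert select_by_fold(res, 1.41, "up") == {"g0", "g1"}

    def test_exact_half_log2_not_selected_at_sqrt2(self):
        res = self._result([0.5])
        # fold 2**0.5 has log2 exactly 0.5; strict > excludes the boundary gene
        assert select_by_fold(res, 2**0.5, "up") == set()

    def test_down_direction_and_fdr_gate(self):
        res = self._result([-0.6, -0.7], qs=[0.01, 0.5])
        assert select_by_fold(res, 1.41, "down", fdr=0.25) == {"g0"}

    def test_empty_result_gives_empty_set(self):
        res = self._result([])
        assert select_by_fold(res, 1.41, "up") == set()
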