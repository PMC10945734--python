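"""Determinism, moment, and inverse-consistency contracts of the simulators."""

import numpy as np
import pandas as pd
import pytest

import ribote
from ribote.simulate import _allocation, track_to_raw_3prime


class TestAnnotation:
    def test_uorf_fraction_extremes(self):
        none = ribote.simulate_annotation(10, 0.0, seed=1)
        assert len(none) == 10 and len(none.uorfs()) == 0
        every = ribote.simulate_annotation(10, 1.0, seed=1)
        assert all(len(tx.uorfs) >= 1 for tx in every)

    def test_same_seed_reproduces_annotation(self):
        a = ribote.simulate_annotation(25, 0.4, seed=9)
        b = ribote.simulate_annotation(25, 0.4, seed=9)
        assert a == b
        assert [u.uorf_id for u in a.uorfs()] == [u.uorf_id for u in b.uorfs()]

    def test_cds_lengths_within_stated_range_and_frame(self):
        ann = ribote.simulate_annotation(50, 0.0, seed=2)
        for tx in ann:
            assert 300 <= tx.cds_length <= 3000
            assert tx.cds_length % 3 == 0
            assert 60 <= tx.cds_start <= 300  # 5' UTR length

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            ribote.simulate_annotation(0, 0.5)
        with pytest.raises(ValueError):
            ribote.simulate_annotation(5, 1.5)


class TestCounts:
    def test_zero_noise_zero_effect_gives_constant_te_ratio(self, small_annotation, design):
        truth = ribote.SimulationTruth.build(small_annotation, dispersion=0.0)
        ct = ribote.simulate_counts(small_annotation, design, truth, seed=3)
        rpf = ct.counts[[s.sample_id for s in ct.samples if s.assay.value == "RPF"]]
        rna = ct.counts[[s.sample_id for s in ct.samples if s.assay.value == "RNA"]]
        ratios = rpf.to_numpy() / rna.to_numpy()
        assert np.allclose(ratios, ratios[:, :1])

    def test_same_seed_identical_counts(self, small_annotation, design):
        truth = ribote.SimulationTruth.build(small_annotation, dispersion=0.05)
        a = ribote.simulate_counts(small_annotation, design, truth, seed=4)
        b = ribote.simulate_counts(small_annotation, design, truth, seed=4)
        assert a.counts.equals(b.counts)
        assert a.region_counts.equals(b.region_counts)

    def test_planted_effect_recovered_in_empirical_te(self):
        ann = ribote.simulate_annotation(250, 0.0, seed=5)
        genes = pd.Index(ann.transcript_ids)
        truth = ribote.SimulationTruth.build(
            ann, base_mean_rna=200.0, dispersion=0.01,
            log2_te_condition=pd.Series(1.0, index=genes),
        )
        ct = ribote.simulate_counts(ann, ribote.factorial_design(), truth, seed=6)

        def cell_mean(cond, assay):
            cols = [s.sample_id for s in ct.samples
                    if s.genotype.value == "WT" and s.condition.value == cond
                    and s.assay.value == assay]
            return ct.counts[cols].mean(axis=1)

        log2_te_ratio = np.log2(
            (cell_mean("SM", "RPF") / cell_mean("SM", "RNA"))
            / (cell_mean("untreated", "RPF") / cell_mean("untreated", "RNA"))
        )
        assert abs(log2_te_ratio.mean() - 1.0) < 0.2

    def test_nb_moments_match_parameterization(self):
        from ribote.simulate import _draw_counts

        mu, alpha, n = 150.0, 0.1, 20000
        ours = _draw_counts(np.random.default_rng(8), np.full(n, mu), np.full(n, alpha))
        target_var = mu + alpha * mu**2
        se_mean = np.sqrt(target_var / n)
        assert abs(ours.mean() - mu) < 3 * se_mean
        assert abs(ours.var() - target_var) / target_var < 0.1

    def test_uorf_counts_track_true_rro(self, small_annotation, design):
        truth = ribote.SimulationTruth.build(small_annotation, dispersion=0.0, true_rro=0.25,
                                             base_mean_rna=4000.0)
        ct = ribote.simulate_counts(small_annotation, design, truth, seed=9)
        rro = ribote.compute_rro(ct, small_annotation)
        ratios = rro.rro.to_numpy()
        assert np.allclose(ratios, 0.25, atol=0.01)

    def test_missing_assay_in_cell_rejected(self, small_annotation):
        truth = ribote.SimulationTruth.build(small_annotation)
        design = [d for d in ribote.factorial_design() if d.assay.value == "RPF"]
        with pytest.raises(ValueError, match="lacks RNA"):
            ribote.simulate_counts(small_annotation, design, truth, seed=1)


class TestTrack:
    def test_uniform_density_without_planted_motifs(self, small_annotation):
        peps = ribote.simulate_peptides(small_annotation, seed=10)
        truth = ribote.SimulationTruth.build(small_annotation)
        track = ribote.simulate_track(small_annotation, peps, truth, depth=1e4, sampled=False)
        for tx in small_annotation:
            cds = track.density[tx.transcript_id][tx.cds_start : tx.cds_end]
            assert np.allclose(cds, cds[0])
            outside = np.delete(track.density[tx.transcript_id],
                                np.arange(tx.cds_start, tx.cds_end))
            assert np.all(outside == 0)

    def test_planted_motif_density_ratio(self, small_annotation):
        peps = ribote.simulate_peptides(small_annotation, seed=11, motif="PPG", n_planted=20)
        truth = ribote.SimulationTruth.build(small_annotation, pause_multipliers={"PPG": 5.0})
        track = ribote.simulate_track(small_annotation, peps, truth, depth=1e5, sampled=False)
        for tx in small_annotation:
            pep = peps[tx.transcript_id]
            arr = track.density[tx.transcript_id]
            for k in range(len(pep) - 2):
                if pep[k : k + 3] == "PPG":
                    s = tx.cds_start + 3 * k
                    background = arr[tx.cds_start]
                    if pep[:3] != "PPG":
                        assert np.allclose(arr[s : s + 9] / background, 5.0)

    def test_depth_doubling_doubles_density(self, small_annotation):
        peps = ribote.simulate_peptides(small_annotation, seed=12)
        truth = ribote.SimulationTruth.build(small_annotation)
        t1 = ribote.simulate_track(small_annotation, peps, truth, depth=1e4, sampled=False)
        t2 = ribote.simulate_track(small_annotation, peps, truth, depth=2e4, sampled=False)
        for tid in t1.density:
            assert np.allclose(t2.density[tid], 2 * t1.density[tid])

    def test_sampled_track_depth_and_determinism(self, small_annotation):
        peps = ribote.simulate_peptides(small_annotation, seed=13)
        truth = ribote.SimulationTruth.build(small_annotation)
        a = ribote.simulate_track(small_annotation, peps, truth, depth=5e3, seed=14)
        b = ribote.simulate_track(small_annotation, peps, truth, depth=5e3, seed=14)
        assert a == b
        assert a.total_reads() == 5e3

    def test_peptide_length_mismatch_rejected(self, small_annotation):
        peps = ribote.simulate_peptides(small_annotation, seed=15)
        tid = small_annotation.transcript_ids[0]
        peps[tid] = peps[tid][:-1]
        truth = ribote.SimulationTruth.build(small_annotation)
        with pytest.raises(ValueError, match="peptide length"):
            ribote.simulate_track(small_annotation, peps, truth)

    def test_raw_3prime_round_trip_through_shift(self, small_annotation):
        peps = ribote.simulate_peptides(small_annotation, seed=16)
        truth = ribote.SimulationTruth.build(small_annotation)
        track = ribote.simulate_track(small_annotation, peps, truth, depth=1e4, seed=17)
        raw = track_to_raw_3prime(track, 18)
        back = ribote.shift_assign(raw, 18, library_size=track.library_size)
        assert back == track


class TestGradient:
    @pytest.mark.parametrize("te", [1.0, 2.0, 4.0, 8.0])
    def test_zero_noise_identity(self, te):
        g = ribote.simulate_gradient(te, n_fractions=8, noise_sd_ct=0.0, seed=18)
        est = ribote.reconstruct_te(g, "target")
        assert abs(est.te - te) / te < 1e-9

    def test_te_beyond_max_ribosome_weight_rejected(self):
        with pytest.raises(ValueError, match="not attainable"):
            ribote.simulate_gradient(5.0, n_fractions=4, seed=19)

    def test_noisy_recovery_unbiased(self):
        te_true = 3.0
        estimates = []
        for rep in range(100):
            g = ribote.simulate_gradient(te_true, n_fractions=6, noise_sd_ct=0.1, seed=200 + rep)
            estimates.append(ribote.reconstruct_te(g, "target").te)
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / 10
        # lognormal CT noise adds a ~0.1% multiplicative bias; allow 3 SE + that
        assert abs(estimates.mean() - te_true) < 3 * se + 0.01 * te_true

    def test_allocation_hits_target_mean(self):
        w = np.arange(1, 7, dtype=float)
        for te in (1.0, 1.5, 3.7, 6.0):
            f = _allocation(w, te)
            assert abs((w * f).sum() - te) < 1e-9
            assert abs(f.sum() - 1) < 1e-12

    def test_experiment_determinism(self):
        kw = dict(te_true={("WT", "untreated"): {"x": 2.0}, ("WT", "SM"): {"x": 1.5}},
                  replicates=2, seed=21)
        a = ribote.simulate_gradient_experiment(**kw)
        b = ribote.simulate_gradient_experiment(**kw)
        ta = ribote.reconstruct_all(a, ["x"])
        tb = ribote.reconstruct_all(b, ["x"])
        assert ta.equals(tb)
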