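"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study conditions: a 2 genotype x 2 condition x
2 replicate design with paired RPF/RNA libraries, negative-binomial counts
(variance = mu + alpha mu^2), uORF-bearing transcripts with controllable
uORF/CDS footprint ratios, footprint tracks with planted motif-specific
pauses, and polysome gradients whose CT values are back-computed through the
exact inverse of the reconstruction chain so the true TE is recovered
identically at zero noise.  All randomness flows through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.optimize

from .annotation import (
    GenomeAnnotation,
    StartCodonClass,
    Transcript,
    UorfRecord,
    UorfSource,
)
from .design import Assay, Condition, Genotype, SampleDesign, factorial_design
from .diffte import ContrastSpec
from .polysome import ACT1, RRNA_18S, Gradient, GradientDataset, GradientFraction
from .quant import CountTable
from .track import FootprintTrack

__all__ = [
    "SimulationTruth",
    "simulate_annotation",
    "simulate_peptides",
    "simulate_counts",
    "simulate_track",
    "track_to_raw_3prime",
    "simulate_gradient",
    "simulate_gradient_experiment",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated experiment.

    Per-gene TE effects are factorial: the log2 TE of a (genotype, condition)
    cell is  g*[mutant] + c*[SM] + i*[mutant & SM]  relative to untreated WT.
    """

    base_mean_rna: pd.Series
    log2_te_genotype: pd.Series
    log2_te_condition: pd.Series
    log2_te_interaction: pd.Series
    dispersion: pd.Series
    true_rro: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    pause_multipliers: Dict[str, float] = field(default_factory=dict)
    te_true_gradient: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.base_mean_rna <= 0).any():
            raise ValueError("base_mean_rna must be > 0")
        if (self.dispersion < 0).any():
            raise ValueError("dispersion must be >= 0")
        if (self.true_rro < 0).any():
            raise ValueError("true_rro must be >= 0")
        for m, mult in self.pause_multipliers.items():
            if mult < 1:
                raise ValueError(f"pause multiplier for {m} must be >= 1")

    @classmethod
    def build(
        cls,
        annotation: GenomeAnnotation,
        base_mean_rna: Union[float, pd.Series] = 200.0,
        dispersion: Union[float, pd.Series] = 0.05,
        log2_te_genotype: Union[float, pd.Series] = 0.0,
        log2_te_condition: Union[float, pd.Series] = 0.0,
        log2_te_interaction: Union[float, pd.Series] = 0.0,
        true_rro: Union[float, pd.Series] = 0.1,
        pause_multipliers: Optional[Dict[str, float]] = None,
        te_true_gradient: Optional[Dict[str, float]] = None,
    ) -> "SimulationTruth":
        genes = pd.Index(annotation.transcript_ids, name="gene")
        uorfs = pd.Index([u.uorf_id for u in annotation.uorfs()], name="uorf_id")

        def expand(v, index):
            return v.reindex(index) if isinstance(v, pd.Series) else pd.Series(float(v), index=index)

        return cls(
            base_mean_rna=expand(base_mean_rna, genes),
            log2_te_genotype=expand(log2_te_genotype, genes),
            log2_te_condition=expand(log2_te_condition, genes),
            log2_te_interaction=expand(log2_te_interaction, genes),
            dispersion=expand(dispersion, genes),
            true_rro=expand(true_rro, uorfs),
            pause_multipliers=pause_multipliers or {},
            te_true_gradient=te_true_gradient or {},
        )

    def log2_te_cell(self, genotype: Genotype, condition: Condition) -> pd.Series:
        g = float(genotype == Genotype.eIF2AD)
        c = float(condition == Condition.SM)
        return (
            g * self.log2_te_genotype
            + c * self.log2_te_condition
            + g * c * self.log2_te_interaction
        )

    def true_log2_dte(self, contrast: ContrastSpec) -> pd.Series:
        """Planted log2 TE change for a named contrast (numerator / denominator cell)."""
        return self.log2_te_cell(*contrast.numerator_cell) - self.log2_te_cell(
            *contrast.denominator_cell
        )

    def to_frame(self) -> pd.DataFrame:
        """Gene-level truth table (written alongside fixtures as truth.tsv)."""
        return pd.DataFrame(
            {
                "base_mean_rna": self.base_mean_rna,
                "log2_te_genotype": self.log2_te_genotype,
                "log2_te_condition": self.log2_te_condition,
                "log2_te_interaction": self.log2_te_interaction,
                "dispersion": self.dispersion,
            }
        )


# ---------------------------------------------------------------------------
# Annotation and peptides


def simulate_annotation(
    n_genes: int,
    uorf_fraction: float = 0.0,
    seed: int = 0,
    cds_codon_range: Tuple[int, int] = (100, 1000),
    utr5_range: Tuple[int, int] = (60, 300),
    utr3_range: Tuple[int, int] = (50, 200),
) -> GenomeAnnotation:
    """Random transcripts: CDS 300-3000 nt (multiples of 3), 5' UTRs 60-300 nt;
    ``uorf_fraction`` of transcripts carry 1-2 uORFs (AUG/NCC half and half)
    upstream of the CDS.  Deterministic for a given seed."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= uorf_fraction <= 1.0:
        raise ValueError("uorf_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    transcripts = []
    for i in range(n_genes):
        tid = f"g{i + 1:0{width}d}"
        cds_len = 3 * int(rng.integers(cds_codon_range[0], cds_codon_range[1] + 1))
        utr5 = int(rng.integers(utr5_range[0], utr5_range[1] + 1))
        utr3 = int(rng.integers(utr3_range[0], utr3_range[1] + 1))
        uorfs: List[UorfRecord] = []
        if rng.random() < uorf_fraction:
            for j in range(int(rng.integers(1, 3))):
                ulen = 3 * int(rng.integers(2, 11))
                start = int(rng.integers(0, utr5 - ulen + 1))
                uorfs.append(
                    UorfRecord(
                        uorf_id=f"{tid}_u{j + 1}",
                        transcript_id=tid,
                        start=start,
                        end=start + ulen,
                        start_codon_class=(
                            StartCodonClass.AUG if rng.random() < 0.5 else StartCodonClass.NCC
                        ),
                        annotation_source=UorfSource(
                            rng.choice(["annotated", "conserved", "functional"])
                        ),
                    )
                )
        transcripts.append(Transcript(tid, utr5 + cds_len + utr3, utr5, utr5 + cds_len, uorfs))
    return GenomeAnnotation(transcripts)


def simulate_peptides(
    annotation: GenomeAnnotation,
    seed: int = 0,
    motif: Optional[str] = None,
    n_planted: int = 0,
    window_nt: int = 50,
) -> Dict[str, str]:
    """Random peptide per gene (length = CDS codons - 1), optionally planting
    ``n_planted`` copies of a tripeptide ``motif`` at window-safe positions."""
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    peptides = {
        tx.transcript_id: "".join(rng.choice(aa, size=tx.n_codons - 1))
        for tx in annotation
    }
    if motif is not None and n_planted > 0:
        if len(motif) != 3:
            raise ValueError("motif must be a tripeptide")
        slots = []
        margin = (window_nt + 2) // 3 + 1
        for tx in annotation:
            n_pep = tx.n_codons - 1
            for k in range(margin, n_pep - 2 - margin, 4):  # stride avoids overlap
                slots.append((tx.transcript_id, k))
        if len(slots) < n_planted:
            raise ValueError(f"only {len(slots)} slots for {n_planted} planted motifs")
        chosen = rng.choice(len(slots), size=n_planted, replace=False)
        for idx in chosen:
            tid, k = slots[idx]
            pep = peptides[tid]
            peptides[tid] = pep[:k] + motif + pep[k + 3 :]
    return peptides


# ---------------------------------------------------------------------------
# Counts


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draws with variance mu + alpha mu^2; alpha == 0 is the deterministic limit."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.rint(mu).astype(np.int64)
    noisy = alpha > 0
    if noisy.any():
        n = 1.0 / alpha[noisy]
        p = n / (n + mu[noisy])
        out[noisy] = rng.negative_binomial(n, p)
    return out


def simulate_counts(
    annotation: GenomeAnnotation,
    design: Sequence[SampleDesign],
    truth: SimulationTruth,
    seed: int = 0,
    library_scale: Optional[Dict[str, float]] = None,
) -> CountTable:
    """Gene x sample counts (plus uORF region counts for RPF libraries).

    RNA counts have mean base_mean_rna x library scale; RPF counts multiply in
    the cell's TE (2**log2_te_cell); uORF counts have mean true_rro x the host
    CDS RPF mean, keeping the expected uORF/CDS ratio exactly at true_rro.
    """
    design = list(design)
    cells = {(s.genotype, s.condition) for s in design}
    for cell in cells:
        for assay in Assay:
            if not any(s.cell == cell and s.assay == assay for s in design):
                raise ValueError(f"design cell {cell} lacks {assay.value} samples")
    rng = np.random.default_rng(seed)
    genes = annotation.transcript_ids
    uorfs = [u.uorf_id for u in annotation.uorfs()]
    hosts = {u.uorf_id: u.transcript_id for u in annotation.uorfs()}
    base = truth.base_mean_rna.loc[genes].to_numpy()
    alpha = truth.dispersion.loc[genes].to_numpy()
    cols, region_cols = {}, {}
    for s in design:
        scale = 1.0 if library_scale is None else library_scale[s.sample_id]
        mu = base * scale
        if s.assay == Assay.RPF:
            mu = mu * 2.0 ** self_te(truth, s).to_numpy()
        cols[s.sample_id] = _draw_counts(rng, mu, alpha)
        if s.assay == Assay.RPF and uorfs:
            host_mu = pd.Series(mu, index=genes).loc[[hosts[u] for u in uorfs]].to_numpy()
            mu_u = truth.true_rro.loc[uorfs].to_numpy() * host_mu
            alpha_u = pd.Series(alpha, index=genes).loc[[hosts[u] for u in uorfs]].to_numpy()
            region_cols[s.sample_id] = _draw_counts(rng, mu_u, alpha_u)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    region = (
        pd.DataFrame(region_cols, index=pd.Index(uorfs, name="uorf_id")) if region_cols else None
    )
    return CountTable(counts, design, region)


def self_te(truth: SimulationTruth, sample: SampleDesign) -> pd.Series:
    return truth.log2_te_cell(sample.genotype, sample.condition)


# ---------------------------------------------------------------------------
# Footprint tracks


def simulate_track(
    annotation: GenomeAnnotation,
    peptides: Dict[str, str],
    truth: SimulationTruth,
    depth: float = 1e5,
    seed: int = 0,
    sampled: bool = True,
) -> FootprintTrack:
    """Footprint density: uniform within each CDS (weighted per gene by
    base_mean_rna), multiplied by the planted pause multiplier over each
    occurrence of a planted motif, scaled to ``depth`` total reads.  With
    ``sampled`` the expected density is multinomially sampled; otherwise the
    exact expectation is returned."""
    expected: Dict[str, np.ndarray] = {}
    for tx in annotation:
        pep = peptides.get(tx.transcript_id)
        if pep is None:
            raise ValueError(f"transcript {tx.transcript_id}: no peptide provided")
        if len(pep) != tx.n_codons - 1:
            raise ValueError(
                f"transcript {tx.transcript_id}: peptide length {len(pep)} != {tx.n_codons - 1}"
            )
        arr = np.zeros(tx.length)
        arr[tx.cds_start : tx.cds_end] = truth.base_mean_rna[tx.transcript_id] / tx.cds_length
        for motif, mult in truth.pause_multipliers.items():
            for k in range(len(pep) - 2):
                if pep[k : k + 3] == motif:
                    s = tx.cds_start + 3 * k
                    arr[s : s + 9] *= mult
        expected[tx.transcript_id] = arr
    total = sum(arr.sum() for arr in expected.values())
    for tid in expected:
        expected[tid] = expected[tid] * (depth / total)
    if not sampled:
        return FootprintTrack(expected, library_size=depth)
    rng = np.random.default_rng(seed)
    tids = list(expected)
    flat = np.concatenate([expected[t] for t in tids])
    draws = rng.multinomial(int(round(depth)), flat / flat.sum()).astype(float)
    out: Dict[str, np.ndarray] = {}
    pos = 0
    for t in tids:
        n = expected[t].size
        out[t] = draws[pos : pos + n]
        pos += n
    return FootprintTrack(out, library_size=float(int(round(depth))))


def track_to_raw_3prime(track: FootprintTrack, shift_nt: int) -> Dict[str, np.ndarray]:
    """Inverse of shift_assign: move assigned positions back to footprint 3' ends."""
    out = {}
    for tid, arr in track.density.items():
        raw = np.zeros_like(arr)
        if shift_nt == 0:
            raw[:] = arr
        else:
            raw[shift_nt:] = arr[: arr.size - shift_nt]
            if arr[arr.size - shift_nt :].sum() > 0:
                raise ValueError(
                    f"transcript {tid}: density within {shift_nt} nt of the 3' end cannot be represented"
                )
        out[tid] = raw
    return out


# ---------------------------------------------------------------------------
# Polysome gradients


def _allocation(weights: np.ndarray, te_true: float) -> np.ndarray:
    """Softmax allocation over ribosome weights with weighted mean == te_true."""
    lam_lo, lam_hi = -40.0, 40.0

    def mean_at(lam: float) -> float:
        z = lam * (weights - weights.mean())
        f = np.exp(z - z.max())
        f /= f.sum()
        return float((weights * f).sum())

    if not mean_at(lam_lo) <= te_true <= mean_at(lam_hi):
        raise ValueError(
            f"te_true={te_true} not attainable with ribosome weights {weights.min()}..{weights.max()}"
        )
    lam = scipy.optimize.brentq(lambda l: mean_at(l) - te_true, lam_lo, lam_hi, xtol=1e-14)
    z = lam * (weights - weights.mean())
    f = np.exp(z - z.max())
    return f / f.sum()


def simulate_gradient(
    te_true: Union[float, Dict[str, float]],
    n_fractions: int = 4,
    noise_sd_ct: float = 0.0,
    seed: int = 0,
    gradient_id: str = "grad1",
    genotype: str = "WT",
    condition: str = "untreated",
    replicate: int = 1,
    gradient_recovery: float = 1.0,
    area_scale: float = 1.0,
) -> Gradient:
    """One gradient whose CT values invert the reconstruction chain exactly.

    The target's corrected amounts across fractions are allocated so that the
    ribosome-weighted, fully normalized sum divided by the ACT1-normalized
    input equals ``te_true`` when ``noise_sd_ct`` is 0 (mass conservation:
    the ACT1-normalized input equals the total target across fractions, so
    te_true must lie within [1, n_fractions]).  Gaussian CT noise is added to
    the target CTs only.
    """
    if n_fractions < 2:
        raise ValueError("n_fractions must be >= 2 (80S plus at least one polysome class)")
    targets = te_true if isinstance(te_true, dict) else {"target": float(te_true)}
    for t, v in targets.items():
        if v <= 0:
            raise ValueError(f"te_true for {t} must be > 0")
    rng = np.random.default_rng(seed)
    weights = np.arange(1, n_fractions + 1, dtype=float)

    a260 = np.exp(-0.4 * np.arange(n_fractions)) * rng.uniform(0.9, 1.1, n_fractions)
    a260 = a260 / a260.sum() * 20.0 * area_scale
    a260_share = a260 / a260.sum()
    s18_share = a260_share * rng.uniform(0.8, 1.2, n_fractions)
    s18_share = s18_share / s18_share.sum()
    pooled_vol = rng.uniform(300.0, 700.0, n_fractions)
    rt_vol = rng.uniform(10.0, 25.0, n_fractions)

    M = 2.0**-8  # overall measured 18S scale, sets CTs into a plausible range
    vc = (pooled_vol / 300.0) * (25.0 / rt_vol)
    ct_18s = -np.log2(s18_share * M / vc)
    rf = a260_share / s18_share

    ct_in_18s, ct_in_act1 = 10.0, 16.0
    act1_rel = 2.0 ** (-(ct_in_act1 - ct_in_18s))

    fractions = [
        GradientFraction(
            fraction_id=f"f{i + 1}",
            ribosome_weight=int(weights[i]),
            a260_area=float(a260[i]),
            pooled_volume_ul=float(pooled_vol[i]),
            rt_input_fraction_volume_ul=float(rt_vol[i]),
            ct={RRNA_18S: float(ct_18s[i])},
        )
        for i in range(n_fractions)
    ]
    input_ct = {RRNA_18S: ct_in_18s, ACT1: ct_in_act1}
    A = 1e-3  # total corrected target amount across the gradient (arbitrary units)
    for target, te in targets.items():
        f_alloc = _allocation(weights, te)
        a_i = A * f_alloc
        rel = a_i / (vc * rf * gradient_recovery)
        ct_t = ct_18s - np.log2(rel)
        if noise_sd_ct > 0:
            ct_t = ct_t + rng.normal(0.0, noise_sd_ct, n_fractions)
        for i, fr in enumerate(fractions):
            fr.ct[target] = float(ct_t[i])
        ct_in_t = ct_in_18s - np.log2(A * act1_rel)
        if noise_sd_ct > 0:
            ct_in_t += float(rng.normal(0.0, noise_sd_ct))
        input_ct[target] = float(ct_in_t)

    return Gradient(
        gradient_id=gradient_id,
        fractions=fractions,
        input_ct=input_ct,
        genotype=genotype,
        condition=condition,
        replicate=replicate,
    )


def simulate_gradient_experiment(
    te_true: Dict[Tuple[str, str], Dict[str, float]],
    replicates: int = 3,
    n_fractions: int = 4,
    noise_sd_ct: float = 0.0,
    seed: int = 0,
) -> GradientDataset:
    """Gradients for every (genotype, condition) x replicate, with differing
    monosome+polysome recoveries that the reconstruction's gradient-recovery
    factor undoes.  ``te_true`` maps (genotype, condition) -> target -> TE."""
    rng = np.random.default_rng(seed)
    layout = [
        (geno, cond, rep)
        for (geno, cond) in te_true
        for rep in range(1, replicates + 1)
    ]
    scales = rng.uniform(0.7, 1.3, len(layout))
    # gradient-recovery factors must be known at construction time to invert them
    totals = 20.0 * scales
    grf = [totals.mean() / t for t in totals]
    gradients = []
    for i, (geno, cond, rep) in enumerate(layout):
        gradients.append(
            simulate_gradient(
                te_true[(geno, cond)],
                n_fractions=n_fractions,
                noise_sd_ct=noise_sd_ct,
                seed=int(rng.integers(0, 2**31 - 1)),
                gradient_id=f"{geno}_{cond}_{rep}",
                genotype=geno,
                condition=cond,
                replicate=rep,
                gradient_recovery=grf[i],
                area_scale=float(scales[i]),
            )
        )
    return GradientDataset(gradients)
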