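"""Differential translational efficiency: NB interaction model with Wald tests.

The change in TE between two (genotype, condition) cells is estimated per gene
by a log-link negative-binomial GLM on raw counts with terms

    assay + cell + assay:cell        (offset = log size factor)

fitted over the paired RPF and RNA libraries of the two cells.  The
assay-by-cell interaction coefficient is the log fold-change in TE
(reported in log2 units); its Wald test gives the p-value and BH adjustment
the FDR.  Library depth is normalized by median-of-ratios size factors per
assay.  Gene-wise NB dispersions are method-of-moments estimates shrunk
toward a mean-dispersion trend, an empirical-Bayes device needed because two
replicates per cell leave only four residual degrees of freedom per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .config import AnalysisConfig
from .design import Assay, Condition, Genotype, SampleDesign
from .quant import CountTable

__all__ = [
    "ContrastSpec",
    "ContrastResult",
    "DifferentialTE",
    "DifferentialTEResults",
    "size_factors",
    "bh_fdr",
    "delta_te",
    "select_by_fold",
    "standard_contrasts",
]

logger = logging.getLogger(__name__)

Cell = Tuple[Genotype, Condition]

_LN2 = np.log(2.0)
_MIN_DISP = 1e-8
_MAX_DISP = 10.0


@dataclass(frozen=True)
class ContrastSpec:
    """A named TE comparison between two (genotype, condition) cells."""

    name: str
    numerator_cell: Cell
    denominator_cell: Cell
    fdr_threshold: float = 0.25

    def __post_init__(self) -> None:
        if tuple(self.numerator_cell) == tuple(self.denominator_cell):
            raise ValueError(f"contrast {self.name}: numerator equals denominator")

    def swapped(self) -> "ContrastSpec":
        return ContrastSpec(
            name=f"{self.name}(swapped)",
            numerator_cell=self.denominator_cell,
            denominator_cell=self.numerator_cell,
            fdr_threshold=self.fdr_threshold,
        )


def standard_contrasts() -> List[ContrastSpec]:
    """The four comparisons of the study's factorial design, in diagnostic order:
    mutant-vs-WT under SM, SM-vs-untreated in the mutant, SM-vs-untreated in WT,
    and mutant-vs-WT untreated."""
    G, C = Genotype, Condition
    return [
        ContrastSpec("eIF2AD+SM/WT+SM", (G.eIF2AD, C.SM), (G.WT, C.SM)),
        ContrastSpec("eIF2AD+SM/eIF2AD", (G.eIF2AD, C.SM), (G.eIF2AD, C.untreated)),
        ContrastSpec("WT+SM/WT", (G.WT, C.SM), (G.WT, C.untreated)),
        ContrastSpec("eIF2AD/WT", (G.eIF2AD, C.untreated), (G.WT, C.untreated)),
    ]


@dataclass
class ContrastResult:
    """Per-gene effects for one contrast.

    ``table`` is indexed by gene with columns ``log2_effect``, ``se``, ``p``,
    ``q``, ``status`` (``tested`` or ``excluded:<reason>``).
    """

    contrast: ContrastSpec
    table: pd.DataFrame

    REQUIRED_COLUMNS = ("log2_effect", "se", "p", "q", "status")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"result table missing columns {sorted(missing)}")

    @property
    def tested(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "tested"]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


# ---------------------------------------------------------------------------
# Normalization and FDR primitives


def size_factors(counts: CountTable, assay: Assay) -> pd.Series:
    """Median-of-ratios size factors for one assay's libraries.

    For every gene with all-positive counts, each library's count is divided
    by the gene's geometric mean across the assay's libraries; the library's
    factor is the median of those ratios, rescaled so the factors have
    geometric mean 1.
    """
    cols = [s.sample_id for s in counts.samples if s.assay == assay]
    if not cols:
        raise ValueError(f"no {assay.value} samples in table")
    mat = counts.counts[cols].to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with all-positive counts; cannot compute size factors")
    mat = mat[positive]
    log_geomean = np.log(mat).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(mat) - log_geomean, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cols)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_by_fold(
    result: ContrastResult,
    fold: float,
    direction: str,
    fdr: Optional[float] = None,
) -> Set[str]:
    """Genes with a strict >``fold`` change (``direction`` 'up' or 'down'),
    optionally also requiring q < ``fdr``."""
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    t = result.tested
    cutoff = np.log2(fold)
    mask = t["log2_effect"] > cutoff if direction == "up" else t["log2_effect"] < -cutoff
    if fdr is not None:
        mask &= t["q"] < fdr
    return set(t.index[mask])


# ---------------------------------------------------------------------------
# Dispersion estimation


def _moment_dispersions(
    norm_counts: np.ndarray, group_masks: List[np.ndarray]
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-gene method-of-moments NB dispersion pooled across groups.

    For each group, var - mean estimates alpha * mean^2; pooling the
    numerators and denominators over groups gives one estimate per gene.
    Returns (raw estimates, per-gene mean normalized count).
    """
    num = np.zeros(norm_counts.shape[0])
    den = np.zeros(norm_counts.shape[0])
    for mask in group_masks:
        sub = norm_counts[:, mask]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += v - m
        den += m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return raw, norm_counts.mean(axis=1)


def _fit_trend(raw: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Fit the parametric mean-dispersion trend a0 + a1/mean (a0, a1 >= 0)."""
    ok = np.isfinite(raw) & (means > 0)
    if ok.sum() < 10:
        level = max(float(np.nanmean(np.clip(raw[ok], 0, _MAX_DISP))) if ok.any() else 0.0,
                    _MIN_DISP)
        return np.full_like(means, level)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, _ = scipy.optimize.nnls(X, np.clip(raw[ok], 0.0, _MAX_DISP))
    trend = coef[0] + coef[1] / np.maximum(means, 1e-300)
    return np.clip(trend, _MIN_DISP, _MAX_DISP)


def shrink_dispersions(
    norm_counts: np.ndarray,
    group_masks: List[np.ndarray],
    weight: Union[float, str] = "auto",
) -> np.ndarray:
    """Gene-wise dispersions shrunk toward the mean-dispersion trend.

    ``weight`` is the pull toward the trend; ``"auto"`` sets a per-gene
    empirical-Bayes weight  V_samp / (V_samp + V_prior),  where V_samp is the
    (trend-based) sampling variance of the gene-wise moment estimate and
    V_prior the excess spread of those estimates across genes.  With two
    replicates per group the gene-wise estimates alone are far too noisy to
    plug into Wald standard errors; near-homogeneous dispersion data drive
    the auto weight toward 1 (trend only), while genuinely heterogeneous
    dispersions keep gene-wise information.
    """
    raw, means = _moment_dispersions(norm_counts, group_masks)
    trend = _fit_trend(raw, means)
    # sampling variance of the moment estimator, evaluated on the trend:
    # var(v_g) ~= 2 sigma_g^4 / (n_g - 1) with sigma_g^2 = m + trend m^2
    v_samp = np.zeros_like(raw)
    den = np.zeros_like(raw)
    for mask in group_masks:
        n_g = int(mask.sum())
        m = norm_counts[:, mask].mean(axis=1)
        sigma2 = m + trend * m**2
        v_samp += 2.0 * sigma2**2 / max(n_g - 1, 1)
        den += m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_samp = np.where(den > 0, v_samp / np.maximum(den**2, 1e-300), np.inf)
    if weight == "auto":
        finite = np.isfinite(v_samp)
        centred = np.clip(raw, 0.0, _MAX_DISP) - trend
        total_var = float(np.var(centred[finite])) if finite.any() else 0.0
        prior_var = max(total_var - float(np.median(v_samp[finite])) if finite.any() else 0.0,
                        1e-12)
        w = v_samp / (v_samp + prior_var)
        w = np.where(np.isfinite(w), w, 1.0)
    else:
        w = np.full_like(raw, float(weight))
    shrunk = (1.0 - w) * np.clip(raw, 0.0, _MAX_DISP) + w * trend
    return np.clip(shrunk, _MIN_DISP, _MAX_DISP)


# ---------------------------------------------------------------------------
# The model


class DifferentialTE:
    """NB interaction model for the TE change between two design cells.

    Parameters
    ----------
    counts
        A :class:`~ribote.quant.CountTable` containing paired RPF/RNA
        libraries for both cells of the contrast (>= 2 replicates each).
    contrast
        The named comparison to estimate.
    config
        Analysis thresholds; defaults to :class:`AnalysisConfig()`.
    size_factors_
        Optional per-sample size factors (Series over sample_ids).  By
        default median-of-ratios factors are computed per assay from
        ``counts``.  Pass all-ones to disable depth normalization (used for
        within-library ratios such as RRO).

    Examples
    --------
    >>> model = DifferentialTE(counts, standard_contrasts()[0])
    >>> res = model.fit()
    >>> res.table.head()
    """

    def __init__(
        self,
        counts: CountTable,
        contrast: ContrastSpec,
        config: Optional[AnalysisConfig] = None,
        size_factors_: Optional[pd.Series] = None,
    ):
        self.config = config or AnalysisConfig()
        self.contrast = contrast
        cells = [tuple(contrast.numerator_cell), tuple(contrast.denominator_cell)]
        samples = counts.select(cells=cells)
        for cell in cells:
            for assay in Assay:
                n = len([s for s in samples if s.cell == cell and s.assay == assay])
                if n == 0:
                    raise ValueError(f"contrast {contrast.name}: no {assay.value} samples in cell {cell}")
                if n < 2:
                    raise ValueError(
                        f"contrast {contrast.name}: cell {cell} has {n} {assay.value} replicate(s); >= 2 required"
                    )
        self.counts = counts.subset([s.sample_id for s in samples])
        if size_factors_ is None:
            sf = pd.concat([size_factors(self.counts, a) for a in Assay])
        else:
            sf = size_factors_
        self.size_factors_ = sf.reindex([s.sample_id for s in self.counts.samples])
        if self.size_factors_.isna().any() or (self.size_factors_ <= 0).any():
            raise ValueError("size factors must be positive and cover all contrast samples")
        self._build_design()

    def _build_design(self) -> None:
        samples = self.counts.samples
        num = tuple(self.contrast.numerator_cell)
        is_rpf = np.array([s.assay == Assay.RPF for s in samples], dtype=float)
        is_num = np.array([s.cell == num for s in samples], dtype=float)
        self.exog = np.column_stack([np.ones(len(samples)), is_rpf, is_num, is_rpf * is_num])
        self.exog_names = ["intercept", "assay[RPF]", "cell[num]", "assay[RPF]:cell[num]"]
        self._is_rpf = is_rpf.astype(bool)
        self._is_num = is_num.astype(bool)
        self.offset = np.log(self.size_factors_.to_numpy(dtype=float))

    # -- exclusions ---------------------------------------------------------

    def _exclusion_reasons(self) -> pd.Series:
        c = self.counts.counts
        rna_cols = [s.sample_id for s in self.counts.samples if s.assay == Assay.RNA]
        reasons = pd.Series("", index=c.index, dtype=object)
        reasons[(c[rna_cols] == 0).any(axis=1)] = "zero_rna"
        for cell_mask in (self._is_num, ~self._is_num):
            cols = [
                s.sample_id
                for s, m, r in zip(self.counts.samples, cell_mask, self._is_rpf)
                if m and r
            ]
            allzero = (c[cols] == 0).all(axis=1)
            reasons[allzero & (reasons == "")] = "zero_rpf"
        return reasons

    # -- fitting ------------------------------------------------------------

    def fit(self, method: str = "wald") -> "DifferentialTEResults":
        """Estimate per-gene log2 TE changes.

        ``method="wald"`` (default) tests the interaction coefficient against
        its asymptotic normal distribution; ``method="perm"`` computes an
        exact permutation p-value by re-assigning samples to cells within
        each assay (slower; exact under exchangeability).
        """
        if method not in ("wald", "perm"):
            raise ValueError("method must be 'wald' or 'perm'")
        c = self.counts.counts
        genes = list(c.index)
        reasons = self._exclusion_reasons()
        norm = c.to_numpy(dtype=float) / self.size_factors_.to_numpy(dtype=float)

        # dispersion: groups are the four assay x cell combinations
        masks = [
            (self._is_rpf == a) & (self._is_num == b)
            for a in (True, False)
            for b in (True, False)
        ]
        testable = (reasons == "").to_numpy()
        disp = np.full(len(genes), np.nan)
        if testable.any():
            disp[testable] = shrink_dispersions(
                norm[testable], masks, self.config.dispersion_shrink
            )

        log2_eff = np.full(len(genes), np.nan)
        se = np.full(len(genes), np.nan)
        pvals = np.full(len(genes), np.nan)
        y_all = c.to_numpy(dtype=float)
        for i in np.flatnonzero(testable):
            beta, beta_se = self._fit_gene(y_all[i], disp[i])
            log2_eff[i] = beta / _LN2
            se[i] = beta_se / _LN2
            if method == "wald":
                if beta_se > 0:
                    z = beta / beta_se
                    pvals[i] = 2.0 * scipy.stats.norm.sf(abs(z))
                else:
                    pvals[i] = 1.0
            else:
                pvals[i] = self._perm_pvalue(norm[i])
        q = np.full(len(genes), np.nan)
        if testable.any():
            q[testable] = bh_fdr(pvals[testable])

        status = np.where(testable, "tested", "excluded:" + reasons.to_numpy(dtype=object))
        table = pd.DataFrame(
            {
                "log2_effect": log2_eff,
                "se": se,
                "p": pvals,
                "q": q,
                "status": status,
            },
            index=pd.Index(genes, name="gene"),
        )
        return DifferentialTEResults(
            contrast=self.contrast,
            table=table,
            dispersions=pd.Series(disp, index=genes),
            method=method,
            config=self.config,
        )

    def _fit_gene(self, y: np.ndarray, alpha: float) -> Tuple[float, float]:
        """One NB GLM fit; returns (interaction coefficient, its SE) in natural log."""
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        fam = sm.families.NegativeBinomial(alpha=max(alpha, _MIN_DISP))
        model = sm.GLM(y, self.exog, family=fam, offset=self.offset)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # noiseless fixtures fit exactly and trigger the separation warning
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            try:
                res = model.fit(maxiter=200, tol=1e-10)
            except Exception:  # pragma: no cover - numerical fallback
                return self._moment_effect(y), np.inf
        return float(res.params[3]), float(res.bse[3])

    def _moment_effect(self, y: np.ndarray) -> float:
        norm = y / self.size_factors_.to_numpy(dtype=float)
        return self._ratio_of_ratios(norm, self._is_num)

    def _ratio_of_ratios(self, norm: np.ndarray, is_num: np.ndarray) -> float:
        means = {}
        for a in (True, False):
            for b in (True, False):
                means[(a, b)] = norm[(self._is_rpf == a) & (is_num == b)].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            return float(
                np.log(means[(True, True)])
                - np.log(means[(True, False)])
                - np.log(means[(False, True)])
                + np.log(means[(False, False)])
            )

    def _perm_pvalue(self, norm: np.ndarray) -> float:
        """Exact permutation test re-assigning samples to cells within each assay."""
        from itertools import combinations

        obs = abs(self._ratio_of_ratios(norm, self._is_num))
        stats = []
        rpf_idx = np.flatnonzero(self._is_rpf)
        rna_idx = np.flatnonzero(~self._is_rpf)
        n_rpf_num = int(self._is_num[rpf_idx].sum())
        n_rna_num = int(self._is_num[rna_idx].sum())
        for rpf_num in combinations(rpf_idx, n_rpf_num):
            for rna_num in combinations(rna_idx, n_rna_num):
                is_num = np.zeros_like(self._is_num)
                is_num[list(rpf_num)] = True
                is_num[list(rna_num)] = True
                stats.append(abs(self._ratio_of_ratios(norm, is_num)))
        stats = np.asarray(stats)
        return float((stats >= obs - 1e-12).mean())


class DifferentialTEResults(ContrastResult):
    """Fitted per-gene TE changes with uncertainties and FDR.

    Inherits the :class:`ContrastResult` table contract and adds the fitted
    dispersions, the test method, and presentation helpers.
    """

    def __init__(
        self,
        contrast: ContrastSpec,
        table: pd.DataFrame,
        dispersions: pd.Series,
        method: str,
        config: AnalysisConfig,
    ):
        super().__init__(contrast=contrast, table=table)
        self.dispersions = dispersions
        self.method = method
        self.config = config

    @property
    def log2_effect(self) -> pd.Series:
        return self.table["log2_effect"]

    @property
    def pvalues(self) -> pd.Series:
        return self.table["p"]

    @property
    def qvalues(self) -> pd.Series:
        return self.table["q"]

    def discoveries(self, fdr: Optional[float] = None, direction: str = "both") -> Set[str]:
        fdr = self.contrast.fdr_threshold if fdr is None else fdr
        t = self.tested
        mask = t["q"] < fdr
        if direction == "up":
            mask &= t["log2_effect"] > 0
        elif direction == "down":
            mask &= t["log2_effect"] < 0
        return set(t.index[mask])

    def select_by_fold(self, fold: float, direction: str, fdr: Optional[float] = None) -> Set[str]:
        return select_by_fold(self, fold, direction, fdr)

    def summary(self) -> str:
        t = self.tested
        lines = [
            f"Differential TE contrast: {self.contrast.name}",
            f"  numerator cell:   {tuple(v.value for v in self.contrast.numerator_cell)}",
            f"  denominator cell: {tuple(v.value for v in self.contrast.denominator_cell)}",
            f"  test: NB interaction {self.method}",
            f"  genes tested: {len(t)}   excluded: {len(self.table) - len(t)}",
            f"  discoveries: q<{self.config.fdr_loose:g}: {len(self.discoveries(self.config.fdr_loose))}"
            f"   q<{self.config.fdr_strict:g}: {len(self.discoveries(self.config.fdr_strict))}",
            f"  median log2 dTE (tested): {t['log2_effect'].median():.4f}",
        ]
        top = t.nsmallest(min(5, len(t)), "q")
        if len(top):
            lines.append("  top genes by FDR:")
            for g, row in top.iterrows():
                lines.append(
                    f"    {g}: log2dTE={row.log2_effect:+.3f} +/- {row.se:.3f}"
                    f"  p={row.p:.3g}  q={row.q:.3g}"
                )
        return "\n".join(lines)

    def plot_volcano(self, ax=None, fdr: Optional[float] = None):
        """Volcano plot: log2 dTE vs -log10 FDR, discoveries highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fdr = self.contrast.fdr_threshold if fdr is None else fdr
        t = self.tested
        sig = t["q"] < fdr
        ax.scatter(t.loc[~sig, "log2_effect"], -np.log10(t.loc[~sig, "q"].clip(lower=1e-300)),
                   s=6, c="0.6")
        ax.scatter(t.loc[sig, "log2_effect"], -np.log10(t.loc[sig, "q"].clip(lower=1e-300)),
                   s=8, c="crimson")
        ax.axhline(-np.log10(fdr), ls=":", c="k", lw=0.8)
        ax.set_xlabel(r"log$_2\Delta$TE")
        ax.set_ylabel(r"$-$log$_{10}$ FDR")
        ax.set_title(self.contrast.name)
        return ax


def delta_te(
    counts: CountTable,
    contrast: ContrastSpec,
    config: Optional[AnalysisConfig] = None,
    size_factors_: Optional[pd.Series] = None,
    method: str = "wald",
) -> DifferentialTEResults:
    """Convenience wrapper: build a :class:`DifferentialTE` model and fit it."""
    return DifferentialTE(counts, contrast, config=config, size_factors_=size_factors_).fit(method)
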