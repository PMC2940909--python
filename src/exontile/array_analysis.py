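"""Exon-array expression statistics.

Implements the analysis applied to the leaf/root validation experiment:
median standardisation of log2 signals, a fold-change pre-filter removing
"not changing" genes (normalised fold change inside [0.77, 1.3]),
one-way ANOVA with Benjamini-Hochberg correction and a fold-change
cut-off for differential expression, gene-normalised splicing index for
alternative-splicing candidates, and a one-tailed Welch t-test on 3'/5'
control-probe ratios for labelling bias.

All signal values are log2; fold changes and splicing indices are
reported on the linear scale.  Band and threshold comparisons are done
in log2 space (a monotone transform, so the decision is identical) to
keep boundary cases exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import AnalysisParams, ExpressionMatrix

__all__ = [
    "DEResult",
    "SplicingResult",
    "BiasPair",
    "standardize_to_median",
    "prefilter_fold_change",
    "bh_adjust",
    "de_test",
    "gene_normalize",
    "splicing_index",
    "three_prime_bias",
]


# Boundary comparisons against printed thresholds (0.77, 1.3, 5, ...) are
# made tie-robust: values equal to the threshold up to relative 1e-9 count
# as equal, so last-ulp rounding in mean/normalisation chains cannot flip
# an exact tie.  This is an equality guard, not a band change.
_REL_TOL = 1e-9


def _ge(a: float, b: float) -> bool:
    return a > b or math.isclose(a, b, rel_tol=_REL_TOL, abs_tol=1e-12)


def _le(a: float, b: float) -> bool:
    return a < b or math.isclose(a, b, rel_tol=_REL_TOL, abs_tol=1e-12)


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    fold_change: float  # linear, condition1 / condition2
    statistic: float  # one-way ANOVA F
    p_raw: float
    p_bh: float
    significant: bool


@dataclass(frozen=True)
class SplicingResult:
    probe_set_id: str
    gene_id: str
    splicing_index: float  # linear ratio
    flagged: bool


@dataclass(frozen=True)
class BiasPair:
    """A 5'/3' control-probe pair on one control transcript."""

    control_gene: str
    probe5_signal: float  # log2
    probe3_signal: float  # log2
    tissue: str = ""

    @property
    def ratio(self) -> float:
        """Linear 3'/5' signal ratio."""
        return 2.0 ** (self.probe3_signal - self.probe5_signal)


def standardize_to_median(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each probe set's median log2 signal across samples
    (division by the median on the linear scale)."""
    centred = matrix.values.sub(matrix.values.median(axis=1), axis=0)
    return ExpressionMatrix(
        values=centred,
        condition_of=dict(matrix.condition_of),
        gene_of=dict(matrix.gene_of),
    )


def prefilter_fold_change(
    matrix: ExpressionMatrix, params: AnalysisParams | None = None
) -> list[str]:
    """Genes retained after removing the "not changing" fold-change band.

    Gene-level signal is the mean of the gene's probe sets; the fold
    change between condition means (conditions in sorted label order) is
    compared against the inclusive band [prefilter_low, prefilter_high].
    With more than two conditions a gene is removed only when every
    pairwise fold change lies inside the band.
    """
    params = params or AnalysisParams()
    lo = math.log2(params.prefilter_low)
    hi = math.log2(params.prefilter_high)
    gene_values = matrix.gene_level()
    conditions = matrix.conditions
    if len(conditions) < 2:
        raise ValueError("pre-filter requires >= 2 conditions")
    cond_means = {
        c: gene_values[matrix.samples_of(c)].mean(axis=1) for c in conditions
    }
    retained: list[str] = []
    for gene in gene_values.index:
        diffs = [
            cond_means[c1][gene] - cond_means[c2][gene]
            for i, c1 in enumerate(conditions)
            for c2 in conditions[i + 1 :]
        ]
        inside = all(_ge(d, lo) and _le(d, hi) for d in diffs)
        if not inside:
            retained.append(gene)
    return retained


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_i = min_{j >= i} (p_(j) * m / j), clipped at 1, where p_(j) are
    the sorted raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def de_test(
    matrix: ExpressionMatrix, params: AnalysisParams | None = None
) -> list[DEResult]:
    """Per-gene one-way ANOVA across conditions with BH correction.

    Significance requires BH-corrected p < de_alpha AND linear fold
    change (either direction) > de_fold_change.  Intended to run on the
    pre-filtered gene set (subset the matrix first).  A condition with
    fewer than two replicates is a hard error.
    """
    params = params or AnalysisParams()
    gene_values = matrix.gene_level()
    conditions = matrix.conditions
    if len(conditions) < 2:
        raise ValueError("ANOVA requires >= 2 conditions")
    groups_samples = {c: matrix.samples_of(c) for c in conditions}
    for c, samples in groups_samples.items():
        if len(samples) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 replicates")

    genes = list(gene_values.index)
    f_stats: list[float] = []
    p_raw: list[float] = []
    fold: list[float] = []
    c1, c2 = conditions[0], conditions[1]
    for gene in genes:
        groups = [gene_values.loc[gene, groups_samples[c]].to_numpy() for c in conditions]
        if np.ptp(np.concatenate(groups)) == 0:
            f_val, p_val = 0.0, 1.0
        else:
            f_val, p_val = stats.f_oneway(*groups)
            if np.isnan(f_val):
                f_val, p_val = 0.0, 1.0
            elif np.isinf(f_val):
                # zero within-group variance with distinct group means:
                # perfect separation
                p_val = 0.0
        f_stats.append(float(f_val))
        p_raw.append(float(p_val))
        d = float(
            gene_values.loc[gene, groups_samples[c1]].mean()
            - gene_values.loc[gene, groups_samples[c2]].mean()
        )
        fold.append(2.0 ** d)
    p_bh = bh_adjust(p_raw)
    results = []
    for gene, f_val, pr, pb, fc in zip(genes, f_stats, p_raw, p_bh, fold):
        sig = pb < params.de_alpha and max(fc, 1.0 / fc) > params.de_fold_change
        results.append(
            DEResult(
                gene_id=gene,
                fold_change=fc,
                statistic=f_val,
                p_raw=pr,
                p_bh=float(pb),
                significant=sig,
            )
        )
    return results


def gene_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per sample, subtract from each probe set the mean log2 signal of
    all probe sets of its gene (division by the gene signal on the
    linear scale).  Removes gene-level expression changes, leaving
    exon-specific deviations."""
    genes = pd.Series({p: matrix.gene_of[p] for p in matrix.values.index})
    gene_means = matrix.values.groupby(genes).transform("mean")
    return ExpressionMatrix(
        values=matrix.values - gene_means,
        condition_of=dict(matrix.condition_of),
        gene_of=dict(matrix.gene_of),
    )


def splicing_index(
    matrix: ExpressionMatrix,
    condition_pair: tuple[str, str],
    params: AnalysisParams | None = None,
) -> list[SplicingResult]:
    """Splicing index per probe set between two conditions.

    Expects a gene-normalised matrix (see :func:`gene_normalize`).  The
    index is the contrast of mean gene-normalised log2 intensities,
    reported as a linear ratio; a probe set is flagged when the index
    (in either direction) reaches ``splicing_index_min``.  With
    ``si_scale='log2'`` the threshold applies to |log2 contrast| instead.
    """
    params = params or AnalysisParams()
    c1, c2 = condition_pair
    s1, s2 = matrix.samples_of(c1), matrix.samples_of(c2)
    if not s1 or not s2:
        raise ValueError(f"conditions {condition_pair} not both present")
    d = matrix.values[s1].mean(axis=1) - matrix.values[s2].mean(axis=1)
    if params.si_scale == "log2":
        threshold = params.splicing_index_min
    else:
        threshold = math.log2(params.splicing_index_min)
    flagged_mask = d.abs().apply(lambda v: _ge(v, threshold))
    results = []
    for probe_set in matrix.values.index:
        results.append(
            SplicingResult(
                probe_set_id=probe_set,
                gene_id=matrix.gene_of[probe_set],
                splicing_index=2.0 ** float(d[probe_set]),
                flagged=bool(flagged_mask[probe_set]),
            )
        )
    return results


def three_prime_bias(
    platform_a_pairs: Sequence[BiasPair],
    platform_b_pairs: Sequence[BiasPair],
    params: AnalysisParams | None = None,
) -> tuple[list[float], list[float], float, float]:
    """One-tailed Welch t-test comparing 3'/5' control ratios between
    two platforms.

    Returns (platform A ratios, platform B ratios, t statistic,
    one-tailed p).  The default alternative ('greater') tests whether
    platform B is more 3'-biased than platform A.
    """
    params = params or AnalysisParams()
    ratios_a = [p.ratio for p in platform_a_pairs]
    ratios_b = [p.ratio for p in platform_b_pairs]
    if len(ratios_a) < 2 or len(ratios_b) < 2:
        raise ValueError("need >= 2 ratios per platform")
    t_stat, p_val = stats.ttest_ind(
        ratios_b, ratios_a, equal_var=False, alternative=params.bias_alternative
    )
    return ratios_a, ratios_b, float(t_stat), float(p_val)
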