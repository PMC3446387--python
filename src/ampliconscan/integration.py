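"""Copy-number / expression integration: genes overexpressed when amplified.

Clone-level smoothed log2 ratios are mapped to genes as the median over all
clones whose genomic interval overlaps the gene (half-open overlap), giving
a 1:1 matrix of expression and copy-number values per gene and sample.
Expression probes failing detection (detection P >= 0.01 in at least 75% of
samples) are removed first.

A gene is flagged "overexpressed when amplified" when the two-sided
Mann-Whitney U test comparing its expression between amplified and
non-amplified samples (grouping by the gene-level categorical state) gives
P < alpha AND the amplified group's median expression is the larger.
Per the source analysis convention, no multiple-testing correction is
applied to the flags; Benjamini-Hochberg q-values are emitted alongside
for reference.  Pearson's r between the continuous smoothed values and
expression is reported per gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .states import STATE_CODES, AMPLIFICATION, StateThresholds, call_states

__all__ = [
    "detection_filter",
    "gene_cn",
    "pearson_cn_expression",
    "mann_whitney",
    "overexpressed_when_amplified",
]


def detection_filter(
    expression: pd.DataFrame,
    detection_p: pd.DataFrame,
    p_cut: float = 0.01,
    sample_fraction: float = 0.25,
) -> pd.DataFrame:
    """Keep probes detected (P < p_cut) in strictly more than sample_fraction of samples."""
    if expression.shape != detection_p.shape:
        raise ValueError("expression and detection-P matrices must share dimensions")
    detected_frac = (detection_p.to_numpy() < p_cut).mean(axis=1)
    return expression.loc[detected_frac > sample_fraction]


def gene_cn(
    smoothed: pd.DataFrame,
    genes: pd.DataFrame,
    thresholds: StateThresholds = StateThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene smoothed copy-number value and state.

    ``smoothed`` carries clone_id/chrom/start/end plus one column per
    sample; ``genes`` carries symbol/chrom/start/end (0-based half-open).
    Gene value = median of the smoothed values of clones overlapping the
    gene; genes with no overlapping clone are returned as all-NaN rows
    (excluded from downstream tests).

    Returns (values, states) as gene x sample DataFrames; states use the
    codes -1/0/1/2.
    """
    samples = [c for c in smoothed.columns if c not in ("clone_id", "chrom", "start", "end")]
    values = np.full((len(genes), len(samples)), np.nan)
    chroms = smoothed["chrom"].to_numpy()
    starts = smoothed["start"].to_numpy()
    ends = smoothed["end"].to_numpy()
    mat = smoothed[samples].to_numpy(dtype=float)
    for gi, gene in enumerate(genes.itertuples(index=False)):
        hit = (chroms == gene.chrom) & (starts < gene.end) & (ends > gene.start)
        if hit.any():
            values[gi] = np.nanmedian(mat[hit], axis=0)
    vals = pd.DataFrame(values, index=list(genes["symbol"]), columns=samples)
    return vals, call_states(vals, thresholds)


def pearson_cn_expression(cn_values: np.ndarray, expression: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation of paired (smoothed value, expression).

    Returns (r, P) where P comes from the standard t transform.  Fewer than
    3 complete pairs or zero variance on either axis -> (nan, nan).
    """
    x = np.asarray(cn_values, dtype=float)
    y = np.asarray(expression, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def mann_whitney(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: (U, P).

    Exact null enumeration when both groups have <= 8 observations and the
    pooled values contain no ties; the tie-corrected normal approximation
    (with continuity correction) otherwise.  U is reported in the classical
    min(U_a, U_b) orientation.  All-identical pooled values give P = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    return u, float(res.pvalue)


def overexpressed_when_amplified(
    cn_values: pd.DataFrame,
    cn_states: pd.DataFrame,
    expression: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene amplified-vs-not expression test and copy-number correlation.

    For each gene present in both matrices with at least one amplified and
    one non-amplified sample, computes the two-sided Mann-Whitney U P-value
    (amplification as grouping variable), group sizes and medians, Pearson
    r on the continuous smoothed values, and the
    ``overexpressed_when_amplified`` flag (P < alpha and amplified median
    greater).  BH q-values are added for reference but do not drive flags.
    """
    shared_genes = [g for g in cn_values.index if g in expression.index]
    shared_samples = [s for s in cn_values.columns if s in expression.columns]
    rows = []
    for gene in shared_genes:
        cn = cn_values.loc[gene, shared_samples].to_numpy(dtype=float)
        st = cn_states.loc[gene, shared_samples].to_numpy(dtype=float)
        ex = expression.loc[gene, shared_samples].to_numpy(dtype=float)
        ok = np.isfinite(cn) & np.isfinite(ex) & np.isfinite(st)
        cn, st, ex = cn[ok], st[ok], ex[ok]
        amp = st == STATE_CODES[AMPLIFICATION]
        n_amp, n_not = int(amp.sum()), int((~amp).sum())
        if n_amp == 0 or n_not == 0:
            rows.append(
                dict(symbol=gene, n_amplified=n_amp, n_not_amplified=n_not,
                     u=np.nan, p_mwu=np.nan, median_amplified=np.nan,
                     median_not_amplified=np.nan, pearson_r=np.nan, pearson_p=np.nan,
                     overexpressed_when_amplified=False, tested=False)
            )
            continue
        u, p = mann_whitney(ex[amp], ex[~amp])
        med_amp = float(np.median(ex[amp]))
        med_not = float(np.median(ex[~amp]))
        r, rp = pearson_cn_expression(cn, ex)
        rows.append(
            dict(symbol=gene, n_amplified=n_amp, n_not_amplified=n_not,
                 u=u, p_mwu=p, median_amplified=med_amp, median_not_amplified=med_not,
                 pearson_r=r, pearson_p=rp,
                 overexpressed_when_amplified=bool(p < alpha and med_amp > med_not),
                 tested=True)
        )
    result = pd.DataFrame(rows).set_index("symbol")
    # BH q-values over the tested genes (reference column, not used for flags)
    result["q_bh"] = np.nan
    tested = result.index[result["tested"]]
    if len(tested):
        p = result.loc[tested, "p_mwu"].to_numpy(dtype=float)
        order = np.argsort(p)
        m = p.size
        q = np.empty(m)
        q[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        result.loc[tested, "q_bh"] = np.minimum(q, 1.0)
    return result
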