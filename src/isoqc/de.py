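"""Differential-expression engine.

Counts in, per-feature logFC / p / q out: trimmed-mean-of-M-values scale
factors, isoform-to-gene aggregation, a two-group negative-binomial
exact-style test with a moment-estimated common dispersion, Benjamini-
Hochberg correction and the |logFC| >= 1.5 & FDR < 0.05 subset filter.
Counts can be binomially thinned to emulate lower sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_qvalues

__all__ = [
    "DEResult",
    "tmm_factors",
    "aggregate_gene_counts",
    "estimate_common_dispersion",
    "de_test",
    "threshold_filter",
    "downsample_counts",
]

DISPERSION_FLOOR = 1e-4


@dataclass
class DEResult:
    table: pd.DataFrame  # columns: logFC, p_value, q_value, mean_expr
    condition_order: tuple[str, str]
    dispersion: float


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors against a reference sample.

    M-values are gene-wise log2 ratios of raw counts versus the reference
    sample (the one whose upper quartile is closest to the mean upper
    quartile), doubly trimmed by M (30%) and by average intensity (5%),
    combined by precision weights; factors are rescaled to geometric mean
    one. Dividing a sample's counts by its factor puts samples on a common
    scale (the factor absorbs sequencing depth).
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    libsizes = counts.sum(axis=0)
    if (libsizes <= 0).any():
        bad = list(libsizes.index[libsizes <= 0])
        raise ValueError(f"zero-count sample(s): {bad}")
    uq = counts.apply(lambda col: np.percentile(col, 75), axis=0)
    ref_name = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_name].to_numpy(dtype=float)

    log_factors = {}
    for name in counts.columns:
        obs = counts[name].to_numpy(dtype=float)
        mask = (obs > 0) & (ref > 0)
        if name == ref_name or not mask.any():
            log_factors[name] = 0.0
            continue
        o, r = obs[mask], ref[mask]
        m = np.log2(o / r)
        a = 0.5 * np.log2(o * r)
        w = 1.0 / o + 1.0 / r  # delta-method variance of M
        n = m.size
        m_lo, m_hi = np.floor(n * logratio_trim), np.ceil(n * (1 - logratio_trim))
        a_lo, a_hi = np.floor(n * sum_trim), np.ceil(n * (1 - sum_trim))
        m_rank = sps.rankdata(m, method="ordinal")
        a_rank = sps.rankdata(a, method="ordinal")
        keep = (
            (m_rank > m_lo)
            & (m_rank <= m_hi)
            & (a_rank > a_lo)
            & (a_rank <= a_hi)
        )
        if not keep.any():
            log_factors[name] = 0.0
            continue
        log_factors[name] = float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))

    f = pd.Series(log_factors).loc[counts.columns]
    f -= f.mean()  # geometric mean of 2**f becomes 1
    return 2.0**f


def aggregate_gene_counts(
    counts: pd.DataFrame, tx2gene: dict[str, str]
) -> pd.DataFrame:
    """Sum transcript counts per gene; column sums are preserved."""
    missing = [t for t in counts.index if t not in tx2gene]
    if missing:
        raise KeyError(f"unmapped transcripts: {missing[:10]}")
    genes = pd.Series({t: tx2gene[t] for t in counts.index})
    out = counts.groupby(genes).sum()
    out.index.name = counts.index.name
    return out


def estimate_common_dispersion(
    norm: np.ndarray, group1: np.ndarray, group2: np.ndarray
) -> float:
    """Method-of-moments common NB dispersion on normalized counts.

    Per feature: pooled within-group variance v and grand mean m give
    phi = (v - m) / m^2; the median over sufficiently expressed features
    is floored at ``DISPERSION_FLOOR``.
    """
    n1, n2 = group1.sum(), group2.sum()
    m1 = norm[:, group1].mean(axis=1)
    m2 = norm[:, group2].mean(axis=1)
    v1 = norm[:, group1].var(axis=1, ddof=1)
    v2 = norm[:, group2].var(axis=1, ddof=1)
    v = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    m = (n1 * m1 + n2 * m2) / (n1 + n2)
    ok = m > 1.0
    if not ok.any():
        return DISPERSION_FLOOR
    phi = (v[ok] - m[ok]) / m[ok] ** 2
    return float(max(np.median(phi), DISPERSION_FLOOR))


def _nb_exact_pvalue(
    sum1: float, n1: int, sum2: float, n2: int, phi: float
) -> float:
    """Conditional two-group NB test on equal-scale group sums.

    The group sums are NB with shared per-sample mean under H0; the
    two-sided p-value sums, over the conditional support, the outcomes no
    more probable than the observed split.
    """
    t = int(round(sum1 + sum2))
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)
    r1, r2 = n1 / phi, n2 / phi
    p1 = r1 / (r1 + n1 * mu)
    p2 = r2 / (r2 + n2 * mu)
    if t > 100_000:
        # normal approximation for very large totals
        var = (mu + phi * mu**2) * (1.0 / n1 + 1.0 / n2)
        z = (sum1 / n1 - sum2 / n2) / np.sqrt(var)
        return float(2 * sps.norm.sf(abs(z)))
    support = np.arange(t + 1)
    logq = sps.nbinom.logpmf(support, r1, p1) + sps.nbinom.logpmf(
        t - support, r2, p2
    )
    logq -= logq.max()
    q = np.exp(logq)
    q /= q.sum()
    obs = q[int(round(sum1))]
    return float(q[q <= obs * (1 + 1e-10)].sum())


def de_test(
    counts: pd.DataFrame,
    design: pd.Series,
    norm_factors: pd.Series | None = None,
    dispersion: float | None = None,
    conditions: tuple[str, str] | None = None,
) -> DEResult:
    """Two-group differential expression on a feature x sample matrix.

    Features with zero counts across all samples are removed before
    testing. logFC is condition 1 vs condition 2 from normalized group
    means with a 0.5 pseudo-count; condition order defaults to first
    appearance in ``design``.
    """
    if conditions is None:
        conditions = list(pd.unique(design.loc[counts.columns]))
    else:
        conditions = list(conditions)
    if len(conditions) != 2 or set(conditions) != set(
        design.loc[counts.columns]
    ):
        raise ValueError("exactly two conditions required")
    labels = design.loc[counts.columns].to_numpy()
    g1 = labels == conditions[0]
    g2 = labels == conditions[1]
    if (g1.sum() < 2 or g2.sum() < 2) and dispersion is None:
        raise ValueError(
            "a condition with a single sample requires a supplied dispersion"
        )
    counts = counts.loc[counts.sum(axis=1) > 0]
    if norm_factors is None:
        norm_factors = tmm_factors(counts)
    factors = norm_factors.loc[counts.columns].to_numpy(dtype=float)
    raw = counts.to_numpy(dtype=float)
    norm = raw / factors

    if dispersion is None:
        dispersion = estimate_common_dispersion(norm, g1, g2)

    # equalize scales by adjusting counts to the common (geometric-mean)
    # factor so the conditional test sees exchangeable samples
    adj = np.rint(norm).astype(np.int64)
    sum1 = adj[:, g1].sum(axis=1)
    sum2 = adj[:, g2].sum(axis=1)
    pvals = np.array(
        [
            _nb_exact_pvalue(s1, int(g1.sum()), s2, int(g2.sum()), dispersion)
            for s1, s2 in zip(sum1, sum2)
        ]
    )
    mean1 = norm[:, g1].mean(axis=1)
    mean2 = norm[:, g2].mean(axis=1)
    logfc = np.log2((mean1 + 0.5) / (mean2 + 0.5))
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "p_value": pvals,
            "q_value": bh_qvalues(pvals),
            "mean_expr": norm.mean(axis=1),
        },
        index=counts.index,
    )
    return DEResult(table, (str(conditions[0]), str(conditions[1])), dispersion)


def threshold_filter(
    res: DEResult, lfc: float = 1.5, fdr: float = 0.05
) -> pd.DataFrame:
    """Features with |logFC| >= lfc (inclusive) and q < fdr, with an
    up/down direction column."""
    t = res.table
    keep = (t["logFC"].abs() >= lfc) & (t["q_value"] < fdr)
    out = t.loc[keep].copy()
    out["direction"] = np.where(out["logFC"] > 0, "up", "down")
    return out


def downsample_counts(
    counts: pd.DataFrame, fraction: float, seed: int
) -> pd.DataFrame:
    """Binomial thinning of every cell with the given keep probability."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return counts.copy()
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(counts.to_numpy(dtype=np.int64), fraction)
    return pd.DataFrame(thinned, index=counts.index, columns=counts.columns)
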