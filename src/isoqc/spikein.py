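"""Spike-in sensitivity analysis.

TPM computation, expected log-fold-changes between the two concentration
mixes, broken-stick limit-of-quantification (LOQ) estimation, and the
expected-vs-observed regression report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SequinMix",
    "LOQResult",
    "SensitivityReport",
    "tpm_from_counts",
    "expected_logfc",
    "estimate_loq",
    "sensitivity_report",
    "read_mix_table",
    "write_mix_table",
]


@dataclass
class SequinMix:
    """Known concentrations per spike-in for the two mixes, plus the
    per-sample mix assignment (alternating across conditions)."""

    mix_a: dict[str, float]
    mix_b: dict[str, float]
    lengths: dict[str, int] = field(default_factory=dict)
    sample_mix: dict[str, str] = field(default_factory=dict)  # sample -> {A, B}

    def __post_init__(self) -> None:
        for mix in (self.mix_a, self.mix_b):
            for sid, c in mix.items():
                if c <= 0:
                    raise ValueError(f"non-positive concentration for {sid}")
        for s, m in self.sample_mix.items():
            if m not in ("A", "B"):
                raise ValueError(f"sample {s} assigned unknown mix {m!r}")

    def ids(self) -> list[str]:
        return sorted(set(self.mix_a) & set(self.mix_b))


def read_mix_table(path) -> SequinMix:
    """TSV columns: sequin_id, mixA_conc, mixB_conc, length."""
    df = pd.read_csv(path, sep="\t")
    return SequinMix(
        mix_a=dict(zip(df["sequin_id"], df["mixA_conc"].astype(float))),
        mix_b=dict(zip(df["sequin_id"], df["mixB_conc"].astype(float))),
        lengths=dict(zip(df["sequin_id"], df["length"].astype(int))),
    )


def write_mix_table(mix: SequinMix, path) -> None:
    rows = [
        {
            "sequin_id": sid,
            "mixA_conc": mix.mix_a[sid],
            "mixB_conc": mix.mix_b[sid],
            "length": mix.lengths.get(sid, 1000),
        }
        for sid in mix.ids()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def tpm_from_counts(
    counts: pd.DataFrame, effective_lengths: pd.Series
) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates rescaled to sum to
    1e6 per sample."""
    lengths = effective_lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be > 0")
    rate = counts.div(lengths, axis=0)
    total = rate.sum(axis=0)
    tpm = rate.div(total.where(total > 0, 1.0), axis=1) * 1e6
    return tpm


def expected_logfc(mix: SequinMix, formula: str = "standard") -> pd.Series:
    """Expected log-fold change B vs A per spike-in.

    ``standard``: log2(MixB / MixA). ``literal``: log2(MixB/MixA - 1) + 1,
    the printed form, which is undefined when MixB <= MixA; such entries
    raise. The two coincide at a ratio of exactly 2.
    """
    out = {}
    for sid in mix.ids():
        ratio = mix.mix_b[sid] / mix.mix_a[sid]
        if formula == "standard":
            out[sid] = float(np.log2(ratio))
        elif formula == "literal":
            if ratio <= 1:
                raise ValueError(
                    f"literal expected-logFC undefined for {sid}: "
                    f"MixB/MixA = {ratio:.4g} <= 1"
                )
            out[sid] = float(np.log2(ratio - 1) + 1)
        else:
            raise ValueError(f"unknown formula {formula!r}")
    return pd.Series(out).sort_index()


@dataclass
class LOQResult:
    breakpoint_concentration: float
    below_slope: float
    below_intercept: float
    above_slope: float
    above_intercept: float
    total_sse: float
    single_line_sse: float


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept, SSE; a flat fit when degenerate."""
    if x.size == 0:
        return 0.0, 0.0, 0.0
    if x.size == 1 or np.ptp(x) == 0:
        b = float(y.mean())
        return 0.0, b, float(((y - b) ** 2).sum())
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float((resid**2).sum())


def _fit_left(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Left segment may be flat (detection floor) or a free line; keep the
    smaller SSE."""
    s, b, sse = _fit_line(x, y)
    b_flat = float(y.mean()) if y.size else 0.0
    sse_flat = float(((y - b_flat) ** 2).sum())
    if sse_flat <= sse:
        return 0.0, b_flat, sse_flat
    return s, b, sse


def estimate_loq(
    concentrations: np.ndarray,
    abundances: np.ndarray,
    min_points: int = 4,
    pseudo_tpm: float = 0.01,
) -> LOQResult:
    """Broken-stick regression of log2 abundance on log2 concentration.

    Candidate breakpoints are the observed concentrations; for each, the
    points strictly below form the left segment (flat or free slope) and
    the rest the right segment, both fit by least squares. The breakpoint
    minimizing total SSE is the LOQ; if a single line does as well (within
    1e-9), the LOQ is the minimum observed concentration.
    """
    conc = np.asarray(concentrations, dtype=float)
    tpm = np.asarray(abundances, dtype=float)
    if conc.shape != tpm.shape:
        raise ValueError("concentrations and abundances must align")
    distinct = np.unique(conc)
    if distinct.size < min_points:
        raise ValueError(f"need >= {min_points} distinct concentrations")
    x = np.log2(conc)
    y = np.log2(tpm + pseudo_tpm)

    single_slope, single_b, single_sse = _fit_line(x, y)

    best = None
    for c in distinct[1:-1]:  # leave at least one point on each side
        left = conc < c
        right = ~left
        if left.sum() < 2 or right.sum() < 2:
            continue
        ls, lb, lsse = _fit_left(x[left], y[left])
        rs, rb, rsse = _fit_line(x[right], y[right])
        total = lsse + rsse
        if best is None or total < best[0] - 1e-15:
            best = (total, float(c), ls, lb, rs, rb)

    if best is None or single_sse <= best[0] + 1e-9:
        return LOQResult(
            breakpoint_concentration=float(distinct[0]),
            below_slope=single_slope,
            below_intercept=single_b,
            above_slope=single_slope,
            above_intercept=single_b,
            total_sse=single_sse,
            single_line_sse=single_sse,
        )
    total, c, ls, lb, rs, rb = best
    return LOQResult(c, ls, lb, rs, rb, total, single_sse)


@dataclass
class SensitivityReport:
    slope: float
    intercept: float
    r_squared: float
    n_pairs: int
    n_excluded: int
    table: pd.DataFrame  # per-sequin expected and observed logFC


def sensitivity_report(
    expected: pd.Series, observed: pd.Series
) -> SensitivityReport:
    """OLS of observed on expected logFC with R^2; undefined expected
    values are excluded and counted."""
    joined = pd.concat(
        {"expected": expected, "observed": observed}, axis=1
    ).replace([np.inf, -np.inf], np.nan)
    n_excluded = int(joined.isna().any(axis=1).sum())
    joined = joined.dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 paired finite values")
    fit = sps.linregress(joined["expected"], joined["observed"])
    return SensitivityReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_pairs=len(joined),
        n_excluded=n_excluded,
        table=joined,
    )
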