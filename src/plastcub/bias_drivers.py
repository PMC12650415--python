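"""Mutation-versus-selection diagnostics of codon usage.

Three classical gene-level diagnostics are provided:

* the neutrality plot — ordinary least squares of GC12 on GC3 across the
  genes of one species; a slope near 1 indicates mutation-driven usage,
  near 0 selection-driven, and 100*slope is read as the percentage of
  variance attributable to mutation pressure;
* the ENC-plot — observed ENC against GC3s compared with the mutation-only
  expectation ENC_exp = 2 + GC3s + 29/(GC3s^2 + (1-GC3s)^2), summarized by
  the relative deviation (ENC_exp - ENC_obs)/ENC_exp binned into width-0.1
  intervals centred so one bin spans [-0.05, 0.05);
* the parity-rule-2 plot — per-gene point (G3/(G3+C3), A3/(A3+T3)); the
  centre (0.5, 0.5) is strand-symmetric, unbiased usage.

A Pearson correlation matrix over the per-gene composition metrics rounds
out the diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codon_usage import GeneCUBProfile


@dataclass
class NeutralPlotResult:
    slope: float
    intercept: float
    r: float
    r2: float
    p_value: float
    stderr: float
    mutation_pct: float
    selection_pct: float
    points: list[tuple[str, float, float]]  # (gene, gc3, gc12)


@dataclass
class ENCPlotPoint:
    gene: str
    gc3s: float
    enc_obs: float
    enc_exp: float
    dev: float


@dataclass
class ENCPlotResult:
    points: list[ENCPlotPoint]
    bins: dict[tuple[float, float], float]  # [lo, hi) -> frequency


@dataclass
class PR2Point:
    gene: str
    x: float | None  # G3/(G3+C3)
    y: float | None  # A3/(A3+T3)
    quadrant: str = ""


def neutral_plot(profiles: list[GeneCUBProfile]) -> NeutralPlotResult:
    """OLS regression of GC12 on GC3 over the genes of one species."""
    pts = [(p.gene, p.gc3, p.gc12) for p in profiles]
    if len(pts) < 3:
        raise ValueError("neutral_plot needs at least three genes")
    x = np.array([p[1] for p in pts])
    y = np.array([p[2] for p in pts])
    if np.ptp(x) == 0:
        return NeutralPlotResult(
            slope=math.nan, intercept=math.nan, r=math.nan, r2=math.nan,
            p_value=math.nan, stderr=math.nan, mutation_pct=math.nan,
            selection_pct=math.nan,
            points=pts,
        )
    fit = stats.linregress(x, y)
    return NeutralPlotResult(
        slope=fit.slope,
        intercept=fit.intercept,
        r=fit.rvalue,
        r2=fit.rvalue**2,
        p_value=fit.pvalue,
        stderr=fit.stderr,
        mutation_pct=100.0 * fit.slope,
        selection_pct=100.0 * (1.0 - fit.slope),
        points=pts,
    )


def enc_expected(gc3s: float) -> float:
    """Mutation-only ENC expectation at a given GC3s."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError("gc3s must be in [0, 1]")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)


_BIN_WIDTH = 0.1
_BIN_OFFSET = -0.05  # so one bin is exactly [-0.05, 0.05)


def _dev_bin(dev: float) -> tuple[float, float]:
    k = math.floor((dev - _BIN_OFFSET) / _BIN_WIDTH)
    lo = _BIN_OFFSET + k * _BIN_WIDTH
    return (round(lo, 10), round(lo + _BIN_WIDTH, 10))


def enc_plot(profiles: list[GeneCUBProfile]) -> ENCPlotResult:
    """Per-gene ENC deviation from the standard curve plus its binned
    frequency distribution (left-closed, right-open bins; frequencies sum
    to 1 over the genes with defined ENC and GC3s)."""
    points = []
    for p in profiles:
        if p.enc is None or p.gc3s is None:
            continue
        exp = enc_expected(p.gc3s)
        points.append(
            ENCPlotPoint(gene=p.gene, gc3s=p.gc3s, enc_obs=p.enc, enc_exp=exp,
                         dev=(exp - p.enc) / exp)
        )
    bins: dict[tuple[float, float], float] = {}
    for pt in points:
        b = _dev_bin(pt.dev)
        bins[b] = bins.get(b, 0) + 1
    if points:
        bins = {b: n / len(points) for b, n in sorted(bins.items())}
    return ENCPlotResult(points=points, bins=bins)


def pr2(profile: GeneCUBProfile) -> PR2Point:
    """Parity-rule-2 coordinates of one gene; coordinates are None when a
    denominator is zero."""
    gc = profile.g3 + profile.c3
    at = profile.a3 + profile.t3
    x = profile.g3 / gc if gc else None
    y = profile.a3 / at if at else None
    quadrant = ""
    if x is not None and y is not None:
        quadrant = ("upper" if y >= 0.5 else "lower") + " " + ("right" if x >= 0.5 else "left")
    return PR2Point(gene=profile.gene, x=x, y=y, quadrant=quadrant)


_CORR_VARS = ("gc1", "gc2", "gc3", "gc_all", "enc", "codon_no")


def correlation_matrix(rows: pd.DataFrame | list[dict], variables=_CORR_VARS):
    """Pairwise Pearson r and two-sided p over the composition metrics.

    Returns (r, p, marks) DataFrames; marks are '**' for p < 0.01, '*' for
    p < 0.05, '' otherwise. Constant columns give NaN for their pairs.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    variables = [v for v in variables if v in df.columns]
    if len(df) < 3:
        raise ValueError("correlation_matrix needs at least three rows")
    n = len(variables)
    r = pd.DataFrame(np.full((n, n), np.nan), index=variables, columns=variables)
    p = r.copy()
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            xa = df[a].astype(float).to_numpy()
            xb = df[b].astype(float).to_numpy()
            ok = ~(np.isnan(xa) | np.isnan(xb))
            if ok.sum() < 3 or np.ptp(xa[ok]) == 0 or np.ptp(xb[ok]) == 0:
                continue
            res = stats.pearsonr(xa[ok], xb[ok])
            r.iloc[i, j] = res.statistic
            p.iloc[i, j] = res.pvalue
    marks = p.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else ""))
    return r, p, marks
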