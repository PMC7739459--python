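"""Mutation-vs-selection diagnostics: neutrality plot and ENc plot.

The neutrality plot regresses per-gene GC12 on GC3: a slope near 1
means the same mutational process drives all codon positions, a slope
near 0 means selective constraint.  The ENc plot compares observed ENc
against the expectation under pure GC3s composition,
``ENc_exp = 2 + F + 29 / (F^2 + (1-F)^2)``, and summarises the relative
deviation ``d = (ENc_exp - ENc_obs) / ENc_exp`` as a histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .metrics import GeneMetrics


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of GC12 on GC3 for one species."""

    slope: float | None
    intercept: float | None
    r2: float
    p_value: float | None
    n_genes: int


@dataclass(frozen=True)
class EncPlotPoint:
    """One gene on the ENc plot: observed vs composition-expected ENc."""

    gene_id: str
    gc3s_fraction: float
    enc_obs: float
    enc_exp: float
    deviation: float


@dataclass
class DeviationHistogram:
    """Binned relative ENc deviations, width 0.05 over [-1, 1].

    ``fractions[i]`` is the gene fraction in ``[edges[i], edges[i+1])``;
    the first and last bins absorb any underflow/overflow.
    ``fraction_in_0_01`` is the mass in [0, 0.1).
    """

    edges: np.ndarray
    fractions: np.ndarray
    fraction_in_0_01: float
    n_genes: int


def neutrality_regression(
    gc12: list[float], gc3: list[float]
) -> RegressionResult:
    """Ordinary least squares of GC12 (percent) on GC3 (percent).

    Returns slope, intercept, r-squared and the two-sided t-test
    p-value for slope = 0.  Zero variance in GC3 leaves the slope
    undefined (``None``); fewer than 3 genes is an error.
    """
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    if x.shape != y.shape:
        raise ValueError("gc12 and gc3 must be paired lists of equal length")
    if x.size < 3:
        raise ValueError("neutrality regression needs at least 3 genes")
    if np.ptp(x) == 0:
        return RegressionResult(None, None, 0.0, None, int(x.size))
    if np.ptp(y) == 0:
        # constant response: exact zero slope, no explained variance
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_genes=int(x.size),
    )


def expected_enc(f):
    """Expected ENc when codon usage is set by GC3s composition alone.

    ``f`` is the GC3s fraction in [0, 1] (scalar or array); returns
    ``2 + f + 29 / (f^2 + (1-f)^2)``.
    """
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("GC3s fraction must lie in [0, 1]")
    value = 2.0 + arr + 29.0 / (arr**2 + (1.0 - arr) ** 2)
    return float(value) if np.isscalar(f) or arr.ndim == 0 else value


def enc_plot_table(
    metrics: list[GeneMetrics],
) -> tuple[list[EncPlotPoint], int]:
    """One ENc-plot point per gene with defined ENc and GC3s.

    Returns the points plus the number of genes omitted for undefined
    values, so ``len(points) + n_omitted == len(metrics)``.
    """
    points: list[EncPlotPoint] = []
    n_omitted = 0
    for m in metrics:
        if m.enc is None or m.gc3s is None:
            n_omitted += 1
            continue
        f = m.gc3s / 100.0
        exp = expected_enc(f)
        points.append(
            EncPlotPoint(
                gene_id=m.gene_id,
                gc3s_fraction=f,
                enc_obs=m.enc,
                enc_exp=exp,
                deviation=(exp - m.enc) / exp,
            )
        )
    return points, n_omitted


def deviation_histogram(
    points: list[EncPlotPoint], bin_width: float = 0.05
) -> DeviationHistogram:
    """Histogram of relative ENc deviations over [-1, 1].

    Bins are left-closed right-open; values outside the range (which
    cannot occur for genuine ENc values but may for synthetic input)
    are clipped into the end bins.  Fractions sum to 1.
    """
    if not points:
        raise ValueError("no ENc-plot points to bin")
    d = np.array([p.deviation for p in points])
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    idx = np.clip(np.floor((d + 1.0) / bin_width).astype(int), 0, len(edges) - 2)
    fractions = np.bincount(idx, minlength=len(edges) - 1) / d.size
    in_band = float(np.mean((d >= 0.0) & (d < 0.1)))
    return DeviationHistogram(
        edges=edges,
        fractions=fractions,
        fraction_in_0_01=in_band,
        n_genes=int(d.size),
    )
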