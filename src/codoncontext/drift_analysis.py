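"""Codon-usage drift between conditions via the Frobenius matrix norm.

Drift between two codon context matrices A and B is ||A - B||_F, the
square root of the sum of squared entrywise differences of their
(stop-free, 61x61) probability matrices.  Identical matrices drift 0;
a condition whose gene set uses codon pairs very differently from the
whole-genome control drifts far.

The subsampling experiment quantifies the sampling-noise baseline:
random gene sets of increasing size are drawn from the genome, a matrix
is built per sample, and mean drift to the reference falls off with
size following a power law y = A x^b (fitted by ordinary least squares
on log10-log10 axes).  A condition-specific set whose drift sits above
that baseline at its size carries genuinely distinct codon usage, not
just small-sample noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from codoncontext.codon_stats import CodonContextMatrix, build_context_matrix
from codoncontext.seq_core import CodingSequence

__all__ = [
    "PowerLawFit",
    "DriftCurve",
    "frobenius_drift",
    "pairwise_drift",
    "subsample_drift",
    "fit_power_law",
]


def frobenius_drift(A: CodonContextMatrix, B: CodonContextMatrix) -> float:
    """Frobenius norm of the entrywise difference of two context
    matrices sharing the canonical 61-codon labels."""
    if A.labels != B.labels:
        raise ValueError("matrices do not share codon labels")
    return float(np.linalg.norm(A.P - B.P, ord="fro"))


def pairwise_drift(matrices: Mapping[str, CodonContextMatrix]) -> pd.DataFrame:
    """Symmetric table of Frobenius drifts between all matrix pairs.

    Diagonal is zero; row/column order follows the mapping order.
    """
    names = list(matrices)
    if len(names) < 2:
        raise ValueError("need at least 2 matrices for a pairwise table")
    table = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j > i:
                table[i, j] = table[j, i] = frobenius_drift(matrices[a], matrices[b])
    return pd.DataFrame(table, index=names, columns=names)


@dataclass(frozen=True)
class PowerLawFit:
    """Power model y = A * x^b fitted by OLS on log10 axes."""

    A: float
    b: float
    intercept_se: float
    slope_se: float

    def predict(self, x) -> np.ndarray:
        return self.A * np.asarray(x, dtype=float) ** self.b


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> PowerLawFit:
    """Fit y = A x^b by least squares on (log10 x, log10 y).

    Requires at least two points, all strictly positive.  Standard
    errors of the log-space intercept and slope are reported (zero when
    the fit is exact or has no residual degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 (x, y) points")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("power-law fit requires strictly positive x and y")
    lx, ly = np.log10(x), np.log10(y)
    X = np.column_stack([np.ones_like(lx), lx])
    coef, *_ = np.linalg.lstsq(X, ly, rcond=None)
    intercept, slope = coef
    resid = ly - X @ coef
    dof = x.size - 2
    if dof > 0:
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    else:
        se_int = se_slope = 0.0
    return PowerLawFit(
        A=float(10.0**intercept),
        b=float(slope),
        intercept_se=se_int,
        slope_se=se_slope,
    )


@dataclass(frozen=True)
class DriftCurve:
    """Mean/sd drift of random gene subsamples versus subsample size,
    with the fitted power-law coefficients."""

    sizes: tuple[int, ...]
    replicates: int
    mean_norm: tuple[float, ...]
    sd_norm: tuple[float, ...]
    fit_A: float | None
    fit_b: float | None
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size": self.sizes, "mean_norm": self.mean_norm, "sd_norm": self.sd_norm}
        )


DEFAULT_SIZES = (30, 50, 100, 150, 200, 250, 300)
DEFAULT_REPLICATES = 5


def subsample_drift(
    genome: Sequence[CodingSequence],
    reference: CodonContextMatrix,
    sizes: Sequence[int] = DEFAULT_SIZES,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> DriftCurve:
    """Random-subsampling drift experiment.

    For each size, draws ``replicates`` independent without-replacement
    gene samples, builds a context matrix per sample, and measures its
    Frobenius drift to the reference; then fits the power model to mean
    drift versus size.  The fit is omitted (None) when fewer than two
    distinct sizes have strictly positive mean drift.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for s in sizes:
        if s < 1 or s > len(genome):
            raise ValueError(f"subsample size {s} outside 1..{len(genome)}")
    rng = np.random.default_rng(seed)
    means: list[float] = []
    sds: list[float] = []
    for size in sizes:
        norms = []
        for _ in range(replicates):
            picks = rng.choice(len(genome), size=size, replace=False)
            sample = [genome[i] for i in picks]
            m = build_context_matrix(sample, source_label=f"subsample_n{size}")
            norms.append(frobenius_drift(m, reference))
        means.append(float(np.mean(norms)))
        sds.append(float(np.std(norms, ddof=1)) if replicates > 1 else 0.0)

    positive = [(s, m) for s, m in zip(sizes, means) if m > 0]
    fit_A = fit_b = None
    if len({s for s, _ in positive}) >= 2:
        fit = fit_power_law([s for s, _ in positive], [m for _, m in positive])
        fit_A, fit_b = fit.A, fit.b
    return DriftCurve(
        sizes=tuple(int(s) for s in sizes),
        replicates=replicates,
        mean_norm=tuple(means),
        sd_norm=tuple(sds),
        fit_A=fit_A,
        fit_b=fit_b,
        seed=seed,
    )
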