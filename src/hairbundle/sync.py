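"""Pairwise synchronization of bundle motion and coupling classification.

Synchronization between two motion traces x, y is quantified by the
zero-lag normalized cross-correlation

    cc(x, y) = cov(x, y) / (sigma_x * sigma_y)

with population (1/n) normalization, so the coefficient is exactly the
cosine of the angle between the centered traces. A cell counts as coupled
to the overlying membrane when its correlation with the membrane trace
exceeds a threshold derived from the null distribution of cc between
independent, uncoupled bundles: the null spread sets sigma, and the
threshold is the one-decimal value between 4 sigma and 5 sigma (0.2 for
sigma ~= 0.046).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "CorrelationMatrix",
    "CouplingClassification",
    "cross_correlation",
    "correlation_matrix",
    "threshold_from_sigma",
    "derive_threshold",
    "classify_coupled",
    "rearrange_matrix",
    "coupled_count_ratio",
    "GROUP_COUPLED",
    "GROUP_UNDER_MEMBRANE_UNCOUPLED",
    "GROUP_CONTROL",
]

GROUP_COUPLED = "coupled"
GROUP_UNDER_MEMBRANE_UNCOUPLED = "under-membrane-uncoupled"
GROUP_CONTROL = "control"


@dataclass
class CorrelationMatrix:
    """All pairwise zero-lag correlations for one stimulus segment."""

    cc: np.ndarray                       # n x n, symmetric, unit diagonal
    membrane_cc: Optional[np.ndarray]    # n, correlation with the membrane
    cell_ids: Sequence[str]
    segment: str = ""

    def pair_values(self) -> np.ndarray:
        """The n(n-1)/2 unique off-diagonal coefficients."""
        iu = np.triu_indices(self.cc.shape[0], k=1)
        return self.cc[iu]


@dataclass
class CouplingClassification:
    """Coupling labels of each cell against the membrane trace."""

    threshold: float
    coupled: np.ndarray          # bool, membrane_cc > threshold & under membrane
    groups: np.ndarray           # str labels per cell
    membrane_cc: np.ndarray
    null_sigma: Optional[float] = None


def cross_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag normalized cross-correlation cc = cov(x,y)/(sigma_x sigma_y).

    Population normalization (1/n in both covariance and standard
    deviations, so the factors cancel); bounded in [-1, 1]; invariant under
    positive affine rescaling of either input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero-variance input in cross_correlation")
    return float(np.clip(np.dot(xc, yc) / (sx * sy), -1.0, 1.0))


def correlation_matrix(traces: np.ndarray,
                       membrane: Optional[np.ndarray] = None,
                       cell_ids: Optional[Sequence[str]] = None,
                       segment: str = "") -> CorrelationMatrix:
    """Correlation matrix over all trace pairs, plus the membrane column.

    All traces must be time-aligned samples of the same stimulus segment;
    correlations are never computed across stimulus boundaries.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("traces must be an (n_cells, n_samples) array")
    n = traces.shape[0]
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n)]
    sd = traces.std(axis=1)
    bad = np.nonzero(sd == 0.0)[0]
    if bad.size:
        raise ValueError(
            f"zero-variance trace(s) for cell id(s) "
            f"{[cell_ids[i] for i in bad]}")
    cc = np.atleast_2d(np.corrcoef(traces))
    np.fill_diagonal(cc, 1.0)
    cc = np.clip((cc + cc.T) / 2.0, -1.0, 1.0)
    membrane_cc = None
    if membrane is not None:
        membrane = np.asarray(membrane, dtype=float)
        membrane_cc = np.array(
            [cross_correlation(traces[i], membrane) for i in range(n)])
    return CorrelationMatrix(cc=cc, membrane_cc=membrane_cc,
                             cell_ids=list(cell_ids), segment=segment)


def threshold_from_sigma(sigma: float) -> float:
    """One-decimal coupling threshold inside [4 sigma, 5 sigma].

    The smallest qualifying multiple of 0.1 is used; when the interval
    contains none, the midpoint 4.5 sigma is returned. For the canonical
    null spread sigma ~= 0.046 this yields 0.2.
    """
    lo, hi = 4 * sigma, 5 * sigma
    k_lo = int(np.ceil(round(lo, 12) * 10))
    k_hi = int(np.floor(round(hi, 12) * 10))
    if k_lo <= k_hi:
        return k_lo / 10.0
    return float(4.5 * sigma)


def derive_threshold(null_ccs: np.ndarray) -> Tuple[float, float]:
    """Coupling threshold from a null (uncoupled) cc sample.

    A Gaussian-kernel smoothing of the null histogram supplies the spread
    sigma; the threshold is the one-decimal value inside [4 sigma, 5 sigma]
    (the smallest when several qualify, 4.5 sigma when none does).
    Returns (sigma, threshold).
    """
    ccs = np.asarray(null_ccs, dtype=float)
    if ccs.size < 1000:
        warnings.warn(f"only {ccs.size} null cc values (< 1000); sigma may "
                      "be unstable", stacklevel=2)
    kde = gaussian_kde(ccs)
    # variance of the KDE-smoothed distribution: data variance + bw^2
    sigma = float(np.sqrt(np.var(ccs) + kde.factor ** 2 * np.var(ccs)))
    return sigma, threshold_from_sigma(sigma)


def classify_coupled(matrix: CorrelationMatrix,
                     under_membrane: np.ndarray,
                     threshold: float = 0.2,
                     null_sigma: Optional[float] = None,
                     ) -> CouplingClassification:
    """Label each cell coupled / under-membrane-uncoupled / control.

    Coupled requires lying under the membrane AND membrane correlation
    above the threshold. Under-membrane cells below the threshold have
    uncertain mechanical contact and form their own group, excluded from
    coupled-group statistics; all remaining cells are controls.
    """
    if matrix.membrane_cc is None:
        raise ValueError("classification requires the membrane correlation "
                         "column")
    under = np.asarray(under_membrane, dtype=bool)
    mcc = matrix.membrane_cc
    coupled = under & (mcc > threshold)
    groups = np.where(
        coupled, GROUP_COUPLED,
        np.where(under, GROUP_UNDER_MEMBRANE_UNCOUPLED, GROUP_CONTROL))
    return CouplingClassification(threshold=float(threshold),
                                  coupled=coupled, groups=groups,
                                  membrane_cc=mcc, null_sigma=null_sigma)


def rearrange_matrix(matrix: CorrelationMatrix,
                     ) -> Tuple[np.ndarray, CorrelationMatrix]:
    """Sort rows/columns by descending row mean (diagonal excluded).

    Groups strongly correlated cells into contiguous blocks, which makes
    partially synchronized (chimera-like) ensembles visible as a dominant
    corner block. Ties are broken by cell id; the permutation is returned
    for traceability. The multiset of off-diagonal values is preserved.
    """
    cc = matrix.cc
    n = cc.shape[0]
    row_mean = (cc.sum(axis=1) - np.diag(cc)) / max(n - 1, 1)
    order = np.lexsort((list(matrix.cell_ids), -row_mean))
    perm = np.asarray(order)
    new = CorrelationMatrix(
        cc=cc[np.ix_(perm, perm)],
        membrane_cc=None if matrix.membrane_cc is None
        else matrix.membrane_cc[perm],
        cell_ids=[matrix.cell_ids[i] for i in perm],
        segment=matrix.segment)
    return perm, new


def coupled_count_ratio(labels_pre: np.ndarray,
                        labels_during: np.ndarray) -> float:
    """Number of coupled cells during stimulation relative to baseline."""
    pre = np.asarray(labels_pre) == GROUP_COUPLED
    dur = np.asarray(labels_during) == GROUP_COUPLED
    if pre.size != dur.size:
        raise ValueError("label vectors must cover the same cell set")
    n_pre = int(pre.sum())
    if n_pre == 0:
        raise ValueError("no coupled cells at baseline; ratio undefined")
    return float(dur.sum() / n_pre)
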