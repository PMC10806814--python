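"""Distribution-similarity statistics for comparing property ensembles.

The Jensen–Shannon divergence with base-2 logarithms is bounded on [0, 1]:
zero for identical distributions, one for distributions with disjoint
support.  It is built from the Kullback–Leibler divergence against the
average distribution M = (P + Q)/2, which keeps it finite and symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SUM_TOL = 1e-12


class BinningError(ValueError):
    pass


class DivergenceError(ValueError):
    """Raised when KLD is infinite (P has mass where Q has none)."""


@dataclass(frozen=True)
class Distribution:
    """A normalised histogram: strictly increasing bin edges and
    probabilities over the bins."""
    edges: tuple
    p: tuple

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if len(edges) != len(p) + 1:
            raise BinningError("need len(edges) == len(p) + 1")
        if not np.all(np.diff(edges) > 0):
            raise BinningError("bin edges must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")

    @property
    def probs(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)


def _check_shared_binning(P: Distribution, Q: Distribution) -> None:
    if len(P.edges) != len(Q.edges) or not np.allclose(
            P.edges, Q.edges, rtol=0, atol=0):
        raise BinningError("distributions must share identical binning")


def kld(P: Distribution, Q: Distribution) -> float:
    """Kullback–Leibler divergence Σ P_i log2(P_i/Q_i), with 0·log(0/·)=0."""
    _check_shared_binning(P, Q)
    p, q = P.probs, Q.probs
    mask = p > 0
    if np.any(q[mask] == 0):
        raise DivergenceError("P has support where Q is zero; KLD is infinite")
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def jsd(P: Distribution, Q: Distribution) -> float:
    """Jensen–Shannon divergence ½ D(P‖M) + ½ D(Q‖M), M = (P+Q)/2.

    Always finite; 0 ⇔ P = Q, 1 for disjoint support (base-2 logs)."""
    _check_shared_binning(P, Q)
    m = (P.probs + Q.probs) / 2.0
    M = Distribution(P.edges, tuple(m))
    return 0.5 * kld(P, M) + 0.5 * kld(Q, M)


def histogram(samples, n_bins: int, range_: tuple) -> Distribution:
    """Build a normalised Distribution over ``n_bins`` equal-width bins.

    Samples outside ``range_`` are clipped onto the boundary bins so the
    probabilities always sum to one.
    """
    samples = np.asarray(list(samples), dtype=float)
    if samples.size == 0:
        raise ValueError("cannot histogram an empty sample set")
    if n_bins < 1:
        raise ValueError("n_bins must be ≥ 1")
    lo, hi = map(float, range_)
    if not hi > lo:
        raise ValueError("range must be increasing")
    clipped = np.clip(samples, lo, np.nextafter(hi, lo))
    counts, edges = np.histogram(clipped, bins=n_bins, range=(lo, hi))
    p = counts / counts.sum()
    return Distribution(tuple(edges), tuple(p))
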