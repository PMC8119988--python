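"""Connectome summary statistics and the percentile-normalized distance.

The six statistics form the vector

    gamma = (rr_ee, rr_ei, rr_ie, rr_ii, r5, r_io)

where rr_xy is the relative reciprocity between populations x and y (the
reciprocity divided by the value expected in a pairwise-random graph of the
same connectivity), r5 the relative prevalence of directed cycles of length 5
in the excitatory subgraph, and r_io the Pearson correlation of excitatory
in- and out-degrees.  All statistics are computed on binarized graphs.

A statistic can be undefined (e.g. the degree correlation when a degree
sequence is constant); undefined components are carried as NaN and the vector
is flagged so callers can discard it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import Connectome, binarize

__all__ = [
    "SummaryStats",
    "DistanceNorms",
    "reciprocity",
    "relative_reciprocities",
    "recurrency",
    "inout_degree_correlation",
    "summarize",
    "calibrate_norms",
    "distance",
]

STAT_NAMES = ("rr_ee", "rr_ei", "rr_ie", "rr_ii", "r5", "r_io")


@dataclass(frozen=True)
class SummaryStats:
    rr_ee: float
    rr_ei: float
    rr_ie: float
    rr_ii: float
    r5: float
    r_io: float

    def to_array(self) -> np.ndarray:
        return np.array([self.rr_ee, self.rr_ei, self.rr_ie, self.rr_ii,
                         self.r5, self.r_io], dtype=float)

    @property
    def defined(self) -> bool:
        return bool(np.all(np.isfinite(self.to_array())))

    @classmethod
    def from_array(cls, arr) -> "SummaryStats":
        return cls(*(float(v) for v in arr))


@dataclass(frozen=True)
class DistanceNorms:
    """Per-statistic scale: 80th minus 20th percentile over a calibration
    sample (linear-interpolation percentiles), floored at machine epsilon."""

    scales: tuple[float, ...]
    percentile_convention: str = "linear"

    def to_array(self) -> np.ndarray:
        return np.asarray(self.scales, dtype=float)


def _population_indices(connectome: Connectome, pop: str) -> np.ndarray:
    if pop not in ("e", "i"):
        raise ValueError("population must be 'e' or 'i'")
    return np.flatnonzero(connectome.types > 0 if pop == "e"
                          else connectome.types < 0)


def _binary_support(connectome: Connectome) -> sp.csr_matrix:
    if not connectome.binary:
        connectome = binarize(connectome)
    return connectome.support()


def reciprocity(connectome: Connectome, x: str, y: str) -> float:
    """Fraction of directed x->y connections that are reciprocated.

    Counts ordered connections: a mutually connected pair within one
    population contributes two connections and two reciprocations, so the
    value estimates P(y->x exists | x->y exists).  Returns 0.0 when there is
    no x->y connection at all.
    """
    B = _binary_support(connectome)
    xi = _population_indices(connectome, x)
    yi = _population_indices(connectome, y)
    # x->y edges live in block rows yi, cols xi (A[post, pre]).
    fwd = B[np.ix_(yi, xi)]
    n_edges = fwd.nnz
    if n_edges == 0:
        return 0.0
    back = B[np.ix_(xi, yi)]  # y->x edges
    n_recip = int(fwd.multiply(back.T).nnz)
    return n_recip / n_edges


def _block_connectivity(B: sp.csr_matrix, pre: np.ndarray,
                        post: np.ndarray, same: bool) -> float:
    n_possible = (len(pre) * (len(pre) - 1) if same
                  else len(pre) * len(post))
    if n_possible == 0:
        return np.nan
    return B[np.ix_(post, pre)].nnz / n_possible


def relative_reciprocities(connectome: Connectome):
    """(rr_ee, rr_ei, rr_ie, rr_ii): each reciprocity divided by the
    empirical connectivity of the reverse direction (rr_xy = r_xy / p_yx),
    which is the reciprocity expected of a pairwise-random graph with the
    same connectivity.  NaN where the reverse connectivity is zero."""
    B = _binary_support(connectome)
    e = _population_indices(connectome, "e")
    i = _population_indices(connectome, "i")
    out = []
    for x_pop, y_pop in (("e", "e"), ("e", "i"), ("i", "e"), ("i", "i")):
        xi = e if x_pop == "e" else i
        yi = e if y_pop == "e" else i
        r_xy = reciprocity(connectome, x_pop, y_pop)
        if B[np.ix_(yi, xi)].nnz == 0:
            # zero-connection rule: r_xy := 0, hence rr_xy = 0
            out.append(0.0)
            continue
        # reverse direction y->x: presynaptic yi, postsynaptic xi
        p_yx = _block_connectivity(B, pre=yi, post=xi, same=x_pop == y_pop)
        if not np.isfinite(p_yx) or p_yx == 0.0:
            out.append(np.nan)
        else:
            out.append(r_xy / p_yx)
    return tuple(out)


def recurrency(connectome: Connectome, l: int = 5) -> float:
    """Relative excitatory recurrency r^(l) = tr(C_ee^l) / (n_e * p_e)^l.

    The trace counts closed directed walks of length l in the excitatory
    subgraph; the denominator is the leading-order expectation for a
    pairwise-random graph with the empirical excitatory connectivity.
    The trace is computed exactly (integer arithmetic carried in floats whose
    magnitudes stay below 2^53, checked via the walk-count bounds n_e^k).
    """
    B = _binary_support(connectome)
    e = _population_indices(connectome, "e")
    n_e = len(e)
    if n_e < 2:
        return np.nan
    Cee = B[np.ix_(e, e)]
    n_edges = Cee.nnz
    p_e = n_edges / (n_e * (n_e - 1))
    if p_e == 0.0:
        return np.nan
    if l != 5:
        M = Cee.astype(np.float64).toarray()
        tr = float(np.trace(np.linalg.matrix_power(M, l)))
        return tr / (n_e * p_e) ** l
    # l = 5: two matmuls, C2 = C^2, F = C2 @ C, tr(C^5) = sum(C2 * F.T).
    # Entries of C2 (<= n_e) and F (<= n_e^2) are exactly representable in
    # float32 up to n_e <= 2^12; accumulate the final sum in float64.
    dtype = np.float32 if n_e <= 4000 else np.float64
    M = Cee.astype(dtype).toarray()
    C2 = M @ M
    F = C2 @ M
    tr = float(np.einsum("ij,ji->", C2.astype(np.float64),
                         F.astype(np.float64)))
    return tr / (n_e * p_e) ** 5


def inout_degree_correlation(connectome: Connectome) -> float:
    """Pearson correlation of in- and out-degrees of excitatory neurons,
    degrees counted within the excitatory subgraph.  NaN when either degree
    sequence has zero variance."""
    B = _binary_support(connectome)
    e = _population_indices(connectome, "e")
    if len(e) < 2:
        return np.nan
    Cee = B[np.ix_(e, e)]
    in_deg = np.asarray(Cee.sum(axis=1)).ravel().astype(float)   # row sums
    out_deg = np.asarray(Cee.sum(axis=0)).ravel().astype(float)  # col sums
    if in_deg.std() == 0.0 or out_deg.std() == 0.0:
        return np.nan
    return float(np.corrcoef(in_deg, out_deg)[0, 1])


def summarize(connectome: Connectome, cycle_length: int = 5) -> SummaryStats:
    """Binarize and compute the six-statistic summary vector gamma."""
    b = binarize(connectome) if not connectome.binary else connectome
    rr = relative_reciprocities(b)
    r5 = recurrency(b, cycle_length)
    r_io = inout_degree_correlation(b)
    return SummaryStats(rr[0], rr[1], rr[2], rr[3], r5, r_io)


def calibrate_norms(stat_sample) -> DistanceNorms:
    """Per-statistic scale = 80th - 20th percentile over a calibration sample
    of defined summary vectors; zero-width scales are floored at machine
    epsilon."""
    arrs = [s.to_array() if isinstance(s, SummaryStats) else np.asarray(s)
            for s in stat_sample]
    if len(arrs) == 0:
        raise ValueError("cannot calibrate distance norms on an empty sample")
    mat = np.vstack(arrs)
    hi = np.percentile(mat, 80, axis=0)
    lo = np.percentile(mat, 20, axis=0)
    scales = hi - lo
    eps = np.finfo(float).eps
    scales = np.where(scales > 0, scales, eps)
    return DistanceNorms(scales=tuple(float(s) for s in scales))


def distance(a: SummaryStats, b: SummaryStats, norms: DistanceNorms) -> float:
    """Normalized L1 distance between two summary vectors."""
    av, bv = a.to_array(), b.to_array()
    if not (np.all(np.isfinite(av)) and np.all(np.isfinite(bv))):
        raise ValueError("distance undefined for vectors with undefined "
                         "components; discard such particles")
    return float(np.sum(np.abs(av - bv) / norms.to_array()))
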