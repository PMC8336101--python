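"""Sparse intrachromosomal Hi-C contact matrices and matrix-level statistics.

A :class:`ContactMatrix` stores, per chromosome, the upper triangle of a
symmetric contact-count matrix at a fixed bin size.  On top of it this module
provides

* ICE balancing (iterative correction of multiplicative per-bin biases),
* the distance-decay expected profile and the observed/expected transform,
* the stratum-adjusted correlation coefficient (SCC) between two maps, and
* a map-resolution estimate (smallest bin size at which most bins are
  covered by at least a target number of contacts).

Matrices are persisted as plain triplet TSV (chrom, bin_i, bin_j, value)
with ``bin_i <= bin_j``, alongside a standard chrom.sizes file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import uniform_filter
from sklearn.base import BaseEstimator

from .core import GenomeLayout

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "IceNormalizer",
    "ice_normalize",
    "expected_by_distance",
    "oe_transform",
    "scc",
    "estimate_map_resolution",
]


@dataclass
class ContactMatrix:
    """Per-chromosome symmetric sparse contact counts at a fixed resolution.

    ``data`` maps chromosome name to a COO matrix holding the upper triangle
    (row <= col) only; values are non-negative.  ``bias`` optionally carries
    the per-bin multiplicative ICE bias (NaN = invalid bin).
    """

    layout: GenomeLayout
    resolution: int
    data: dict[str, sp.coo_matrix]
    normalized: bool = False
    bias: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for chrom, m in self.data.items():
            n = self.layout.n_bins(chrom, self.resolution)
            if m.shape != (n, n):
                raise ValueError(f"{chrom}: matrix shape {m.shape} != ({n}, {n})")
            if len(m.data) and (m.data < 0).any():
                raise ValueError(f"{chrom}: negative contact values")
            if len(m.data) and (m.row > m.col).any():
                raise ValueError(f"{chrom}: lower-triangle entries stored")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.data)

    def n_bins(self, chrom: str) -> int:
        return self.layout.n_bins(chrom, self.resolution)

    def dense(self, chrom: str) -> np.ndarray:
        """Full symmetric dense matrix for one chromosome."""
        upper = self.data[chrom].toarray()
        full = upper + upper.T
        full[np.diag_indices_from(full)] -= np.diag(upper)
        return full

    def marginals(self, chrom: str) -> np.ndarray:
        return self.dense_marginals(self.data[chrom])

    @staticmethod
    def dense_marginals(upper: sp.coo_matrix) -> np.ndarray:
        n = upper.shape[0]
        marg = np.zeros(n)
        np.add.at(marg, upper.row, upper.data)
        off = upper.row != upper.col
        np.add.at(marg, upper.col[off], upper.data[off])
        return marg

    def total(self, chrom: str | None = None) -> float:
        chroms = [chrom] if chrom else self.chromosomes
        tot = 0.0
        for c in chroms:
            m = self.data[c]
            off = m.row != m.col
            tot += 2 * m.data[off].sum() + m.data[~off].sum()
        return float(tot)

    @classmethod
    def from_dense(cls, layout: GenomeLayout, resolution: int,
                   dense: dict[str, np.ndarray], normalized: bool = False,
                   bias: dict[str, np.ndarray] | None = None) -> "ContactMatrix":
        data = {}
        for chrom, full in dense.items():
            upper = sp.coo_matrix(np.triu(full))
            data[chrom] = upper
        return cls(layout, resolution, data, normalized=normalized, bias=bias)

    def aggregate(self, factor: int) -> "ContactMatrix":
        """Sum counts into bins ``factor`` times coarser."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        new_res = self.resolution * factor
        data = {}
        for chrom, m in self.data.items():
            n_new = self.layout.n_bins(chrom, new_res)
            r, c = m.row // factor, m.col // factor
            # aggregation can land former upper-triangle pixels below the
            # new diagonal only if r > c, impossible with integer division
            agg = sp.coo_matrix((m.data, (r, c)), shape=(n_new, n_new))
            agg.sum_duplicates()
            data[chrom] = agg
        return ContactMatrix(self.layout, new_res, data, normalized=False)

    # -- I/O ---------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        """Triplet TSV: chrom, bin_i, bin_j, value (upper triangle only)."""
        frames = []
        for chrom, m in self.data.items():
            order = np.lexsort((m.col, m.row))
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "bin_i": m.row[order],
                "bin_j": m.col[order],
                "value": m.data[order],
            }))
        out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chrom", "bin_i", "bin_j", "value"])
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, layout: GenomeLayout, resolution: int,
             normalized: bool = False) -> "ContactMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        data = {}
        for chrom in layout.names:
            sub = df[df["chrom"] == chrom]
            n = layout.n_bins(chrom, resolution)
            data[chrom] = sp.coo_matrix(
                (sub["value"].to_numpy(float),
                 (sub["bin_i"].to_numpy(int), sub["bin_j"].to_numpy(int))),
                shape=(n, n))
        return cls(layout, resolution, data, normalized=normalized)


@dataclass
class ExpectedProfile:
    """Mean contact value per genomic distance (in bins) for one chromosome."""

    chrom: str
    values: np.ndarray          # E(d), d = 0 .. n_bins-1
    counts: np.ndarray          # number of valid pixels contributing at d

    def __post_init__(self) -> None:
        if len(self.values) != len(self.counts):
            raise ValueError("values and counts length mismatch")


# ---------------------------------------------------------------------------
# ICE balancing

class IceNormalizer(BaseEstimator):
    """Iterative correction (ICE) of per-bin multiplicative coverage biases.

    Bins whose raw marginal falls at or below the ``low_coverage_quantile``
    quantile of the positive marginals are masked (bias NaN) before
    balancing, mirroring common Hi-C pipeline defaults.  Balancing iterates
    ``b_i <- b_i * s_i / mean(s)`` with ``s`` the current corrected marginal,
    until the coefficient of variation of the corrected marginals drops
    below ``tol``.  The corrected matrix is ``raw_ij / (b_i * b_j)``,
    rescaled so the mean corrected marginal matches the mean raw marginal
    over valid bins.

    Attributes
    ----------
    bias_ : dict[str, np.ndarray]
        Per-chromosome bias vectors (NaN on masked bins).
    matrix_ : ContactMatrix
        The balanced matrix (``normalized=True``, carries ``bias_``).
    converged_ : dict[str, bool]
    n_iter_ : dict[str, int]
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-5,
                 low_coverage_quantile: float = 0.02):
        self.max_iter = max_iter
        self.tol = tol
        self.low_coverage_quantile = low_coverage_quantile

    def fit(self, m: ContactMatrix) -> "IceNormalizer":
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if m.total() == 0:
            raise ValueError("no signal: contact matrix is all zero")
        self.bias_ = {}
        self.converged_ = {}
        self.n_iter_ = {}
        data = {}
        for chrom in m.chromosomes:
            upper = m.data[chrom].tocoo()
            bias, vals, conv, it = self._balance_chrom(upper)
            self.bias_[chrom] = bias
            self.converged_[chrom] = conv
            self.n_iter_[chrom] = it
            data[chrom] = sp.coo_matrix((vals, (upper.row, upper.col)),
                                        shape=upper.shape)
        self.matrix_ = ContactMatrix(m.layout, m.resolution, data,
                                     normalized=True, bias=self.bias_)
        return self

    def _balance_chrom(self, upper: sp.coo_matrix):
        n = upper.shape[0]
        marg = ContactMatrix.dense_marginals(upper)
        valid = marg > 0
        if valid.sum() == 0:
            return np.full(n, np.nan), np.zeros_like(upper.data), True, 0
        if self.low_coverage_quantile > 0:
            positive = marg[valid]
            cutoff = np.quantile(positive, self.low_coverage_quantile)
            valid &= marg >= cutoff
        if valid.sum() < 2:
            # degenerate chromosome: keep highest-coverage bins only
            valid = marg >= np.max(marg)
        sym = (upper + sp.triu(upper, k=1).T).tocsr()
        b = np.ones(n)
        inv = np.zeros(n)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            inv[:] = 0.0
            inv[valid] = 1.0 / b[valid]
            s = (sym @ inv) * inv
            sv = s[valid]
            mean = sv.mean()
            cv = sv.std() / mean if mean > 0 else np.inf
            if cv < self.tol:
                converged = True
                break
            b[valid] *= sv / mean
        if not converged:
            warnings.warn("ICE did not converge within max_iter; returning best iterate")
        # rescale: mean corrected marginal == mean raw marginal on valid bins
        inv[:] = 0.0
        inv[valid] = 1.0 / b[valid]
        s = (sym @ inv) * inv
        scale = np.sqrt(s[valid].mean() / marg[valid].mean())
        b[valid] *= scale
        bias = np.where(valid, b, np.nan)
        bi, bj = bias[upper.row], bias[upper.col]
        vals = np.where(np.isnan(bi) | np.isnan(bj), 0.0,
                        upper.data / (bi * bj))
        return bias, vals, converged, it


def ice_normalize(m: ContactMatrix, max_iter: int = 200, tol: float = 1e-5,
                  low_coverage_quantile: float = 0.02
                  ) -> tuple[ContactMatrix, dict[str, np.ndarray]]:
    """Functional wrapper over :class:`IceNormalizer`; returns (matrix, bias)."""
    norm = IceNormalizer(max_iter=max_iter, tol=tol,
                         low_coverage_quantile=low_coverage_quantile).fit(m)
    return norm.matrix_, norm.bias_


# ---------------------------------------------------------------------------
# expected profile and O/E

def valid_bins(m: ContactMatrix, chrom: str) -> np.ndarray:
    """Boolean mask of usable bins (ICE-valid if balanced, else marginal > 0)."""
    if m.bias is not None and chrom in m.bias:
        return ~np.isnan(m.bias[chrom])
    return m.marginals(chrom) > 0


def expected_by_distance(m: ContactMatrix, chrom: str) -> ExpectedProfile:
    """E(d): mean pixel value over all valid-bin pairs at distance d."""
    n = m.n_bins(chrom)
    mask = valid_bins(m, chrom)
    upper = m.data[chrom]
    keep = mask[upper.row] & mask[upper.col]
    d = upper.col[keep] - upper.row[keep]
    sums = np.bincount(d, weights=upper.data[keep], minlength=n)
    counts = np.zeros(n, dtype=np.int64)
    mask_i = mask.astype(np.int64)
    for dist in range(n):
        if dist == 0:
            counts[dist] = mask_i.sum()
        else:
            counts[dist] = int((mask_i[:-dist] * mask_i[dist:]).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return ExpectedProfile(chrom, values, counts)


def oe_transform(m: ContactMatrix,
                 expected: dict[str, ExpectedProfile] | None = None) -> ContactMatrix:
    """Observed/expected transform; pixels with E(d) = 0 are dropped."""
    if expected is None:
        expected = {c: expected_by_distance(m, c) for c in m.chromosomes}
    data = {}
    for chrom in m.chromosomes:
        prof = expected[chrom]
        if len(prof.values) != m.n_bins(chrom):
            raise ValueError(f"{chrom}: expected profile length mismatch "
                             "(resolution mismatch?)")
        upper = m.data[chrom]
        e = prof.values[upper.col - upper.row]
        keep = e > 0
        data[chrom] = sp.coo_matrix(
            (upper.data[keep] / e[keep], (upper.row[keep], upper.col[keep])),
            shape=upper.shape)
    return ContactMatrix(m.layout, m.resolution, data, normalized=m.normalized,
                         bias=m.bias)


# ---------------------------------------------------------------------------
# SCC (stratum-adjusted correlation)

def scc(m1: ContactMatrix, m2: ContactMatrix, smooth_span: int = 2,
        max_distance: int = 5_000_000) -> float:
    """Stratum-adjusted correlation coefficient between two Hi-C maps.

    Both matrices are mean-filter smoothed with a (2*smooth_span+1) square
    window; per distance stratum ``d <= max_distance`` the Pearson
    correlation ``rho_d`` is computed over pixels whose bins are valid in
    both maps, and combined as ``sum(w_d * rho_d) / sum(w_d)`` with
    ``w_d = N_d * sigma1_d * sigma2_d``.  The weights are a transparent
    stand-in for HiCRep's variance-stabilized weights; the stratification
    and smoothing follow the same design.
    """
    if m1.resolution != m2.resolution or m1.layout.lengths != m2.layout.lengths:
        raise ValueError("matrices must share layout and resolution")
    max_d = max_distance // m1.resolution
    num = den = 0.0
    any_stratum = False
    size = 2 * smooth_span + 1
    for chrom in m1.chromosomes:
        a = m1.dense(chrom)
        b = m2.dense(chrom)
        mask = valid_bins(m1, chrom) & valid_bins(m2, chrom)
        if mask.sum() < 2:
            continue
        if smooth_span > 0:
            a = uniform_filter(a, size=size, mode="nearest")
            b = uniform_filter(b, size=size, mode="nearest")
        n = a.shape[0]
        for d in range(0, min(max_d, n - 1) + 1):
            # trim the stratum ends: clipped smoothing windows there mix in
            # off-stratum means identically in both maps, faking correlation
            lo, hi = smooth_span, n - d - smooth_span
            if hi - lo < 2:
                continue
            idx = np.arange(lo, hi)
            keep = mask[idx] & mask[idx + d]
            if keep.sum() < 2:
                continue
            x = a[idx[keep], idx[keep] + d]
            y = b[idx[keep], idx[keep] + d]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            rho = float(np.corrcoef(x, y)[0, 1])
            w = len(x) * sx * sy
            num += w * rho
            den += w
            any_stratum = True
    if not any_stratum:
        raise ValueError("degenerate input: no stratum with variance in both maps")
    return float(num / den)


# ---------------------------------------------------------------------------
# map resolution

def estimate_map_resolution(m: ContactMatrix, candidate_bins: list[int],
                            count_threshold: int = 1000,
                            bin_fraction: float = 0.80) -> int | None:
    """Smallest candidate bin size at which ``bin_fraction`` of bins on
    non-empty chromosomes have a marginal of at least ``count_threshold``.

    Defaults follow the convention that a map "has" a given resolution when
    80% of bins see >= 1000 contacts.  Returns None when no candidate passes.
    """
    if sorted(candidate_bins) != list(candidate_bins):
        raise ValueError("candidate_bins must be sorted ascending")
    nonempty = [c for c in m.chromosomes if m.total(c) > 0]
    if not nonempty:
        return None
    for cand in candidate_bins:
        if cand % m.resolution:
            raise ValueError(f"candidate {cand} not a multiple of base resolution")
        agg = m.aggregate(cand // m.resolution)
        marg = np.concatenate([agg.marginals(c) for c in nonempty])
        if len(marg) and (marg >= count_threshold).mean() >= bin_fraction:
            return cand
    return None
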