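"""Contact-domain (TAD) calling and downstream domain analyses.

Domain calling follows the arrowhead idea: the balanced matrix is mapped to

    A(i, d) = (M(i, i-d) - M(i, i+d)) / (M(i, i-d) + M(i, i+d))

which is positive when upstream contacts at distance d dominate downstream
ones.  For a candidate domain [a, b) the corner score averages, over the
pixels (i, j) with a <= i < j < b, the contrast between the transform seen
from the downstream boundary (A(j, j-i), comparing the intra-domain pixel
with its mirror beyond the domain) and from the upstream boundary
(A(i, j-i)).  Enriched domains score positive; a featureless distance-decay
background scores zero.  This is a deterministic, scale-invariant
simplification of the Juicer Arrowhead corner statistics.

Candidates above the score threshold are kept greedily (highest score
first) after non-maximum suppression of near-duplicate boundary pairs;
accepted domains may nest but never partially overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import GeneTable, GenomicInterval, PeakSet, overlap_fraction
from .matrix import ContactMatrix

__all__ = [
    "ContactDomain",
    "DomainCaller",
    "arrowhead_transform",
    "call_domains",
    "boundaries",
    "BoundarySet",
    "ctcf_boundary_fraction",
    "common_domains",
    "classify_domain_states",
    "state_switch_genes",
    "domain_size_stats",
]


@dataclass(frozen=True)
class ContactDomain:
    interval: GenomicInterval
    score: float
    sample: str = ""

    def __len__(self) -> int:
        return len(self.interval)


def arrowhead_transform(dense: np.ndarray, max_dist: int | None = None) -> np.ndarray:
    """Arrowhead transform of a symmetric dense matrix.

    Returns A with shape (n, max_dist + 1); A[i, d] compares M(i, i-d) with
    M(i, i+d) and lies in [-1, 1].  Entries are NaN where either index falls
    off the matrix or the denominator is zero.  A[:, 0] is 0 by convention.
    """
    n = dense.shape[0]
    if max_dist is None:
        max_dist = n - 1
    max_dist = min(max_dist, n - 1)
    A = np.full((n, max_dist + 1), np.nan)
    A[:, 0] = 0.0
    for d in range(1, max_dist + 1):
        i = np.arange(d, n - d)
        if len(i) == 0:
            continue
        up = np.maximum(dense[i, i - d], 0.0)
        down = np.maximum(dense[i, i + d], 0.0)
        denom = up + down
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(denom > 0, np.clip((up - down) / denom, -1.0, 1.0),
                            np.nan)
        A[i, d] = vals
    return A


class DomainCaller(BaseEstimator):
    """Corner-score contact-domain caller on a balanced matrix.

    Parameters
    ----------
    max_domain_bins : int
        Largest domain size scanned, in bins.
    min_domain_bins : int
        Smallest domain size scanned; very small candidates average too few
        pixels to be reliable.
    score_threshold : float
        Minimum corner score for a candidate to be kept.
    nms_radius : int
        Candidates whose two boundaries both lie within this many bins of a
        higher-scoring accepted candidate are suppressed (near-duplicates).
    nested_score_ratio : float
        A candidate nested inside an accepted domain is kept only when its
        score reaches this fraction of the enclosing score; residual corner
        signal inside a strong domain otherwise spawns spurious sub-domains,
        while genuinely nested domains carry extra enrichment of their own.

    Attributes
    ----------
    domains_ : list[ContactDomain]
    scores_ : dict[str, pd.DataFrame]   candidate scores per chromosome
    """

    def __init__(self, max_domain_bins: int = 200, min_domain_bins: int = 10,
                 score_threshold: float = 0.3, nms_radius: int = 2,
                 nested_score_ratio: float = 0.75, min_nest_ratio: float = 2.0,
                 noise_z: float = 5.5, smooth_span: int = 0):
        self.max_domain_bins = max_domain_bins
        self.min_domain_bins = min_domain_bins
        self.score_threshold = score_threshold
        self.nms_radius = nms_radius
        self.nested_score_ratio = nested_score_ratio
        self.min_nest_ratio = min_nest_ratio
        self.noise_z = noise_z
        self.smooth_span = smooth_span

    def fit(self, m: ContactMatrix, sample: str = "") -> "DomainCaller":
        if not m.normalized:
            raise ValueError("domain calling requires a balanced matrix")
        from .matrix import valid_bins
        self.domains_ = []
        self.scores_ = {}
        for chrom in m.chromosomes:
            dense = m.dense(chrom)
            invalid = ~valid_bins(m, chrom)
            if invalid.any():
                # masked bins are missing data, not empty contacts: zeros
                # there would fake one-sided corners at the mask edges
                dense[invalid, :] = np.nan
                dense[:, invalid] = np.nan
            cands = self._score_chrom(dense)
            self.scores_[chrom] = cands
            kept = self._select(cands)
            res = m.resolution
            length = m.layout.lengths[chrom]
            for a, b, s in kept:
                self.domains_.append(ContactDomain(
                    GenomicInterval(chrom, int(a) * res, min(int(b) * res, length)),
                    float(s), sample))
        return self

    def _score_chrom(self, dense: np.ndarray) -> pd.DataFrame:
        n = dense.shape[0]
        if self.smooth_span > 0:
            from scipy.ndimage import uniform_filter
            dense = uniform_filter(dense, size=2 * self.smooth_span + 1,
                                   mode="nearest")
        L = min(self.max_domain_bins, n)
        A = arrowhead_transform(dense, max_dist=L)
        Az = np.nan_to_num(A)                      # zero-filled sums
        Ac = (~np.isnan(A)).astype(np.float64)     # defined-entry counts
        Az[:, 0] = 0.0
        Ac[:, 0] = 0.0
        # P[i, k] = sum_{d<=k} A[i, d]; Pc analogous count
        P = np.cumsum(Az, axis=1)
        Pc = np.cumsum(Ac, axis=1)

        starts_all, ends_all, scores_all = [], [], []
        # Informative pixel terms only: for a candidate [a, b) the
        # downstream view U(i,j) = A(j, j-i) is counted when its mirror
        # 2j-i lies at or beyond b, the upstream view V(i,j) = A(i, j-i)
        # when its mirror 2i-j lies before a; terms whose mirror stays
        # inside the candidate compare the domain with itself and carry no
        # boundary information.
        for ell in range(max(2, self.min_domain_bins), L + 1):
            a_max = n - ell
            if a_max < 0:
                break
            a = np.arange(0, a_max + 1)
            SU = np.zeros(a_max + 1)
            CU = np.zeros(a_max + 1)
            SV = np.zeros(a_max + 1)
            CV = np.zeros(a_max + 1)
            for t in range(1, ell):          # row j = a + t
                if 2 * t >= ell:             # informative U depths: ell-t .. t
                    rows = a + t
                    SU += P[rows, t] - P[rows, ell - 1 - t]
                    CU += Pc[rows, t] - Pc[rows, ell - 1 - t]
            for v in range(0, ell - 1):      # row i = a + v
                hi = ell - 1 - v
                if hi > v:                   # informative V depths: v+1 .. ell-1-v
                    rows = a + v
                    SV += P[rows, hi] - P[rows, v]
                    CV += Pc[rows, hi] - Pc[rows, v]
            cnt = CU + CV
            # mean of (U - V) over the informative, defined pixel terms
            with np.errstate(invalid="ignore", divide="ignore"):
                score = np.where(cnt > 0, (SU - SV) / np.maximum(cnt, 1), np.nan)
            full = 2 * (ell * ell // 4)      # informative terms when all defined
            ok = cnt >= full / 2
            # noise floor: per-term A values are bounded by 1, so the score
            # standard deviation under a featureless background is at most
            # ~ sigma_A * sqrt(2)/ell with sigma_A <= ~0.7 at shallow counts
            floor = max(self.score_threshold,
                        self.noise_z * 0.7 * np.sqrt(2.0) / ell)
            ok &= np.nan_to_num(score, nan=-np.inf) > floor
            if ok.any():
                starts_all.append(a[ok])
                ends_all.append(a[ok] + ell)
                scores_all.append(score[ok])
        if starts_all:
            return pd.DataFrame({
                "start_bin": np.concatenate(starts_all),
                "end_bin": np.concatenate(ends_all),
                "score": np.concatenate(scores_all),
            })
        return pd.DataFrame(columns=["start_bin", "end_bin", "score"])

    def _select(self, cands: pd.DataFrame) -> list[tuple[int, int, float]]:
        if len(cands) == 0:
            return []
        order = np.lexsort((cands["start_bin"], -cands["score"]))
        accepted: list[tuple[int, int, float]] = []
        r = self.nms_radius
        for idx in order:
            a = int(cands["start_bin"].iat[idx])
            b = int(cands["end_bin"].iat[idx])
            s = float(cands["score"].iat[idx])
            dup = conflict = False
            for (a2, b2, s2) in accepted:
                if abs(a - a2) <= r and abs(b - b2) <= r:
                    dup = True
                    break
                if a < b2 and a2 < b:  # overlapping
                    if a2 <= a and b <= b2:  # nested inside accepted
                        if (s < self.nested_score_ratio * s2
                                or (b2 - a2) < self.min_nest_ratio * (b - a)):
                            conflict = True
                            break
                    elif a <= a2 and b2 <= b:  # contains accepted
                        # a genuine parent is substantially larger than the
                        # nested call; marginal containers are ridge
                        # artifacts of the contained corner
                        if (b - a) < self.min_nest_ratio * (b2 - a2):
                            conflict = True
                            break
                    else:  # partial overlap
                        conflict = True
                        break
            if not dup and not conflict:
                accepted.append((a, b, s))
        accepted.sort()
        return accepted


def call_domains(m: ContactMatrix, sample: str = "",
                 **params) -> list[ContactDomain]:
    """Functional wrapper over :class:`DomainCaller`."""
    return DomainCaller(**params).fit(m, sample=sample).domains_


@dataclass
class BoundarySet:
    """Deduplicated domain boundary points with a +/- flank window (bp)."""

    points: dict[str, np.ndarray]   # chrom -> sorted unique boundary bp
    flank: int = 5000

    @property
    def count(self) -> int:
        return int(sum(len(v) for v in self.points.values()))

    def windows(self, chrom: str) -> np.ndarray:
        p = self.points[chrom]
        return np.stack([np.maximum(p - self.flank, 0), p + self.flank], axis=1)


def boundaries(domains: list[ContactDomain], flank: int = 5000) -> BoundarySet:
    """Unique domain start/end points; shared or nested endpoints deduplicate."""
    pts: dict[str, set[int]] = {}
    for d in domains:
        pts.setdefault(d.interval.chrom, set()).update((d.interval.start, d.interval.end))
    return BoundarySet({c: np.array(sorted(v), dtype=np.int64)
                        for c, v in sorted(pts.items())}, flank=flank)


def _any_overlap(windows: np.ndarray, spans: np.ndarray) -> np.ndarray:
    """For each half-open window, whether it overlaps >= 1 span (both sorted)."""
    if len(spans) == 0:
        return np.zeros(len(windows), dtype=bool)
    starts, ends = spans[:, 0], spans[:, 1]
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    cummax_end = np.maximum.accumulate(ends)
    idx = np.searchsorted(starts, windows[:, 1])  # spans starting before window end
    out = np.zeros(len(windows), dtype=bool)
    has = idx > 0
    out[has] = cummax_end[idx[has] - 1] > windows[has, 0]
    return out


def ctcf_boundary_fraction(b: BoundarySet, ctcf: PeakSet) -> float:
    """Fraction of boundary +/-flank windows containing at least one CTCF peak."""
    if b.count == 0:
        raise ValueError("empty boundary set")
    hit = total = 0
    for chrom, pts in b.points.items():
        if len(pts) == 0:
            continue
        windows = b.windows(chrom)
        hits = _any_overlap(windows, ctcf.spans(chrom))
        hit += int(hits.sum())
        total += len(pts)
    return hit / total


def common_domains(d1: list[ContactDomain], d2: list[ContactDomain],
                   min_frac: float = 0.8):
    """Best-reciprocal matching of domains with > min_frac overlap both ways.

    Returns (pairs, specific1, specific2); each domain joins at most one
    pair, chosen greedily by the smaller of the two overlap fractions.
    """
    cands = []
    for i, x in enumerate(d1):
        for j, y in enumerate(d2):
            f1, f2 = overlap_fraction(x.interval, y.interval)
            if f1 > min_frac and f2 > min_frac:
                cands.append((min(f1, f2), i, j))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used1: set[int] = set()
    used2: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        pairs.append((d1[i], d2[j]))
    specific1 = [d for i, d in enumerate(d1) if i not in used1]
    specific2 = [d for j, d in enumerate(d2) if j not in used2]
    return pairs, specific1, specific2


_STATE_MARKS = ("H3K9me3", "H3K27me3", "H3K36me3")


def classify_domain_states(domains: list[ContactDomain],
                           peaks: dict[str, PeakSet],
                           top_quantile: float = 0.25) -> pd.DataFrame:
    """Histone-state flags and a single-class view per domain.

    For each of H3K9me3 / H3K27me3 / H3K36me3 the peaks with signal in the
    top ``top_quantile`` are selected (ties included); a domain is
    mark-enriched iff it intersects at least one selected peak.  The derived
    class applies the precedence active (H3K36me3) > heterochromatic
    (H3K9me3) > repressed (H3K27me3), else 'none'.
    """
    import warnings as _warnings
    flags = {}
    for mark in _STATE_MARKS:
        ps = peaks.get(mark)
        if ps is None or len(ps) == 0:
            _warnings.warn(f"no peaks for {mark}; all flags false")
            flags[mark] = np.zeros(len(domains), dtype=bool)
            continue
        top = ps.top_signal(top_quantile)
        by_chrom = {c: top.spans(c) for c in top.df["chrom"].unique()}
        hit = np.zeros(len(domains), dtype=bool)
        for k, d in enumerate(domains):
            spans = by_chrom.get(d.interval.chrom)
            if spans is None:
                continue
            window = np.array([[d.interval.start, d.interval.end]])
            hit[k] = bool(_any_overlap(window, spans)[0])
        flags[mark] = hit
    cls = np.full(len(domains), "none", dtype=object)
    cls[flags["H3K27me3"]] = "repressed"
    cls[flags["H3K9me3"]] = "heterochromatic"
    cls[flags["H3K36me3"]] = "active"
    return pd.DataFrame({
        "chrom": [d.interval.chrom for d in domains],
        "start": [d.interval.start for d in domains],
        "end": [d.interval.end for d in domains],
        "H3K9me3": flags["H3K9me3"],
        "H3K27me3": flags["H3K27me3"],
        "H3K36me3": flags["H3K36me3"],
        "class": cls,
    })


def state_switch_genes(common_pairs: list[tuple[ContactDomain, ContactDomain]],
                       s1: pd.DataFrame, s2: pd.DataFrame,
                       genes: GeneTable, de: pd.DataFrame) -> dict:
    """Genes in common domains that are inactive in sample 1 and active in 2.

    ``s1``/``s2`` are state tables from :func:`classify_domain_states` for
    the full domain lists of each sample; rows are matched by coordinates.
    A gene belongs to a pair when its locus midpoint lies inside the
    sample-2 domain.  The report counts genes with positive / negative /
    zero-or-missing log2 fold change and lists the significantly
    upregulated subset (adjusted p <= 0.05 and log2FC >= 1).
    """
    def state_of(table: pd.DataFrame, d: ContactDomain) -> str:
        row = table[(table["chrom"] == d.interval.chrom)
                    & (table["start"] == d.interval.start)
                    & (table["end"] == d.interval.end)]
        return str(row["class"].iloc[0]) if len(row) else "none"

    switching = [(x, y) for x, y in common_pairs
                 if state_of(s1, x) in ("heterochromatic", "repressed")
                 and state_of(s2, y) == "active"]
    gene_ids = []
    for _x, y in switching:
        iv = y.interval
        sub = genes.df[genes.df["chrom"] == iv.chrom]
        mid = (sub["start"] + sub["end"]) // 2
        gene_ids.extend(sub.loc[(mid >= iv.start) & (mid < iv.end), "gene_id"])
    gene_ids = sorted(set(gene_ids))
    up = down = unchanged = 0
    sig_up = []
    for g in gene_ids:
        if g not in de.index:
            unchanged += 1
            continue
        lfc = float(de.loc[g, "log2FoldChange"])
        padj = de.loc[g, "padj"] if "padj" in de.columns else np.nan
        if lfc > 0:
            up += 1
        elif lfc < 0:
            down += 1
        else:
            unchanged += 1
        if lfc >= 1 and pd.notna(padj) and padj <= 0.05:
            sig_up.append(g)
    return {
        "switching_pairs": switching,
        "genes": gene_ids,
        "n_up": up,
        "n_down": down,
        "n_unchanged": unchanged,
        "significant_up": sorted(sig_up),
    }


def domain_size_stats(d1: list[ContactDomain], d2: list[ContactDomain]) -> dict:
    """Descriptive size statistics (bp) plus a two-sided rank-sum p-value."""
    from .expression import wilcoxon_rank_sum
    if not d1 or not d2:
        raise ValueError("both domain lists must be non-empty")
    s1 = np.array([len(d) for d in d1], dtype=float)
    s2 = np.array([len(d) for d in d2], dtype=float)
    stat, p = wilcoxon_rank_sum(s1, s2, alternative="two-sided")
    return {
        "n1": len(s1), "n2": len(s2),
        "mean1": float(s1.mean()), "mean2": float(s2.mean()),
        "median1": float(np.median(s1)), "median2": float(np.median(s2)),
        "statistic": stat, "p_value": p,
    }
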