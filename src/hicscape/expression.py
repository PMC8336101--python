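"""Expression and survival statistics used across the pipeline.

Differential expression is delegated to DESeq2 (via pydeseq2), matching the
standard two-group negative-binomial Wald analysis, with the usual flags
(BH-adjusted p <= 0.05 and |log2 fold change| >= 1).  The rank-sum test has
an exact enumeration path at small sample sizes (ties handled through
midranks) and a tie-corrected normal approximation otherwise.  Gene-set
scoring is a single-sample rank-based running-sum enrichment score
(ssGSEA-style) with the median-split stratification used for Kaplan-Meier /
log-rank survival comparisons; Kaplan-Meier and log-rank come from
lifelines.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.base import BaseEstimator

__all__ = [
    "ExpressionMatrix",
    "de_test",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "GeneSetScorer",
    "gene_set_score",
    "km_estimator",
    "logrank_test",
    "fpkm",
]


@dataclass
class ExpressionMatrix:
    """Raw counts (genes x samples) with replicate group labels.

    ``groups`` maps sample name -> group label (e.g. cell line); ``lengths``
    holds gene lengths in bp for FPKM computation.
    """

    counts: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def fpkm(self) -> pd.DataFrame:
        if self.lengths is None:
            raise ValueError("gene lengths required for FPKM")
        return fpkm(self.counts, self.lengths)


def fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """counts * 1e9 / (gene length * library size); locus length, no isoforms."""
    lib = counts.sum(axis=0).astype(float)
    lengths = lengths.reindex(counts.index)
    return counts.mul(1e9) .div(lib, axis=1).div(lengths, axis=0)


# ---------------------------------------------------------------------------
# differential expression (DESeq2 via pydeseq2)

def de_test(x: ExpressionMatrix, group1: str, group2: str,
            alpha: float = 0.05, lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Two-group differential expression, group2 vs group1 (DESeq2 Wald test).

    Genes with zero counts in every sample of both groups are excluded and
    reported in the ``excluded`` attribute of the returned frame
    (``result.attrs['excluded']``).  The DE flag is
    ``padj <= alpha and |log2FoldChange| >= lfc_threshold``.
    """
    s1, s2 = x.samples_in_group(group1), x.samples_in_group(group2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("need >= 2 replicates per group")
    sub = x.counts[s1 + s2]
    nonzero = sub.sum(axis=1) > 0
    excluded = list(sub.index[~nonzero])
    sub = sub[nonzero]

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats
    meta = pd.DataFrame({"condition": ["g1"] * len(s1) + ["g2"] * len(s2)},
                        index=s1 + s2)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(counts=sub.T.astype(int), metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "g2", "g1"], quiet=True)
        stats.summary()
    res = stats.results_df.copy()
    res = res.rename_axis("gene_id")
    res["flag"] = (res["padj"].notna() & (res["padj"] <= alpha)
                   & (res["log2FoldChange"].abs() >= lfc_threshold))
    res.attrs["excluded"] = excluded
    return res


# ---------------------------------------------------------------------------
# rank-sum test

def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided",
                      exact_max_n: int = 12) -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (rank-sum statistic of ``a``, p).

    For ``len(a) + len(b) <= exact_max_n`` the null distribution is
    enumerated exactly over all assignments of the pooled values (midranks,
    so ties are handled); otherwise a tie-corrected normal approximation
    with continuity correction is used.  ``alternative`` is 'two-sided',
    'greater' (a tends larger) or 'less'.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty input")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = float(ranks[:n].sum())
    if n + m <= exact_max_n:
        stats = np.array([ranks[list(comb)].sum()
                          for comb in itertools.combinations(range(n + m), n)])
        p_greater = float((stats >= w - 1e-12).mean())
        p_less = float((stats <= w + 1e-12).mean())
    else:
        mean = n * (n + m + 1) / 2
        # tie correction on the variance
        _, tie_counts = np.unique(pooled, return_counts=True)
        tc = (tie_counts ** 3 - tie_counts).sum()
        N = n + m
        var = n * m / 12 * ((N + 1) - tc / (N * (N - 1)))
        if var == 0:
            p_greater = p_less = 1.0
        else:
            sd = np.sqrt(var)
            p_greater = float(norm.sf((w - mean - 0.5) / sd))
            p_less = float(norm.cdf((w - mean + 0.5) / sd))
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2 * min(p_greater, p_less))
    return w, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# single-sample gene-set scoring

class GeneSetScorer(BaseEstimator):
    """Rank-based single-sample gene-set enrichment score with median split.

    For each sample, genes are ranked by expression (descending, midranks on
    ties broken by order after a stable sort).  A running sum walks the
    ranked list: hits (set members) increment proportionally to
    ``rank_value ** weight`` (rank_value = N .. 1), misses decrement
    uniformly; the score is the sum of the running-sum values (ssGSEA-style
    area statistic).  ``transform`` returns a table with the per-sample
    score and a 'high'/'low' group assignment split at the median (score
    <= median -> 'low').
    """

    def __init__(self, weight: float = 0.25):
        self.weight = weight

    def fit(self, expr: pd.DataFrame, gene_set: list[str]) -> "GeneSetScorer":
        hits = expr.index.isin(set(gene_set))
        if not hits.any():
            raise ValueError("gene set shares no genes with the matrix")
        self.gene_set_ = [g for g in gene_set if g in set(expr.index)]
        return self

    def transform(self, expr: pd.DataFrame) -> pd.DataFrame:
        hit_mask = expr.index.isin(set(self.gene_set_))
        n = len(expr.index)
        scores = {}
        for sample in expr.columns:
            vals = expr[sample].to_numpy(dtype=float)
            order = np.argsort(-vals, kind="mergesort")
            hits = hit_mask[order]
            rank_value = np.arange(n, 0, -1, dtype=float)
            inc = np.where(hits, rank_value ** self.weight, 0.0)
            if inc.sum() == 0:
                scores[sample] = 0.0
                continue
            inc /= inc.sum()
            n_miss = n - hits.sum()
            dec = np.where(~hits, 1.0 / n_miss if n_miss else 0.0, 0.0)
            running = np.cumsum(inc - dec)
            scores[sample] = float(running.sum())
        out = pd.DataFrame({"score": pd.Series(scores)})
        med = out["score"].median()
        out["group"] = np.where(out["score"] <= med, "low", "high")
        out.index.name = "sample"
        return out

    def fit_transform(self, expr: pd.DataFrame, gene_set: list[str]) -> pd.DataFrame:
        return self.fit(expr, gene_set).transform(expr)


def gene_set_score(expr: pd.DataFrame, gene_set: list[str],
                   weight: float = 0.25) -> pd.DataFrame:
    """Functional wrapper over :class:`GeneSetScorer`."""
    return GeneSetScorer(weight=weight).fit_transform(expr, gene_set)


# ---------------------------------------------------------------------------
# survival

def km_estimator(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate; frame with columns time, survival."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p), 1 df."""
    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int),
                       "group": np.asarray(group)})
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    g1 = df[df["group"] == levels[0]]
    g2 = df[df["group"] == levels[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("a group has no subjects")
    res = _ll_logrank(g1["time"], g2["time"],
                      event_observed_A=g1["event"], event_observed_B=g2["event"])
    return float(res.test_statistic), float(res.p_value)
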