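"""A/B compartment calling, switch analysis, and PC1 clustering.

Compartments are called per chromosome from a balanced contact matrix at
megabase resolution: the observed/expected map is turned into a Pearson
correlation matrix, its leading eigenvectors are extracted, and the
component that correlates best (in absolute value) with gene density is
chosen and oriented so that the correlation is positive.  Positive entries
are labelled A (active, gene dense), negative entries B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator

from .core import GeneTable
from .matrix import ContactMatrix, expected_by_distance, valid_bins

__all__ = [
    "CompartmentProfile",
    "CompartmentCaller",
    "compartment_call",
    "switch_fraction",
    "cluster_pc1",
    "concordant_switch_genes",
    "gene_density_per_bin",
]


@dataclass
class CompartmentProfile:
    """Oriented eigenvector values and A/B labels per bin of one sample.

    ``pc1`` maps chromosome -> float array (NaN on invalid bins); ``labels``
    maps chromosome -> array of 'A'/'B'/'' (empty = invalid).  ``component``
    records which of the candidate eigenvector components was chosen per
    chromosome (1-based).
    """

    sample: str
    resolution: int
    pc1: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    component: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, vals in self.pc1.items():
            labs = self.labels[chrom]
            for i, (v, l) in enumerate(zip(vals, labs)):
                rows.append((chrom, i * self.resolution, (i + 1) * self.resolution, v, l))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "pc1", "label"])

    def write_bedgraph(self, path) -> None:
        df = self.to_frame()
        df[["chrom", "start", "end", "pc1"]].to_csv(
            path, sep="\t", index=False, header=False, float_format="%.6g")


def gene_density_per_bin(genes: GeneTable, layout, resolution: int) -> dict[str, np.ndarray]:
    """Number of gene TSSs per bin, the orientation covariate for calling."""
    density = {}
    for chrom in layout.names:
        n = layout.n_bins(chrom, resolution)
        tss = genes.tss_positions(chrom)
        density[chrom] = np.bincount(
            np.clip(tss // resolution, 0, n - 1), minlength=n).astype(float)
    return density


class CompartmentCaller(BaseEstimator):
    """Eigenvector-based A/B compartment caller on a balanced 1-Mb matrix.

    Parameters
    ----------
    n_components : int
        Number of leading eigenvectors considered as candidates; the one
        with maximal |Pearson correlation| to gene density is kept.  This
        automates the usual manual curation of PC1/PC2/PC3 against gene
        density and the plaid pattern.
    min_valid_bins : int
        Chromosomes with fewer valid bins are reported entirely invalid.

    Attributes
    ----------
    profile_ : CompartmentProfile
    """

    def __init__(self, n_components: int = 3, min_valid_bins: int = 10):
        self.n_components = n_components
        self.min_valid_bins = min_valid_bins

    def fit(self, m: ContactMatrix, gene_density: dict[str, np.ndarray],
            sample: str = "sample") -> "CompartmentCaller":
        if not m.normalized:
            raise ValueError("compartment calling requires a balanced matrix")
        pc1, labels, component = {}, {}, {}
        for chrom in m.chromosomes:
            n = m.n_bins(chrom)
            density = np.asarray(gene_density[chrom], dtype=float)
            if len(density) != n:
                raise ValueError(f"{chrom}: gene density not aligned to bins")
            vec, comp = self._call_chrom(m, chrom, density)
            pc1[chrom] = vec
            component[chrom] = comp
            lab = np.full(n, "", dtype=object)
            lab[np.nan_to_num(vec) > 0] = "A"
            lab[np.nan_to_num(vec) < 0] = "B"
            lab[np.isnan(vec)] = ""
            labels[chrom] = lab
        self.profile_ = CompartmentProfile(sample, m.resolution, pc1, labels, component)
        return self

    def _call_chrom(self, m: ContactMatrix, chrom: str, density: np.ndarray):
        n = m.n_bins(chrom)
        out = np.full(n, np.nan)
        mask = valid_bins(m, chrom)
        if mask.sum() < self.min_valid_bins:
            warnings.warn(f"{chrom}: fewer than {self.min_valid_bins} valid bins; "
                          "all bins reported invalid")
            return out, 0
        prof = expected_by_distance(m, chrom)
        dense = m.dense(chrom)
        idx = np.where(mask)[0]
        sub = dense[np.ix_(idx, idx)]
        d = np.abs(idx[:, None] - idx[None, :])
        e = prof.values[d]
        with np.errstate(divide="ignore", invalid="ignore"):
            sub = np.where(e > 0, sub / e, 0.0)
        # zero-variance columns are masked, not imputed
        var_ok = sub.std(axis=0) > 0
        if var_ok.sum() < self.min_valid_bins:
            warnings.warn(f"{chrom}: correlation matrix degenerate; bins invalid")
            return out, 0
        idx = idx[var_ok]
        sub = sub[np.ix_(var_ok, var_ok)]
        corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1][: self.n_components]
        dens = density[idx]
        # candidate score = |corr with gene density| x eigenvalue: density
        # alone orients reliably but selects unreliably once compartment
        # switching has decoupled current state from the (fixed) gene
        # annotation, so the plaid-dominant component is preferred and
        # density breaks ties and fixes the sign
        best, best_corr, best_comp, best_score = None, 0.0, 1, -1.0
        for rank, col in enumerate(order, start=1):
            vec = evecs[:, col]
            if vec.std() == 0 or dens.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(vec, dens)[0, 1])
            score = abs(r) * max(float(evals[col]), 0.0)
            if best is None or score > best_score:
                best, best_corr, best_comp, best_score = vec, r, rank, score
        if best_corr < 0:
            best = -best
        out[idx] = best
        return out, best_comp


def compartment_call(m: ContactMatrix, gene_density: dict[str, np.ndarray],
                     n_components: int = 3, sample: str = "sample") -> CompartmentProfile:
    """Functional wrapper over :class:`CompartmentCaller`."""
    return CompartmentCaller(n_components=n_components).fit(
        m, gene_density, sample=sample).profile_


def switch_fraction(p1: CompartmentProfile, p2: CompartmentProfile
                    ) -> tuple[float, pd.DataFrame]:
    """Percentage of jointly valid bins whose A/B label flips, plus the table.

    The switch class per bin is one of A->A, A->B, B->A, B->B or 'invalid';
    the percentage denominator is the number of bins valid in both samples.
    """
    if p1.resolution != p2.resolution or set(p1.labels) != set(p2.labels):
        raise ValueError("profiles must share layout and resolution")
    rows = []
    switched = valid = 0
    for chrom in p1.labels:
        l1, l2 = p1.labels[chrom], p2.labels[chrom]
        if len(l1) != len(l2):
            raise ValueError(f"{chrom}: bin count mismatch")
        for i, (a, b) in enumerate(zip(l1, l2)):
            if a and b:
                cls = f"{a}->{b}"
                valid += 1
                if a != b:
                    switched += 1
            else:
                cls = "invalid"
            rows.append((chrom, i, a, b, cls))
    if valid == 0:
        raise ValueError("no bin is valid in both samples")
    table = pd.DataFrame(rows, columns=["chrom", "bin", "label1", "label2", "class"])
    return 100.0 * switched / valid, table


def cluster_pc1(profiles: list[CompartmentProfile]) -> pd.DataFrame:
    """Per-bin A/B sign pattern across samples, with a hierarchical ordering.

    Returns a frame with one row per jointly valid bin: chrom, bin, the
    pattern string (one letter per sample, e.g. 'BBA' for a bin that is B in
    the first two samples and A in the third), per-sample PC1 values, and an
    ``order`` column giving the bin's position in the hierarchical-clustering
    leaf ordering of the PC1 vectors (for heatmap rendering).
    """
    if len(profiles) < 1:
        raise ValueError("need at least one profile")
    chroms = list(profiles[0].labels)
    rows = []
    for chrom in chroms:
        n = len(profiles[0].labels[chrom])
        for i in range(n):
            labs = [p.labels[chrom][i] for p in profiles]
            if all(labs):
                vals = [p.pc1[chrom][i] for p in profiles]
                rows.append((chrom, i, "".join(labs), *vals))
    cols = ["chrom", "bin", "pattern"] + [p.sample for p in profiles]
    df = pd.DataFrame(rows, columns=cols)
    if len(df) >= 2:
        mat = df[[p.sample for p in profiles]].to_numpy()
        order = leaves_list(linkage(mat, method="average"))
        rank = np.empty(len(df), dtype=int)
        rank[order] = np.arange(len(df))
        df["order"] = rank
    else:
        df["order"] = np.arange(len(df))
    return df


def concordant_switch_genes(pattern: pd.DataFrame, genes: GeneTable,
                            de: pd.DataFrame, target_pattern: str,
                            direction: str, resolution: int
                            ) -> tuple[list[str], list[str]]:
    """Genes whose locus midpoint falls in a bin with ``target_pattern`` and
    whose expression change matches ``direction`` ('up': log2FC > 0).

    ``de`` must be indexed by gene id with a ``log2FoldChange`` column.
    Returns (selected gene ids, genes skipped because absent from ``de``).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    target_bins = {(r.chrom, r.bin) for r in
                   pattern[pattern["pattern"] == target_pattern].itertuples()}
    selected, skipped = [], []
    for row in genes.df.itertuples():
        bin_id = ((row.start + row.end) // 2) // resolution
        if (row.chrom, bin_id) not in target_bins:
            continue
        if row.gene_id not in de.index:
            skipped.append(row.gene_id)
            continue
        lfc = float(de.loc[row.gene_id, "log2FoldChange"])
        if (direction == "up" and lfc > 0) or (direction == "down" and lfc < 0):
            selected.append(row.gene_id)
    return selected, skipped
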