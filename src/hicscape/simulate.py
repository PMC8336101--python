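"""Synthetic multi-omic study generator with planted multiscale structure.

The generator emulates the statistical structure of a two-condition Hi-C /
ChIP-seq / ATAC-seq / RNA-seq study of tumor progression (a "primary" and a
"metastatic" sample): a distance-decay contact background with a
compartment plaid, nested contact domains, focal loop peaks and per-bin
coverage biases; histone-state-consistent peak tracks; expression tied to
the planted structure; and a patient cohort whose survival is linked to a
planted gene-set signal.  Every planted feature is recorded in a
:class:`SimulationTruth` so each pipeline stage has a recovery target.

Planted effects between the two samples:

* a configured fraction of megabase bins switches compartment (B in the
  primary sample, A in the metastatic one, mirroring the focal B->A class),
* a configured fraction of contact domains splits in two in the metastatic
  sample, and a disjoint fraction keeps its span but switches histone
  state from inactive (H3K9me3/H3K27me3) to active (H3K36me3),
* loops are common or sample-specific, each an enhancer-promoter pair;
  genes looped to metastatic-specific enhancers are upregulated, genes
  looped to primary-specific enhancers downregulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import GeneTable, GenomeLayout, PeakSet
from .matrix import ContactMatrix

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "generate_truth",
    "simulate_hic",
    "simulate_tracks",
    "simulate_expression_survival",
    "simulate_counts",
    "simulate_study",
    "write_truth",
]

SAMPLES = ("primary", "metastatic")


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic generator (defaults = the
    desk-scale study conditions; see the methods note)."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000})
    resolution: int = 5000
    compartment_resolution: int = 1_000_000
    depth: int = 1_000_000            # contacts per chromosome
    decay_alpha: float = 1.0
    plaid_strength: float = 2.0       # same-label x s, cross-label x 1/s
    plaid_min_dist_bins: int = 200    # plaid applies beyond this separation only
    compartment_block_bins: tuple[int, int] = (2, 6)   # 1-Mb block length range
    switch_fraction: float = 0.3      # fraction of 1-Mb bins flipping (B->A first)

    n_domains_per_chrom: int = 10
    n_nested_per_chrom: int = 1
    domain_enrichment: float = 3.0
    domain_min_bins: int = 20
    domain_max_bins: int = 60
    domain_split_fraction: float = 0.2
    state_switch_fraction: float = 0.2

    n_loops_common: int = 5           # per chromosome
    n_loops_specific1: int = 3
    n_loops_specific2: int = 6        # the focal metastatic-specific set;
                                      # large enough that its recovery
                                      # statistics are stable
    loop_enrichment: float = 6.0
    loop_peak_bins: int = 2
    loop_min_dist_bins: int = 6       # 30 kb: canonical enhancer-promoter range
    loop_max_dist_bins: int = 12      # 60 kb

    # coverage spread of retained 5-kb bins after the usual low-coverage
    # filtering; wider spreads leave focal peaks at unlucky anchor pairs
    # without enough raw counts to ever reach significance at this depth
    bias_range: tuple[float, float] = (0.65, 1.55)

    n_genes_per_chrom: int = 300
    gene_length_range: tuple[int, int] = (5000, 20000)
    a_density_weight: float = 3.0     # gene-placement weight of A vs B bins
    a_expression_log2_boost: float = 1.0

    n_replicates: int = 3
    base_log_mean: float = np.log(200.0)
    nb_dispersion: float = 0.1
    de_effect_log2fc: float = 2.0

    ctcf_boundary_rate: float = 0.8
    ctcf_anchor_rate: float = 0.8
    peaks_per_state_domain: int = 3
    n_background_enhancers_per_chrom: int = 20

    n_patients: int = 176
    hazard_ratio: float = 2.0
    baseline_hazard: float = 1.0 / 1000.0   # per day
    censor_time: float = 2000.0             # days

    seed: int = 0

    def layout(self) -> GenomeLayout:
        return GenomeLayout(dict(self.chrom_lengths))

    def validate(self) -> None:
        if self.plaid_strength <= 0 or self.domain_enrichment <= 0 \
                or self.loop_enrichment <= 0:
            raise ValueError("all strengths must be > 0")
        for frac in (self.switch_fraction, self.domain_split_fraction,
                     self.state_switch_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


INACTIVE_STATES = ("heterochromatic", "repressed")
STATE_MARK = {"active": "H3K36me3", "heterochromatic": "H3K9me3",
              "repressed": "H3K27me3"}


@dataclass
class SimulationTruth:
    """Ground truth for one synthetic study (see module docstring)."""

    cfg: SimConfig
    compartments: dict[str, dict[str, np.ndarray]]       # sample -> chrom -> labels
    switched_bins: list[tuple[str, int]]                 # (chrom, 1-Mb bin)
    domains: dict[str, pd.DataFrame]                     # sample -> frame
    state_switch_spans: list[tuple[str, int, int]]       # common spans inactive->active
    loops: pd.DataFrame
    genes: pd.DataFrame                                  # gene models + roles
    effects: pd.Series                                   # log2FC metastatic vs primary
    bias: dict[str, np.ndarray]
    ndrs: pd.DataFrame
    upregulated_loop_genes: list[str]
    seed: int

    def domain_boundaries(self, sample: str) -> dict[str, np.ndarray]:
        res = self.cfg.resolution
        pts: dict[str, set[int]] = {}
        for row in self.domains[sample].itertuples():
            pts.setdefault(row.chrom, set()).update(
                (row.start_bin * res, row.end_bin * res))
        return {c: np.array(sorted(v)) for c, v in sorted(pts.items())}


def generate_truth(cfg: SimConfig) -> SimulationTruth:
    """Plant all structures deterministically from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout()
    res = cfg.resolution
    factor = cfg.compartment_resolution // res

    # --- compartments: alternating A/B blocks, then B->A flips in sample 2
    compartments: dict[str, dict[str, np.ndarray]] = {s: {} for s in SAMPLES}
    switched: list[tuple[str, int]] = []
    for chrom in layout.names:
        n_mb = layout.n_bins(chrom, cfg.compartment_resolution)
        labels = np.empty(n_mb, dtype=object)
        pos = 0
        current = "A" if rng.integers(2) else "B"
        while pos < n_mb:
            block = int(rng.integers(cfg.compartment_block_bins[0],
                                     cfg.compartment_block_bins[1] + 1))
            labels[pos:pos + block] = current
            current = "B" if current == "A" else "A"
            pos += block
        compartments["primary"][chrom] = labels.copy()
        n_flip = int(round(cfg.switch_fraction * n_mb))
        # switching is segmental: whole blocks (or contiguous block ends)
        # flip, keeping the plaid blocky; scattered single-bin flips would
        # leave no coherent checkerboard for the eigenvector to see.  B->A
        # blocks flip first (the focal class); A->B only if B runs out.
        # Each compartment keeps >= ~30% of the chromosome so the plaid
        # stays resolvable in both samples.
        lab2 = labels.copy()
        flipped: list[int] = []
        for target in ("B", "A"):
            if len(flipped) >= n_flip:
                break
            blocks = _label_blocks(labels, target)
            rng.shuffle(blocks)
            floor_keep = max(2, int(np.ceil(0.3 * n_mb)))
            avail = max(0, int((labels == target).sum()) - floor_keep)
            budget = min(n_flip - len(flipped), avail)
            for lo, hi in blocks:
                if budget <= 0:
                    break
                take = min(hi - lo, budget)
                lab2[lo:lo + take] = "A" if target == "B" else "B"
                flipped.extend(range(lo, lo + take))
                budget -= take
        compartments["metastatic"][chrom] = lab2
        switched.extend((chrom, int(b)) for b in sorted(flipped))

    # --- domains ---------------------------------------------------------
    states_cycle = ("active", "heterochromatic", "repressed")
    dom_rows = {s: [] for s in SAMPLES}
    state_switch_spans: list[tuple[str, int, int]] = []
    nested_rows = {s: [] for s in SAMPLES}
    for chrom in layout.names:
        n = layout.n_bins(chrom, res)
        spans = _place_disjoint(rng, n, cfg.n_domains_per_chrom,
                                cfg.domain_min_bins, cfg.domain_max_bins, gap=5)
        if len(spans) < cfg.n_domains_per_chrom:
            raise ValueError("infeasible config: cannot place requested domains")
        states = [states_cycle[k % 3] for k in range(len(spans))]
        n_split = int(round(cfg.domain_split_fraction * len(spans)))
        n_state = int(round(cfg.state_switch_fraction * len(spans)))
        inactive_idx = [k for k, st in enumerate(states) if st in INACTIVE_STATES]
        if len(inactive_idx) < n_split + n_state:
            raise ValueError("infeasible config: not enough inactive domains "
                             "for the requested split/state-switch fractions")
        chosen = rng.choice(inactive_idx, size=n_split + n_state, replace=False)
        split_idx = set(int(k) for k in chosen[:n_split])
        state_idx = set(int(k) for k in chosen[n_split:])
        for k, ((a, b), st) in enumerate(zip(spans, states)):
            dom_rows["primary"].append((chrom, a, b, st, "kept"))
            if k in split_idx:
                mid = (a + b) // 2
                dom_rows["metastatic"].append((chrom, a, mid, "active", "split_left"))
                dom_rows["metastatic"].append((chrom, mid, b, st, "split_right"))
            elif k in state_idx:
                dom_rows["metastatic"].append((chrom, a, b, "active", "state_switch"))
                state_switch_spans.append((chrom, a, b))
            else:
                dom_rows["metastatic"].append((chrom, a, b, st, "kept"))
        # nested sub-domains inside the largest domains, same in both samples
        by_size = sorted(range(len(spans)),
                         key=lambda k: spans[k][1] - spans[k][0], reverse=True)
        for k in by_size[: cfg.n_nested_per_chrom]:
            a, b = spans[k]
            third = (b - a) // 3
            if third >= 10:
                nested = (a + third, a + 2 * third)
                for s in SAMPLES:
                    nested_rows[s].append((chrom, nested[0], nested[1],
                                           states[k], "nested"))
    domains = {}
    for s in SAMPLES:
        domains[s] = pd.DataFrame(dom_rows[s] + nested_rows[s],
                                  columns=["chrom", "start_bin", "end_bin",
                                           "state", "role"])

    # --- loops (enhancer-promoter) --------------------------------------
    # anchors keep a donut-width margin from every domain boundary (of any
    # sample): a focal peak straddling a sharp background step is tested
    # against a mixed local expectation and is not a clean recovery target
    loop_rows = []
    for chrom in layout.names:
        n = layout.n_bins(chrom, res)
        edge_bins: set[int] = set()
        for s in SAMPLES:
            for row in domains[s][domains[s]["chrom"] == chrom].itertuples():
                for point in (row.start_bin, row.end_bin):
                    edge_bins.update(range(point - 8, point + 9))
        total = cfg.n_loops_common + cfg.n_loops_specific1 + cfg.n_loops_specific2
        anchors = _place_loop_anchors(rng, n, total, cfg.loop_min_dist_bins,
                                      cfg.loop_max_dist_bins, forbidden=edge_bins)
        if len(anchors) < total:
            raise ValueError("infeasible config: more loops than anchor slots")
        presence = (["common"] * cfg.n_loops_common
                    + ["primary"] * cfg.n_loops_specific1
                    + ["metastatic"] * cfg.n_loops_specific2)
        for (b1, b2), pres in zip(anchors, presence):
            loop_rows.append((chrom, int(b1), int(b2), pres))
    loops = pd.DataFrame(loop_rows, columns=["chrom", "bin1", "bin2", "presence"])
    loops["gene_id"] = [f"LG{k:03d}" for k in range(len(loops))]

    # the enhancer peak spans both bins of the planted peak block, and the
    # promoter TSS sits just past the block's internal bin boundary so the
    # upstream 2-kb window touches both bins: whichever block pixel the
    # caller reports, its anchor overlaps the element
    p = cfg.loop_peak_bins
    loops["enh_start"] = loops["bin1"] * res + 1500
    loops["enh_end"] = (loops["bin1"] + p) * res - 3000
    loops["tss"] = (loops["bin2"] + p - 1) * res + 1999

    # --- genes -----------------------------------------------------------
    gene_rows = []
    effects = {}
    for row in loops.itertuples():
        length = int(rng.integers(8000, 15000))
        gene_rows.append((row.gene_id, row.chrom, row.tss, row.tss + length, "+",
                          "loop_" + row.presence))
        if row.presence == "metastatic":
            effects[row.gene_id] = cfg.de_effect_log2fc
        elif row.presence == "primary":
            effects[row.gene_id] = -cfg.de_effect_log2fc
        else:
            effects[row.gene_id] = 0.0
    # exclusion zones: no background TSS within 2.1 kb of a planted enhancer,
    # and none inside loop-anchor bins
    forbidden = {c: [] for c in layout.names}
    for row in loops.itertuples():
        forbidden[row.chrom].append((row.enh_start - 2100, row.enh_end + 2100))
        for b in (row.bin1, row.bin2):
            forbidden[row.chrom].append((b * res, (b + p) * res))
    gid = 0
    mb_factor = cfg.compartment_resolution
    for chrom in layout.names:
        labels = compartments["primary"][chrom]
        weights = np.where(labels == "A", cfg.a_density_weight, 1.0)
        weights = weights / weights.sum()
        zones = forbidden[chrom]
        length_bp = layout.lengths[chrom]
        placed = 0
        while placed < cfg.n_genes_per_chrom:
            mb_bin = int(rng.choice(len(labels), p=weights))
            tss = int(mb_bin * mb_factor + rng.integers(0, mb_factor))
            tss = min(tss, length_bp - 2500)
            if any(lo <= tss < hi for lo, hi in zones):
                continue
            glen = int(rng.integers(*cfg.gene_length_range))
            strand = "+" if rng.integers(2) else "-"
            if strand == "+":
                start, end = tss, min(tss + glen, length_bp)
            else:
                start, end = max(0, tss - glen), tss
            if end - start < 1000:
                continue
            gene_id = f"BG{gid:04d}"
            gid += 1
            role = "background"
            gene_rows.append((gene_id, chrom, start, end, strand, role))
            placed += 1
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end",
                                             "strand", "role"])
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    genes["mb_bin"] = genes[["start", "end"]].mean(axis=1).astype(int) // mb_factor

    # structural expression effects for background genes
    switched_set = set(switched)
    state_spans = {(c, a, b) for c, a, b in state_switch_spans}
    for row in genes.itertuples():
        if row.gene_id in effects:
            continue
        mid = (row.start + row.end) // 2
        in_state_switch = any(c == row.chrom and a * res <= mid < b * res
                              for c, a, b in state_spans)
        lab1 = compartments["primary"][row.chrom][row.mb_bin]
        lab2 = compartments["metastatic"][row.chrom][row.mb_bin]
        if in_state_switch:
            effects[row.gene_id] = cfg.de_effect_log2fc
        elif (row.chrom, row.mb_bin) in switched_set:
            effects[row.gene_id] = (cfg.de_effect_log2fc if (lab1, lab2) == ("B", "A")
                                    else -cfg.de_effect_log2fc)
        else:
            effects[row.gene_id] = 0.0
    effects = pd.Series(effects, name="log2fc")

    # --- coverage bias ----------------------------------------------------
    lo, hi = np.log(cfg.bias_range[0]), np.log(cfg.bias_range[1])
    bias = {chrom: np.exp(rng.uniform(lo, hi, layout.n_bins(chrom, res)))
            for chrom in layout.names}

    # --- NDR truth --------------------------------------------------------
    ndr_rows = []
    for row in loops.itertuples():
        ndr_rows.append((row.chrom, row.enh_start + 400, row.enh_start + 1100,
                         "enhancer", row.gene_id, row.presence))
        ndr_rows.append((row.chrom, row.tss - 1000, row.tss + 200,
                         "promoter", row.gene_id, row.presence))
    ndrs = pd.DataFrame(ndr_rows, columns=["chrom", "start", "end", "kind",
                                           "gene_id", "presence"])

    up_genes = sorted(loops.loc[loops["presence"] == "metastatic", "gene_id"])
    return SimulationTruth(cfg=cfg, compartments=compartments,
                           switched_bins=switched, domains=domains,
                           state_switch_spans=state_switch_spans, loops=loops,
                           genes=genes, effects=effects, bias=bias, ndrs=ndrs,
                           upregulated_loop_genes=up_genes, seed=cfg.seed)


def _label_blocks(labels: np.ndarray, target: str) -> list[tuple[int, int]]:
    """Maximal runs [lo, hi) of ``target`` in a label vector."""
    blocks = []
    lo = None
    for k, lab in enumerate(labels):
        if lab == target and lo is None:
            lo = k
        elif lab != target and lo is not None:
            blocks.append((lo, k))
            lo = None
    if lo is not None:
        blocks.append((lo, len(labels)))
    return blocks


def _place_disjoint(rng, n_bins: int, count: int, min_len: int, max_len: int,
                    gap: int) -> list[tuple[int, int]]:
    """Place ``count`` disjoint [a, b) spans separated by >= gap bins."""
    spans = []
    pos = gap
    for k in range(count):
        length = int(rng.integers(min_len, max_len + 1))
        slack = (n_bins - gap) - (pos + length)
        if slack < 0:
            break
        # spread remaining spans across the remaining sequence
        jump = int(rng.integers(0, max(1, slack // max(1, count - k))))
        a = pos + jump
        spans.append((a, a + length))
        pos = a + length + gap
    return spans


def _place_loop_anchors(rng, n_bins: int, count: int, dmin: int, dmax: int,
                        min_sep: int = 4,
                        forbidden: set[int] | None = None) -> list[tuple[int, int]]:
    forbidden = forbidden or set()
    anchors: list[tuple[int, int]] = []
    used: list[int] = []
    tries = 0
    while len(anchors) < count and tries < 20000:
        tries += 1
        b1 = int(rng.integers(dmax + 2, n_bins - dmax - 2))
        d = int(rng.integers(dmin, dmax + 1))
        b2 = b1 + d
        if b2 >= n_bins - 1:
            continue
        if b1 in forbidden or b2 in forbidden:
            continue
        if any(abs(b1 - u) < min_sep or abs(b2 - u) < min_sep for u in used):
            continue
        anchors.append((b1, b2))
        used.extend((b1, b2))
    return anchors


# ---------------------------------------------------------------------------
# Hi-C counts

def simulate_hic(truth: SimulationTruth, cfg: SimConfig | None = None,
                 samples: tuple = SAMPLES, seed: int | None = None
                 ) -> dict[str, ContactMatrix]:
    """Poisson contact matrices at ``cfg.resolution`` for each sample.

    The expected pixel value is
    ``depth * c * (1+|i-j|)^-alpha * plaid * domain * loop * b_i * b_j``
    with ``c`` normalising the per-chromosome total to ``depth``.
    """
    cfg = cfg or truth.cfg
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    layout = cfg.layout()
    res = cfg.resolution
    factor = cfg.compartment_resolution // res
    out = {}
    for sample in samples:
        data = {}
        for chrom in layout.names:
            n = layout.n_bins(chrom, res)
            expected = _expected_matrix(truth, cfg, sample, chrom, n, factor)
            iu, ju = np.triu_indices(n)
            mean = expected[iu, ju]
            scale = cfg.depth / mean.sum()
            counts = rng.poisson(mean * scale)
            nz = counts > 0
            data[chrom] = sp.coo_matrix(
                (counts[nz].astype(float), (iu[nz], ju[nz])), shape=(n, n))
        out[sample] = ContactMatrix(layout, res, data, normalized=False)
    return out


def _expected_matrix(truth: SimulationTruth, cfg: SimConfig, sample: str,
                     chrom: str, n: int, factor: int) -> np.ndarray:
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    expected = (1.0 + dist) ** (-cfg.decay_alpha)
    labels_mb = truth.compartments[sample][chrom]
    labels = np.repeat(labels_mb, factor)[:n]
    same = labels[:, None] == labels[None, :]
    s = cfg.plaid_strength
    # the checkerboard is a long-range feature: at sub-megabase separations
    # local structure (domains, loops) dominates and the plaid is invisible
    plaid = np.where(same, s, 1.0 / s)
    plaid[dist < cfg.plaid_min_dist_bins] = 1.0
    expected *= plaid
    doms = truth.domains[sample]
    for row in doms[doms["chrom"] == chrom].itertuples():
        expected[row.start_bin:row.end_bin, row.start_bin:row.end_bin] \
            *= cfg.domain_enrichment
    loops = truth.loops
    p = cfg.loop_peak_bins
    for row in loops[(loops["chrom"] == chrom)
                     & (loops["presence"].isin(["common", sample]))].itertuples():
        a0, a1 = row.bin1, min(row.bin1 + p, n)
        b0, b1 = row.bin2, min(row.bin2 + p, n)
        expected[a0:a1, b0:b1] *= cfg.loop_enrichment
        expected[b0:b1, a0:a1] *= cfg.loop_enrichment
    b = truth.bias[chrom]
    expected *= np.outer(b, b)
    return expected


# ---------------------------------------------------------------------------
# peak tracks and genes

def simulate_tracks(truth: SimulationTruth, cfg: SimConfig | None = None
                    ) -> tuple[dict[str, dict[str, PeakSet]], GeneTable]:
    """State-consistent peak tracks per sample plus the shared gene table.

    Histone-state marks put high-signal foreground peaks inside domains of
    the matching state; exactly three background peaks per foreground peak
    carry strictly lower signals, so the top-25% signal selection recovers
    the foreground deterministically.  H3K27ac carries the planted (and
    background) enhancers, H3K4me3 marks expressed-gene promoters, CTCF sits
    on domain boundaries and loop anchors at the configured rates, and ATAC
    peaks cover every planted NDR.
    """
    cfg = cfg or truth.cfg
    rng = np.random.default_rng(truth.seed + 2)
    layout = cfg.layout()
    res = cfg.resolution
    tracks: dict[str, dict[str, PeakSet]] = {}
    genes = _gene_table(truth, cfg)

    for sample in SAMPLES:
        marks: dict[str, PeakSet] = {}
        doms = truth.domains[sample]
        # state marks
        for state, mark in STATE_MARK.items():
            fg = []
            for row in doms[doms["state"] == state].itertuples():
                lo, hi = row.start_bin * res, row.end_bin * res - 2000
                for _ in range(cfg.peaks_per_state_domain):
                    s0 = int(rng.integers(lo, max(lo + 1, hi)))
                    fg.append((row.chrom, s0, s0 + 2000,
                               10.0 + float(rng.lognormal(1.0, 0.2))))
            bg = []
            for _ in range(3 * max(len(fg), 1)):
                chrom = layout.names[int(rng.integers(len(layout.names)))]
                s0 = int(rng.integers(0, layout.lengths[chrom] - 2000))
                sig = float(np.clip(rng.lognormal(0.0, 0.3), 0.05, 5.0))
                bg.append((chrom, s0, s0 + 2000, sig))
            marks[mark] = PeakSet(mark, pd.DataFrame(
                fg + bg, columns=["chrom", "start", "end", "signal"]))

        # H3K27ac: planted enhancers present in this sample + common background
        enh_rows = []
        lp = truth.loops
        for row in lp[lp["presence"].isin(["common", sample])].itertuples():
            enh_rows.append((row.chrom, row.enh_start, row.enh_end,
                             20.0 + float(rng.lognormal(1.0, 0.2))))
        bg_rng = np.random.default_rng(truth.seed + 3)   # shared across samples
        tss_by_chrom = {c: np.sort(genes.tss_positions(c)) for c in layout.names}
        for chrom in layout.names:
            placed = 0
            tss = tss_by_chrom[chrom]
            while placed < cfg.n_background_enhancers_per_chrom:
                s0 = int(bg_rng.integers(0, layout.lengths[chrom] - 1500))
                e0 = s0 + 1500
                k = np.searchsorted(tss, s0)
                near = []
                if k > 0:
                    near.append(s0 - tss[k - 1])
                if k < len(tss):
                    near.append(max(0, tss[k] - e0) if tss[k] >= e0 else 0)
                if near and min(near) <= 2100:
                    continue
                enh_rows.append((chrom, s0, e0,
                                 10.0 + float(bg_rng.lognormal(0.5, 0.3))))
                placed += 1
        marks["H3K27ac"] = PeakSet("H3K27ac", pd.DataFrame(
            enh_rows, columns=["chrom", "start", "end", "signal"]))

        # H3K4me3 at expressed-gene TSSs
        expressed = genes.expressed_ids(sample)
        k4_rows = []
        for row in genes.df.itertuples():
            if row.gene_id in expressed:
                k4_rows.append((row.chrom, max(0, row.tss - 1500), row.tss + 500,
                                10.0 + float(rng.lognormal(0.5, 0.3))))
        marks["H3K4me3"] = PeakSet("H3K4me3", pd.DataFrame(
            k4_rows, columns=["chrom", "start", "end", "signal"]))

        # CTCF at boundaries and anchors
        ctcf_rows = []
        for row in doms.itertuples():
            for point in (row.start_bin * res, row.end_bin * res):
                if rng.random() < cfg.ctcf_boundary_rate:
                    ctcf_rows.append((row.chrom, max(0, point - 500), point + 500,
                                      5.0 + float(rng.lognormal(0.5, 0.3))))
        for row in lp[lp["presence"].isin(["common", sample])].itertuples():
            for b in (row.bin1, row.bin2):
                if rng.random() < cfg.ctcf_anchor_rate:
                    mid = b * res + res // 2
                    ctcf_rows.append((row.chrom, mid - 500, mid + 500,
                                      5.0 + float(rng.lognormal(0.5, 0.3))))
        marks["CTCF"] = PeakSet("CTCF", pd.DataFrame(
            ctcf_rows, columns=["chrom", "start", "end", "signal"])
            .drop_duplicates(subset=["chrom", "start", "end"]))

        # ATAC covering every planted NDR of elements present in this sample
        atac_rows = []
        nd = truth.ndrs
        for row in nd[nd["presence"].isin(["common", sample])].itertuples():
            atac_rows.append((row.chrom, row.start, row.end,
                              5.0 + float(rng.lognormal(0.5, 0.3))))
        for _ in range(40):
            chrom = layout.names[int(rng.integers(len(layout.names)))]
            s0 = int(rng.integers(0, layout.lengths[chrom] - 800))
            atac_rows.append((chrom, s0, s0 + 800,
                              float(np.clip(rng.lognormal(0.0, 0.3), 0.05, 5.0))))
        marks["ATAC"] = PeakSet("ATAC", pd.DataFrame(
            atac_rows, columns=["chrom", "start", "end", "signal"]))
        tracks[sample] = marks
    return tracks, genes


def _gene_table(truth: SimulationTruth, cfg: SimConfig) -> GeneTable:
    df = truth.genes[["gene_id", "chrom", "start", "end", "strand"]].copy()
    table = GeneTable(df)
    # every planted gene stays above the FPKM-1 floor in both conditions
    # (down-regulation halves twice from a high baseline), so all genes are
    # expressed in both samples
    ids = truth.genes["gene_id"]
    for sample in SAMPLES:
        table.expressed[sample] = pd.Series(True, index=ids)
    return table


# ---------------------------------------------------------------------------
# expression and survival

def simulate_counts(rng, mu: np.ndarray, dispersion: float,
                    size: tuple) -> np.ndarray:
    """NB counts with mean ``mu`` (broadcast to ``size``) and common dispersion."""
    r = 1.0 / dispersion
    mu = np.broadcast_to(mu, size)
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size)


def simulate_expression_survival(truth: SimulationTruth,
                                 cfg: SimConfig | None = None
                                 ) -> tuple[pd.DataFrame, dict[str, str],
                                            pd.Series, pd.DataFrame, pd.DataFrame]:
    """RNA counts for both samples plus a score-linked patient cohort.

    Returns (counts genes x samples, group map, gene lengths, patient
    expression genes x patients, survival frame with the latent risk group).
    """
    cfg = cfg or truth.cfg
    rng = np.random.default_rng(truth.seed + 4)
    genes = truth.genes
    n_genes = len(genes)
    labels1 = np.array([truth.compartments["primary"][c][b] for c, b in
                        zip(genes["chrom"], genes["mb_bin"])])
    base_log = (cfg.base_log_mean
                + np.where(labels1 == "A",
                           cfg.a_expression_log2_boost * np.log(2), 0.0)
                + rng.normal(0, 0.5, n_genes))
    mu1 = np.exp(base_log)
    mu2 = mu1 * np.power(2.0, truth.effects.reindex(genes["gene_id"]).to_numpy())

    reps = cfg.n_replicates
    cols, blocks = [], []
    for sample, mu in (("primary", mu1), ("metastatic", mu2)):
        for r in range(1, reps + 1):
            cols.append(f"{sample}_{r}")
            blocks.append(simulate_counts(rng, mu, cfg.nb_dispersion, (n_genes,)))
    counts = pd.DataFrame(np.column_stack(blocks), index=genes["gene_id"],
                          columns=cols)
    groups = {c: c.rsplit("_", 1)[0] for c in cols}
    lengths = pd.Series((genes["end"] - genes["start"]).to_numpy(),
                        index=genes["gene_id"], name="length")

    # patient cohort: latent risk group carries the planted gene-set signal
    n_pat = cfg.n_patients
    risk = np.array(["high"] * (n_pat // 2) + ["low"] * (n_pat - n_pat // 2))
    rng.shuffle(risk)
    set_mask = genes["gene_id"].isin(truth.upregulated_loop_genes).to_numpy()
    pat_mu = np.tile(np.exp(base_log)[:, None], (1, n_pat))
    pat_mu[np.ix_(set_mask, risk == "high")] *= \
        float(np.power(2.0, cfg.de_effect_log2fc))
    pat_expr = pd.DataFrame(
        rng.lognormal(np.log(pat_mu), 0.4),
        index=genes["gene_id"],
        columns=[f"patient{k:03d}" for k in range(n_pat)])

    hazard = np.where(risk == "high",
                      cfg.baseline_hazard * cfg.hazard_ratio, cfg.baseline_hazard)
    t = rng.exponential(1.0 / hazard)
    event = (t <= cfg.censor_time).astype(int)
    time = np.minimum(t, cfg.censor_time)
    survival = pd.DataFrame({"patient": pat_expr.columns, "time": time,
                             "event": event, "risk_group": risk})
    return counts, groups, lengths, pat_expr, survival


def simulate_study(cfg: SimConfig) -> dict:
    """Convenience: generate truth and every data modality in one call."""
    truth = generate_truth(cfg)
    matrices = simulate_hic(truth, cfg)
    tracks, genes = simulate_tracks(truth, cfg)
    counts, groups, lengths, pat_expr, survival = \
        simulate_expression_survival(truth, cfg)
    return {"truth": truth, "matrices": matrices, "tracks": tracks,
            "genes": genes, "counts": counts, "groups": groups,
            "lengths": lengths, "patient_expression": pat_expr,
            "survival": survival}


def write_truth(truth: SimulationTruth, path) -> None:
    """Serialize the planted truth (JSON, arrays as lists)."""
    payload = {
        "seed": truth.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(truth.cfg).items()},
        "compartments": {s: {c: list(map(str, lab)) for c, lab in d.items()}
                         for s, d in truth.compartments.items()},
        "switched_bins": [[c, int(b)] for c, b in truth.switched_bins],
        "domains": {s: df.to_dict(orient="list") for s, df in truth.domains.items()},
        "state_switch_spans": [[c, int(a), int(b)]
                               for c, a, b in truth.state_switch_spans],
        "loops": truth.loops.to_dict(orient="list"),
        "effects": {k: float(v) for k, v in truth.effects.items()},
        "upregulated_loop_genes": truth.upregulated_loop_genes,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
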