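"""Config-driven end-to-end orchestration of the multiscale analysis.

``run_pipeline`` executes normalize -> reproducibility -> compartments ->
domains -> loops -> regulatory/expression integration -> survival on a
two-sample study, either freshly simulated from a :class:`SimConfig` block
or loaded from files, and writes per-stage artifacts plus a summary
(JSON + TSV) whose numbers are the package's figure-level tabulations:
compartment switch percentages, domain counts and mean sizes,
state-enriched domain proportions, loop counts, CTCF fractions, the loop
category table, looped-gene expression contrasts, and the survival
log-rank p-value.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compartments as comp
from . import domains as dom
from . import expression as expr
from . import loops as lp
from .core import GeneTable, GenomeLayout, write_bed
from .matrix import ContactMatrix, ice_normalize, scc
from .simulate import SAMPLES, SimConfig, simulate_study, write_truth

log = logging.getLogger("hicscape")

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative pipeline run description.

    Either ``simulate`` holds SimConfig field overrides (a synthetic study
    is generated into the output directory), or ``inputs`` points at
    existing artifacts (chrom_sizes, per-sample matrix TSVs, track BEDs,
    gene table, counts).  ``params`` carries per-stage keyword overrides
    under the keys ice, scc, compartments, domains, loops, de, gene_set.
    """

    outdir: str = "hicscape_run"
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def validate_config(cfg: RunConfig) -> list[str]:
    """All violated ranges/paths at once; empty list means the config is ok."""
    findings: list[str] = []
    if cfg.simulate is None and cfg.inputs is None:
        findings.append("one of 'simulate' or 'inputs' must be provided")
    if cfg.simulate is not None:
        valid_fields = {f.name for f in dataclasses.fields(SimConfig)}
        for key in cfg.simulate:
            if key not in valid_fields:
                findings.append(f"simulate: unknown field {key!r}")
        try:
            SimConfig(**{k: v for k, v in cfg.simulate.items()
                         if k in valid_fields}).validate()
        except (TypeError, ValueError) as exc:
            findings.append(f"simulate: {exc}")
    if cfg.inputs is not None:
        for key in ("chrom_sizes", "matrices", "genes", "counts"):
            if key not in cfg.inputs:
                findings.append(f"inputs: missing key {key!r}")
        for key, value in cfg.inputs.items():
            paths = (value.values() if isinstance(value, dict) else [value])
            for p in paths:
                if isinstance(p, dict):
                    paths2 = p.values()
                elif isinstance(p, (str, Path)):
                    paths2 = [p]
                else:
                    continue
                for q in paths2:
                    if isinstance(q, (str, Path)) and not Path(q).exists():
                        findings.append(f"inputs: {key}: file not found: {q}")
    fdr = cfg.params.get("loops", {}).get("fdr")
    if fdr is not None and not 0 < fdr < 1:
        findings.append(f"loops.fdr must lie in (0, 1), got {fdr}")
    for stage, kw in cfg.params.items():
        if not isinstance(kw, dict):
            findings.append(f"params.{stage} must be a mapping")
    return findings


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns the summary dict (also written to disk)."""
    findings = validate_config(cfg)
    if findings:
        raise ValueError("invalid config:\n" + "\n".join(findings))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    with open(outdir / "effective_config.json", "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=1, sort_keys=True, default=str)

    stage_t0 = time.time()

    def tick(stage: str) -> None:
        nonlocal stage_t0
        log.info("stage %-14s %6.1f s", stage, time.time() - stage_t0)
        stage_t0 = time.time()

    try:
        data = _load_or_simulate(cfg, outdir)
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc
    tick("inputs")
    summary: dict = {"seed": cfg.seed, "samples": list(data["samples"])}
    s1, s2 = data["samples"]

    p = cfg.params

    # normalize -----------------------------------------------------------
    try:
        normalized, biases = {}, {}
        for s in data["samples"]:
            normalized[s], biases[s] = ice_normalize(data["matrices"][s],
                                                     **p.get("ice", {}))
            normalized[s].write(outdir / f"matrix_{s}_iced.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'normalize' failed: {exc}") from exc
    tick("normalize")

    # reproducibility ------------------------------------------------------
    try:
        summary["scc_between_samples"] = round(
            scc(data["matrices"][s1], data["matrices"][s2], **p.get("scc", {})), 6)
    except Exception as exc:
        raise RuntimeError(f"stage 'scc' failed: {exc}") from exc
    tick("scc")

    # compartments ---------------------------------------------------------
    try:
        factor = data["compartment_resolution"] // data["resolution"]
        density = comp.gene_density_per_bin(data["genes"], data["layout"],
                                            data["compartment_resolution"])
        profiles = {}
        for s in data["samples"]:
            mb_raw = data["matrices"][s].aggregate(factor)
            # megabase bins are deeply covered; the low-coverage mask is a
            # base-resolution precaution and would drop a bin per chromosome
            mb_norm, _ = ice_normalize(mb_raw, low_coverage_quantile=0.0)
            profiles[s] = comp.compartment_call(
                mb_norm, density, sample=s, **p.get("compartments", {}))
            profiles[s].write_bedgraph(outdir / f"compartments_{s}.bedgraph")
        pct, switch_table = comp.switch_fraction(profiles[s1], profiles[s2])
        switch_table.to_csv(outdir / "compartment_switches.tsv", sep="\t", index=False)
        summary["compartment_switch_pct"] = round(pct, 4)
        pattern = comp.cluster_pc1([profiles[s1], profiles[s2]])
        summary["compartment_pattern_counts"] = \
            pattern["pattern"].value_counts().sort_index().to_dict()
    except Exception as exc:
        raise RuntimeError(f"stage 'compartments' failed: {exc}") from exc
    tick("compartments")

    # expression (needed by domains and loops integration) ----------------
    try:
        xmat = expr.ExpressionMatrix(data["counts"], data["groups"], data["lengths"])
        de = expr.de_test(xmat, s1, s2, **p.get("de", {}))
        de.to_csv(outdir / "de_results.tsv", sep="\t")
        summary["de_flagged_genes"] = int(de["flag"].sum())
    except Exception as exc:
        raise RuntimeError(f"stage 'expression' failed: {exc}") from exc
    tick("expression")

    # domains --------------------------------------------------------------
    try:
        dom_lists, state_tables = {}, {}
        for s in data["samples"]:
            caller = dom.DomainCaller(**p.get("domains", {}))
            dom_lists[s] = caller.fit(normalized[s], sample=s).domains_
            marks = data["tracks"][s]
            state_tables[s] = dom.classify_domain_states(
                dom_lists[s], {m: marks[m] for m in
                               ("H3K9me3", "H3K27me3", "H3K36me3") if m in marks})
            state_tables[s].to_csv(outdir / f"domains_{s}.tsv", sep="\t", index=False)
            b = dom.boundaries(dom_lists[s])
            summary[f"domain_count_{s}"] = len(dom_lists[s])
            summary[f"domain_mean_size_{s}"] = (
                round(float(np.mean([len(d) for d in dom_lists[s]])), 1)
                if dom_lists[s] else 0.0)
            summary[f"boundary_count_{s}"] = b.count
            if "CTCF" in marks and b.count:
                summary[f"ctcf_boundary_fraction_{s}"] = round(
                    dom.ctcf_boundary_fraction(b, marks["CTCF"]), 4)
            for state in ("active", "heterochromatic", "repressed"):
                summary[f"domain_state_{state}_{s}"] = int(
                    (state_tables[s]["class"] == state).sum())
        pairs, spec_1, spec_2 = dom.common_domains(dom_lists[s1], dom_lists[s2])
        summary["common_domains"] = len(pairs)
        summary["specific_domains_" + s1] = len(spec_1)
        summary["specific_domains_" + s2] = len(spec_2)
        if dom_lists[s1] and dom_lists[s2]:
            size_stats = dom.domain_size_stats(dom_lists[s1], dom_lists[s2])
            summary["domain_size_ranksum_p"] = float(size_stats["p_value"])
        switch_report = dom.state_switch_genes(pairs, state_tables[s1],
                                               state_tables[s2], data["genes"], de)
        summary["state_switch_pairs"] = len(switch_report["switching_pairs"])
        summary["state_switch_genes_up"] = switch_report["n_up"]
        summary["state_switch_genes_down"] = switch_report["n_down"]
        summary["state_switch_sig_up"] = len(switch_report["significant_up"])
    except Exception as exc:
        raise RuntimeError(f"stage 'domains' failed: {exc}") from exc
    tick("domains")

    # loops ----------------------------------------------------------------
    try:
        loop_calls, elements = {}, {}
        for s in data["samples"]:
            caller = lp.LoopCaller(**p.get("loops", {}))
            loop_calls[s] = caller.fit(data["matrices"][s], biases[s], sample=s).loops_
            loop_calls[s].to_csv(outdir / f"loops_{s}.tsv", sep="\t", index=False)
            marks = data["tracks"][s]
            elements[s] = lp.define_elements(marks["H3K4me3"], marks["H3K27ac"],
                                             marks["CTCF"], data["genes"], s)
            summary[f"loop_count_{s}"] = len(loop_calls[s])
            if len(loop_calls[s]):
                _, frac = lp.ctcf_loop_fraction(loop_calls[s], marks["CTCF"])
                summary[f"ctcf_loop_fraction_{s}"] = round(frac, 4)
                annotated, cat_table = lp.annotate_loops(loop_calls[s], elements[s])
                annotated.to_csv(outdir / f"loops_{s}_annotated.tsv",
                                 sep="\t", index=False)
                summary[f"top_loop_category_{s}"] = (
                    str(cat_table["category"].iloc[0]) if len(cat_table) else "")
        spec1_enh, _common_enh, spec2_enh = lp.specific_elements(
            elements[s1], elements[s2], "enhancer")
        summary["specific_enhancers_" + s1] = len(spec1_enh)
        summary["specific_enhancers_" + s2] = len(spec2_enh)
        looped = lp.genes_looped_to_enhancers(loop_calls[s2], spec2_enh,
                                              elements[s2], data["genes"])
        looped_genes = sorted(set(looped["gene_id"]))
        summary["genes_looped_to_specific_enhancers"] = len(looped_genes)
        sig_up = [g for g in looped_genes
                  if g in de.index and bool(de.loc[g, "flag"])
                  and float(de.loc[g, "log2FoldChange"]) >= 1]
        summary["looped_genes_sig_up"] = len(sig_up)
        (outdir / "looped_genes.txt").write_text("\n".join(looped_genes) + "\n")
        ndrs = lp.extract_ndrs(elements[s2], looped_genes,
                               data["tracks"][s2]["H3K27ac"],
                               data["tracks"][s2]["H3K4me3"],
                               data["tracks"][s2]["ATAC"])
        ndrs.to_csv(outdir / "ndrs.tsv", sep="\t", index=False)
        summary["ndr_count"] = len(ndrs)
    except Exception as exc:
        raise RuntimeError(f"stage 'loops' failed: {exc}") from exc
    tick("loops")

    # survival -------------------------------------------------------------
    try:
        gene_set = sig_up if sig_up else looped_genes
        if gene_set and data.get("patient_expression") is not None:
            scores = expr.gene_set_score(data["patient_expression"], gene_set,
                                         **p.get("gene_set", {}))
            surv = data["survival"].set_index("patient")
            merged = scores.join(surv)
            stat, pval = expr.logrank_test(merged["time"], merged["event"],
                                           merged["group"])
            merged.to_csv(outdir / "survival_groups.tsv", sep="\t")
            summary["survival_logrank_p"] = float(pval)
            summary["survival_gene_set_size"] = len(gene_set)
    except Exception as exc:
        raise RuntimeError(f"stage 'survival' failed: {exc}") from exc
    tick("survival")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    pd.Series(summary, dtype=object).rename("value").rename_axis("key") \
        .to_csv(outdir / "summary.tsv", sep="\t")
    return summary


def _load_or_simulate(cfg: RunConfig, outdir: Path) -> dict:
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", cfg.seed)
        sim = SimConfig(**sim_kwargs)
        study = simulate_study(sim)
        inputs_dir = outdir / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        sim.layout().write(inputs_dir / "chrom.sizes")
        for s, m in study["matrices"].items():
            m.write(inputs_dir / f"matrix_{s}.tsv")
        for s, marks in study["tracks"].items():
            for mark, ps in marks.items():
                write_bed(ps, inputs_dir / f"{s}_{mark}.bed")
        study["genes"].write(inputs_dir / "genes.tsv")
        study["counts"].to_csv(inputs_dir / "counts.tsv", sep="\t")
        study["survival"].to_csv(inputs_dir / "survival.tsv", sep="\t", index=False)
        write_truth(study["truth"], inputs_dir / "truth.json")
        return {
            "samples": list(SAMPLES),
            "layout": sim.layout(),
            "resolution": sim.resolution,
            "compartment_resolution": sim.compartment_resolution,
            "matrices": study["matrices"],
            "tracks": study["tracks"],
            "genes": study["genes"],
            "counts": study["counts"],
            "groups": study["groups"],
            "lengths": study["lengths"],
            "patient_expression": study["patient_expression"],
            "survival": study["survival"],
            "truth": study["truth"],
        }
    return _load_inputs(cfg.inputs)


def _load_inputs(inputs: dict) -> dict:
    from .core import read_bed
    layout = GenomeLayout.read(inputs["chrom_sizes"])
    resolution = int(inputs.get("resolution", 5000))
    samples = list(inputs["matrices"])
    matrices = {s: ContactMatrix.read(p, layout, resolution)
                for s, p in inputs["matrices"].items()}
    tracks = {}
    for s, marks in inputs.get("tracks", {}).items():
        tracks[s] = {mark: read_bed(path, signal_column=5, mark=mark)
                     for mark, path in marks.items()}
    genes = GeneTable.read(inputs["genes"])
    counts = pd.read_csv(inputs["counts"], sep="\t", index_col=0)
    groups = inputs.get("groups") or \
        {c: c.rsplit("_", 1)[0] for c in counts.columns}
    lengths = pd.Series((genes.df["end"] - genes.df["start"]).to_numpy(),
                        index=genes.df["gene_id"])
    survival = (pd.read_csv(inputs["survival"], sep="\t")
                if "survival" in inputs else None)
    pat = (pd.read_csv(inputs["patient_expression"], sep="\t", index_col=0)
           if "patient_expression" in inputs else None)
    return {"samples": samples, "layout": layout, "resolution": resolution,
            "compartment_resolution": int(inputs.get("compartment_resolution",
                                                     1_000_000)),
            "matrices": matrices, "tracks": tracks, "genes": genes,
            "counts": counts, "groups": groups, "lengths": lengths,
            "patient_expression": pat, "survival": survival, "truth": None}
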