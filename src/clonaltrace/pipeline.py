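"""End-to-end orchestration: simulate/read -> matrix -> tree -> CNV ->
subclones -> ordering -> report.

A single YAML-serializable config drives every stage; all randomness
derives from one seed, so a re-run with the same config is
byte-identical.  Each stage logs the thresholds it actually applied and
records its outputs in a checksummed manifest; a failed stage halts the
downstream stages and leaves a resumable state file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import branch_ordering as bo
from . import cnv_segments as cs
from . import sample_phylogeny as sp
from . import subclone_inference as si
from . import synthetic_tumor as st
from . import variant_matrix as vm
from .errors import ConfigurationError

log = logging.getLogger("clonaltrace")

STAGES = ["simulate", "matrix", "tree", "cnv", "subclones", "order", "report"]


class SimulateConfig(BaseModel):
    preset: str = "figure3c"
    clones: int = 4
    samples: int = 11
    mutations: int = 292
    depth: float = 231.0
    concentration: float = 150.0
    error_rate: float = 0.0


class PresenceConfig(BaseModel):
    min_alt: int = 4
    min_vaf: float = 0.05


class DistanceConfig(BaseModel):
    snv_only: bool = True


class CnvConfig(BaseModel):
    enabled: bool = True
    first_threshold: float = 0.3
    second_threshold: float = 0.2
    n_snps: int = 2000
    depth: float = 200.0


class SubcloneConfig(BaseModel):
    k_min: int = 1
    k_max: int = 5
    restarts: int = 10
    max_iter: int = 200
    tol: float = 1e-6
    elbow_fraction: float = 0.05
    residual_min_depth: int = 30


class OrderingConfig(BaseModel):
    prior_shape: float = 1.1
    tol: float = 1e-10


class PipelineConfig(BaseModel):
    """Full pipeline configuration (one YAML file, CLI flags override)."""

    input_vcfs: list[str] = Field(default_factory=list)
    manifest: Optional[str] = None
    normal_sample: str = "normal"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    presence: PresenceConfig = Field(default_factory=PresenceConfig)
    distance: DistanceConfig = Field(default_factory=DistanceConfig)
    cnv: CnvConfig = Field(default_factory=CnvConfig)
    subclones: SubcloneConfig = Field(default_factory=SubcloneConfig)
    ordering: OrderingConfig = Field(default_factory=OrderingConfig)
    out_dir: str = "results/pipeline"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(doc)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
        return path

    def validate_inputs(self) -> None:
        for p in self.input_vcfs:
            if not Path(p).exists():
                raise ConfigurationError(f"input file not found: {p}")
        if self.input_vcfs and (self.manifest is None or not Path(self.manifest).exists()):
            raise ConfigurationError("a manifest is required with input files")


class ReportSummary(BaseModel):
    """Machine-readable pipeline summary (the shipped report schema)."""

    seed: int
    n_samples: int
    n_unique_variants: int
    total_calls: int
    tmb_per_sample: dict[str, float]
    newick: str
    selected_k: int
    bic_by_k: dict[str, float]
    composition_percent: dict[str, dict[str, float]]
    n_curated_cnv_regions: int
    branch_order_heads: dict[str, list[str]]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_state(out: Path, state: dict) -> None:
    (out / "pipeline_state.json").write_text(json.dumps(state, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns in-memory results.

    Outputs land under ``config.out_dir``; a manifest with SHA-256
    checksums of every declared file is written last.  Any stage failure
    is recorded in ``pipeline_state.json`` before the exception
    propagates, so a re-run can identify the failed stage.
    """
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    state = {"seed": config.seed, "stages": {}}
    results: dict = {}
    files: list[Path] = []

    def done(stage: str) -> None:
        state["stages"][stage] = "done"
        _write_state(out, state)

    try:
        # --- simulate / ingest -------------------------------------------
        if config.input_vcfs:
            log.info("reading cohort from %d input file(s)", len(config.input_vcfs))
            matrix = vm.read_cohort(config.input_vcfs, config.manifest)
            truth = None
        else:
            simc = config.simulate
            log.info("simulating cohort: preset=%s depth=%.0fx seed=%d",
                     simc.preset, simc.depth, config.seed)
            if simc.preset == "figure3c":
                truth, matrix = st.simulate_figure3c_cohort(
                    seed=int(ss[0]), depth_mean=simc.depth,
                    concentration=simc.concentration, error_rate=simc.error_rate)
            else:
                truth = st.simulate_clone_tree(simc.clones, simc.mutations, seed=int(ss[0]))
                st.simulate_clone_fractions(truth, simc.samples,
                                            concentration=simc.concentration or 2.0,
                                            seed=int(ss[1]))
                matrix = st.simulate_read_counts(truth, depth_mean=simc.depth,
                                                 seed=int(ss[2]),
                                                 error_rate=simc.error_rate)
            fx = st.write_fixture(truth, matrix, out / "cohort")
            files.extend(fx.values())
        results["matrix"] = matrix
        results["truth"] = truth
        done("simulate")

        # --- matrix summaries --------------------------------------------
        log.info("presence rule: min_alt=%d min_vaf=%.3f",
                 config.presence.min_alt, config.presence.min_vaf)
        vm.build_presence_sets(matrix, min_alt=config.presence.min_alt,
                               min_vaf=config.presence.min_vaf)
        summary = vm.sharing_summary(matrix)
        tmb = {s: vm.compute_tmb(matrix, s) for s in matrix.tumor_samples}
        results["sharing"] = summary
        results["tmb"] = tmb
        files.extend(vm.write_summary(summary, out / "sharing"))
        p = out / "tmb.tsv"
        pd.Series(tmb, name="tmb_per_mb").rename_axis("sample") \
            .to_frame().to_csv(p, sep="\t", float_format="%.6f")
        files.append(p)
        done("matrix")

        # --- sample tree ---------------------------------------------------
        sets = matrix.presence_sets(snv_only=config.distance.snv_only)
        dm = sp.symmetric_difference_distance(sets)
        tree = sp.clamp_negative_lengths(sp.neighbor_joining(dm))
        rooted = sp.root_at_normal(tree)
        results["distance_matrix"] = dm
        results["tree"] = rooted
        files.append(dm.write_tsv(out / "distances.tsv"))
        files.append(sp.write_newick(rooted, out / "sample_tree.nwk"))
        done("tree")

        # --- CNV -----------------------------------------------------------
        if config.cnv.enabled and truth is not None and truth.cnv_truth:
            log.info("CNV thresholds: first=%.2f second=%.2f",
                     config.cnv.first_threshold, config.cnv.second_threshold)
            purity = {s: float(truth.fractions.drop(index="normal")[s].sum())
                      for s in matrix.tumor_samples}
            snps = st.simulate_het_snps(
                config.cnv.n_snps, matrix.tumor_samples, cnv_truth=truth.cnv_truth,
                depth_mean=config.cnv.depth, purity=purity, seed=int(ss[3]))
            rdep = {s: 1.0 for s in matrix.tumor_samples}
            curated = cs.run_two_pass_curation(
                snps, first_threshold=config.cnv.first_threshold,
                second_threshold=config.cnv.second_threshold, rdep=rdep)
            bundle = cs.build_bundle(curated, matrix, rdep=rdep,
                                     samples=matrix.tumor_samples)
            files.append(cs.write_bed(curated, out / "curated_cnv.bed"))
            files.append(cs.write_regions_tsv(curated, out / "curated_cnv.tsv"))
            files.extend(bundle.write(out / "cnv_bundle").values())
        else:
            bundle = cs.diploid_bundle(matrix)
        results["bundle"] = bundle
        done("cnv")

        # --- subclones -------------------------------------------------------
        sub = config.subclones
        depth = matrix.depth[:, [matrix.sample_index(s) for s in matrix.tumor_samples]]
        low_depth = (depth < sub.residual_min_depth).any(axis=1)
        all_ids = [matrix.variant_label(i) for i in range(len(matrix.variants))]
        core = [m for m, lo in zip(all_ids, low_depth) if not lo]
        residual = [m for m, lo in zip(all_ids, low_depth) if lo]
        if len(core) < 2:
            core, residual = all_ids, []
        log.info("subclone fit: K in [%d, %d], %d core + %d residual mutations, "
                 "elbow fraction %.2f", sub.k_min, sub.k_max, len(core),
                 len(residual), sub.elbow_fraction)
        fit_cfg = si.FitConfig(K_range=(sub.k_min, sub.k_max), restarts=sub.restarts,
                               max_iter=sub.max_iter, tol=sub.tol,
                               elbow_fraction=sub.elbow_fraction, seed=int(ss[4]))
        selected, fits = si.fit_and_select(matrix, bundle, fit_cfg, core)
        posthoc = si.posthoc_assign(selected, matrix, residual, bundle) if residual \
            else pd.DataFrame(columns=["mutation", "edge", "log_likelihood",
                                       "margin", "beats_noise"])
        results["selected"] = selected
        results["fits"] = fits
        results["posthoc"] = posthoc
        p = out / "clone_tree.json"
        p.write_text(selected.to_json() + "\n")
        files.append(p)
        files.extend(si.write_prevalence(selected, out / "composition"))
        p = out / "edge_mutations.tsv"
        rows = [(e, m) for e, ms in selected.edge_mutations().items() for m in ms]
        pd.DataFrame(rows, columns=["edge", "mutation"]).to_csv(p, sep="\t", index=False)
        files.append(p)
        p = out / "posthoc_assignments.tsv"
        posthoc.to_csv(p, sep="\t", index=False, float_format="%.6g")
        files.append(p)
        done("subclones")

        # --- ordering --------------------------------------------------------
        vaf = pd.DataFrame(matrix.vaf, index=all_ids, columns=matrix.samples)
        vaf = vaf[matrix.tumor_samples]
        edge_sets = selected.edge_mutations()
        for _, row in posthoc.iterrows():
            if row["edge"] in edge_sets:
                edge_sets[row["edge"]].append(row["mutation"])
        timelines = []
        for edge, muts in sorted(edge_sets.items()):
            if len(muts) < 2:
                continue
            timelines.append(bo.order_branch(vaf.loc[muts], branch=edge,
                                             a=config.ordering.prior_shape,
                                             tol=config.ordering.tol))
        timeline = pd.concat(timelines, ignore_index=True) if timelines \
            else pd.DataFrame(columns=["branch", "rank", "mutation", "ability",
                                       "max_pair_probability", "tied"])
        results["timeline"] = timeline
        files.append(bo.write_timeline(timeline, out / "timeline.tsv"))
        done("order")

        # --- report ----------------------------------------------------------
        files.extend(render_report(results, config, out))
        done("report")

        manifest = {str(p.relative_to(out)): _checksum(p) for p in sorted(set(files))}
        (out / "output_manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    except Exception as exc:
        failed = next((s for s in STAGES if state["stages"].get(s) != "done"), "unknown")
        state["stages"][failed] = f"failed: {exc}"
        _write_state(out, state)
        log.error("stage %s failed: %s", failed, exc)
        raise
    return results


def render_report(results: dict, config: PipelineConfig, out: Path) -> list[Path]:
    """Write the cohort report (markdown) and the validated JSON summary."""
    out = Path(out)
    matrix = results["matrix"]
    selected = results["selected"]
    timeline = results["timeline"]
    newick = sp.to_newick(results["tree"])
    comp = si.prevalence_report(selected)

    heads = {}
    for branch, group in timeline.groupby("branch"):
        heads[str(branch)] = group.sort_values("rank")["mutation"].head(3).tolist()
    summary = ReportSummary(
        seed=config.seed,
        n_samples=len(matrix.tumor_samples),
        n_unique_variants=results["sharing"]["unique_variants"],
        total_calls=results["sharing"]["total_calls"],
        tmb_per_sample={s: round(v, 6) for s, v in results["tmb"].items()},
        newick=newick,
        selected_k=selected.K,
        bic_by_k={str(k): round(f.bic, 4) for k, f in results["fits"].items()},
        composition_percent={
            s: {str(c): round(float(comp.loc[c, s]), 4)
                for c in comp.index if c != "total"}
            for s in comp.columns},
        n_curated_cnv_regions=len(results["bundle"].segments),
        branch_order_heads=heads,
    )
    js = out / "report.json"
    js.write_text(summary.model_dump_json(indent=1) + "\n")

    lines = ["# Cohort report", ""]
    lines += [f"Seed: {config.seed}", ""]
    lines += ["## Per-sample metrics", "", "| sample | present variants | TMB (mut/Mb) |",
              "|---|---|---|"]
    for s in matrix.tumor_samples:
        lines.append(f"| {s} | {results['sharing']['per_sample'][s]} "
                     f"| {results['tmb'][s]:.2f} |")
    lines += ["", f"Unique variants: {results['sharing']['unique_variants']}; "
                  f"total calls: {results['sharing']['total_calls']}", ""]
    lines += ["## Sample tree (NJ, rooted at normal)", "", "```", newick, "```", ""]
    lines += [f"## Subclones (selected K = {selected.K})", "",
              "BIC by K: " + ", ".join(f"K={k}: {f.bic:.1f}"
                                       for k, f in sorted(results["fits"].items())), "",
              "Composition (%, columns sum to 100):", "```",
              comp.round(2).to_string(), "```", ""]
    lines += ["## Branch timelines", ""]
    if timeline.empty:
        lines.append("single mutation per branch, no ordering")
    else:
        for branch, group in timeline.groupby("branch"):
            first = group.sort_values("rank").head(5)
            lines.append(f"- branch `{branch}`: earliest "
                         + ", ".join(first["mutation"]))
    n_single = sum(1 for e, ms in selected.edge_mutations().items() if len(ms) == 1)
    if n_single:
        lines.append(f"- {n_single} branch(es) with a single mutation: no ordering")
    md = out / "report.md"
    md.write_text("\n".join(lines) + "\n")
    return [js, md]


def report_schema() -> dict:
    """JSON schema of the report summary (shipped with the package)."""
    return ReportSummary.model_json_schema()
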