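"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages run in a fixed order — simulate (optional), ingest, normalize,
smooth, callchers, annotate, fetch-seqs, scan, enrich, evaluate — over a
growing per-probe table, and every run writes a machine-readable manifest
(parameters, input checksums, per-stage record counts) so a run can be
reproduced exactly from its saved config and inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .array_data import (
    compute_log_ratios,
    filter_unique_probes,
    read_intensity_table,
    read_probe_table,
)
from .annotation import assign_chers_to_genes, assignments_to_table, read_gene_models_gff3
from .cher_calling import (
    ThresholdSpec,
    call_chers_all,
    candidate_runs,
    chers_to_bed,
    chers_to_table,
    compute_threshold,
)
from .enrichment import (
    enrich,
    intersect_with_expression,
    propagate_annotations,
    read_annotations,
    read_term_graph,
    results_to_table,
    significant_subdag_dot,
)
from .errors import ConfigError, StageError, ValidationError
from .motif_scan import fetch_cher_sequences, hits_to_table, load_pwms, scan_chers, write_fasta
from .preprocess import normalize, smooth_probes
from .synthetic import (
    RecoveryResult,
    SimulationConfig,
    evaluate_recovery,
    simulate_annotations,
    simulate_experiment,
    write_annotation_files,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs: inputs, outputs and parameters."""

    out_dir: str = "pycher_run"
    seed: int = 1
    simulate: bool = False
    sim_params: dict = field(default_factory=dict)  # overrides for SimulationConfig
    # input paths (filled automatically when simulate=True)
    probe_table: str | None = None
    ip_intensities: str | None = None
    input_intensities: str | None = None
    genes_gff3: str | None = None
    genome_fasta: str | None = None
    pwm_file: str | None = None
    pwm_dialect: str = "jaspar"
    term_edges: str | None = None
    term_names: str | None = None
    annotations: str | None = None
    de_table: str | None = None
    truth_json: str | None = None
    # stage parameters (defaults follow the published analysis)
    half_window: int = 450  # 900-bp full window span
    min_probes: int = 7
    merge_gap: int = 450
    quantile: float = 0.99
    floor_quantile: float | None = 0.5
    upstream_bp: int = 10000
    css_cutoff: float = 0.75
    mss_cutoff: float = 0.80
    min_k: int = 2
    level_filter: int | None = None
    antibody: str = ""
    pool: str = ""
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ConfigError(f"quantile must be in (0, 1), got {self.quantile}")
        if self.floor_quantile is not None and not 0.0 < self.floor_quantile < self.quantile:
            raise ConfigError("floor_quantile must satisfy 0 < floor_quantile < quantile")
        if self.min_probes < 1 or self.half_window < 1 or self.merge_gap < 0:
            raise ConfigError("min_probes/half_window must be >= 1 and merge_gap >= 0")
        if not (0 <= self.css_cutoff <= 1 and 0 <= self.mss_cutoff <= 1):
            raise ConfigError("cutoffs must lie in [0, 1]")
        if not self.simulate and self.probe_table is None:
            raise ConfigError("either simulate=true or a probe_table is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _md5(path) -> str:
    digest = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def threshold_spec(config: RunConfig) -> ThresholdSpec:
    return ThresholdSpec(
        quantile=config.quantile,
        floor_quantile=config.floor_quantile,
        min_probes=config.min_probes,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the manifest dict.

    Any stage error is re-raised as :class:`StageError` naming the stage;
    the config is validated before anything runs.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": config.to_dict(),
        "inputs": {},
        "counts": {},
        "stages": [],
        "outputs": {},
    }
    state: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                fn()
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(name)
        return wrap

    if config.simulate:
        @stage("simulate")
        def _():
            sim_dir = os.path.join(config.out_dir, "sim")
            sim_kwargs = dict(config.sim_params)
            spike_over = sim_kwargs.pop("spike", None)
            ann_over = sim_kwargs.pop("annotation", None)
            if spike_over:
                from .synthetic import SpikeConfig

                sim_kwargs["spike"] = SpikeConfig(**spike_over)
            if ann_over:
                from .synthetic import AnnotationConfig

                sim_kwargs["annotation"] = AnnotationConfig(**ann_over)
            sim = simulate_experiment(SimulationConfig(seed=config.seed, **sim_kwargs))
            paths = sim.write(sim_dir)
            graph, direct, de_table, ann_truth = simulate_annotations(
                [g.gene_id for g in sim.genes],
                sim.config.annotation,
                np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[6]),
                target_genes={s["gene_id"] for s in sim.truth.spikes},
            )
            paths.update(write_annotation_files(sim_dir, graph, direct, de_table))
            sim.truth.de_genes = ann_truth.de_genes
            sim.truth.planted_term = ann_truth.planted_term
            with open(paths["truth"], "w") as fh:
                json.dump(dataclasses.asdict(sim.truth), fh, indent=1, sort_keys=True)
            config.probe_table = paths["probes"]
            config.ip_intensities = paths["ip"]
            config.input_intensities = paths["input"]
            config.genes_gff3 = paths["genes"]
            config.genome_fasta = paths.get("genome")
            config.pwm_file = paths["pwm"]
            config.term_edges = paths["term_edges"]
            config.term_names = paths["term_names"]
            config.annotations = paths["annotations"]
            config.de_table = paths["de_table"]
            config.truth_json = paths["truth"]

    for key in ("probe_table", "ip_intensities", "input_intensities", "genes_gff3",
                "genome_fasta", "pwm_file", "term_edges", "term_names",
                "annotations", "de_table"):
        path = getattr(config, key)
        if path and os.path.exists(path):
            manifest["inputs"][key] = {"path": path, "md5": _md5(path)}

    @stage("ingest")
    def _():
        probes = read_probe_table(config.probe_table)
        kept, removed, frac = filter_unique_probes(probes)
        ip = read_intensity_table(config.ip_intensities)
        input_ = read_intensity_table(config.input_intensities)
        kept_ids = [p.probe_id for p in kept]
        ratios, report = compute_log_ratios(ip[ip.index.isin(kept_ids)],
                                            input_[input_.index.isin(kept_ids)])
        state["probes"] = kept
        state["ratios"] = ratios
        manifest["counts"].update(
            probes_read=len(probes),
            probes_removed_non_unique=removed,
            probes_kept=len(kept),
            removed_fraction=frac,
            probes_missing_channel=report["n_dropped_missing_channel"],
        )

    @stage("normalize")
    def _():
        result = normalize(state["ratios"]["log_ratio"])
        state["normalized"] = result.normalized
        manifest["counts"]["tukey_biweight_location"] = result.location_estimate

    @stage("smooth")
    def _():
        state["tracks"] = smooth_probes(
            state["probes"], state["normalized"],
            half_window=config.half_window, min_probes=config.min_probes,
        )
        table_path = os.path.join(config.out_dir, "probes_smoothed.tsv")
        rows = []
        for chrom in sorted(state["tracks"]):
            t = state["tracks"][chrom]
            for pid, pos, sm in zip(t.probe_ids, t.positions, t.values):
                rows.append((pid, chrom, int(pos),
                             float(state["ratios"]["log_ratio"].get(pid, np.nan)),
                             float(state["normalized"].get(pid, np.nan)),
                             float(sm)))
        pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "raw", "normalized", "smoothed"]) \
            .to_csv(table_path, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"]["probes_smoothed"] = table_path
        manifest["counts"]["smoothed_values"] = int(
            sum(np.isfinite(t.values).sum() for t in state["tracks"].values())
        )

    @stage("callchers")
    def _():
        tr = compute_threshold(state["tracks"], threshold_spec(config))
        chers = call_chers_all(
            state["tracks"], tr.y0,
            min_probes=config.min_probes, merge_gap=config.merge_gap,
            antibody=config.antibody, pool=config.pool,
        )
        state["chers"] = chers
        state["threshold"] = tr
        cher_path = os.path.join(config.out_dir, "chers.tsv")
        chers_to_table(chers).to_csv(cher_path, sep="\t", index=False, float_format="%.6g")
        with open(os.path.join(config.out_dir, "chers.bed"), "w") as fh:
            fh.write(chers_to_bed(chers))
        manifest["outputs"]["chers"] = cher_path
        manifest["counts"].update(
            threshold_y0=tr.y0,
            threshold_candidates=tr.n_candidates,
            threshold_fallback=tr.used_fallback,
            chers_called=len(chers),
        )

    if config.genes_gff3:
        @stage("annotate")
        def _():
            genes = read_gene_models_gff3(config.genes_gff3)
            assignments = assign_chers_to_genes(state["chers"], genes, config.upstream_bp)
            state["genes"] = genes
            state["assignments"] = assignments
            path = os.path.join(config.out_dir, "cher_gene_assignments.tsv")
            assignments_to_table(assignments).to_csv(path, sep="\t", index=False)
            manifest["outputs"]["assignments"] = path
            manifest["counts"].update(
                genes_read=len(genes),
                genes_with_chers=len({a.gene_id for a in assignments}),
                cher_gene_assignments=len(assignments),
            )

    if config.genome_fasta and config.pwm_file:
        @stage("fetch-seqs")
        def _():
            seqs = fetch_cher_sequences(config.genome_fasta, state["chers"])
            state["cher_seqs"] = seqs
            path = os.path.join(config.out_dir, "cher_sequences.fa")
            write_fasta(seqs, path)
            manifest["outputs"]["cher_sequences"] = path
            manifest["counts"]["cher_sequences"] = len(seqs)

        @stage("scan")
        def _():
            pwms = load_pwms(
                config.pwm_file, config.pwm_dialect,
                css_cutoff=config.css_cutoff, mss_cutoff=config.mss_cutoff,
            )
            hits = scan_chers(pwms, state["cher_seqs"])
            state["hits"] = hits
            path = os.path.join(config.out_dir, "motif_hits.tsv")
            hits_to_table(hits).to_csv(path, sep="\t", index=False, float_format="%.4f")
            with_hit = {h.seq_id for h in hits}
            manifest["outputs"]["motif_hits"] = path
            manifest["counts"].update(
                motif_hits=len(hits),
                chers_with_tfbs=len(with_hit),
                chers_with_tfbs_fraction=(len(with_hit) / len(state["chers"]))
                if state["chers"] else 0.0,
            )

    if config.term_edges and config.annotations and config.de_table:
        @stage("enrich")
        def _():
            graph = read_term_graph(config.term_edges, config.term_names)
            direct = read_annotations(config.annotations)
            ann = propagate_annotations(graph, direct)
            de = pd.read_csv(config.de_table, sep="\t")
            target_genes = {a.gene_id for a in state.get("assignments", [])}
            all_de, up, down = intersect_with_expression(target_genes, de)
            reference = set(ann.propagated)
            manifest["counts"].update(
                de_targets=len(all_de), de_targets_up=len(up), de_targets_down=len(down),
            )
            for label, subset in (("all", all_de), ("up", up), ("down", down)):
                if not subset & reference:
                    continue
                results = enrich(subset, reference, ann, graph,
                                 min_k=config.min_k, level_filter=config.level_filter)
                path = os.path.join(config.out_dir, f"enrichment_{label}.tsv")
                results_to_table(results).to_csv(path, sep="\t", index=False)
                manifest["outputs"][f"enrichment_{label}"] = path
                if label == "all":
                    manifest["counts"]["terms_tested"] = len(results)
                    dot = significant_subdag_dot(graph, results)
                    dot_path = os.path.join(config.out_dir, "enrichment_all.dot")
                    with open(dot_path, "w") as fh:
                        fh.write(dot)
                    manifest["outputs"]["enrichment_dag"] = dot_path

    if config.truth_json:
        @stage("evaluate")
        def _():
            with open(config.truth_json) as fh:
                truth = json.load(fh)
            result = evaluate_recovery(state["chers"], truth.get("spikes", []))
            path = os.path.join(config.out_dir, "recovery.tsv")
            result.table.to_csv(path, sep="\t", index=False)
            manifest["outputs"]["recovery"] = path
            manifest["counts"].update(
                spike_sensitivity=result.sensitivity,
                spike_precision=result.precision,
            )

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    with open(os.path.join(config.out_dir, "run_config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# synthetic-experiment convenience drivers (used by tests and benchmarks)


def call_synthetic(config: SimulationConfig, spec: ThresholdSpec | None = None):
    """Simulate, preprocess and call regions in memory.

    Returns (sim, tracks, threshold_result, chers).
    """
    spec = spec or ThresholdSpec()
    sim = simulate_experiment(config)
    kept, _, _ = filter_unique_probes(sim.probes)
    kept_ids = [p.probe_id for p in kept]
    ratios, _ = compute_log_ratios(sim.ip[sim.ip.index.isin(kept_ids)],
                                   sim.input_[sim.input_.index.isin(kept_ids)])
    norm = normalize(ratios["log_ratio"])
    tracks = smooth_probes(kept, norm.normalized, min_probes=spec.min_probes)
    tr = compute_threshold(tracks, spec)
    chers = call_chers_all(tracks, tr.y0, min_probes=spec.min_probes)
    return sim, tracks, tr, chers


def synthetic_recovery(config: SimulationConfig, spec: ThresholdSpec | None = None) -> RecoveryResult:
    """Spike recovery metrics for one synthetic experiment."""
    sim, _, _, chers = call_synthetic(config, spec)
    return evaluate_recovery(chers, sim.truth.spikes)


def null_promotion_fraction(config: SimulationConfig, spec: ThresholdSpec | None = None) -> float:
    """On a spike-free experiment, the fraction of candidate runs promoted.

    Candidate runs are the potential-cher universe used by the threshold;
    promoted means at least ``min_probes`` consecutive probes above y0.
    """
    spec = spec or ThresholdSpec()
    config = dataclasses.replace(
        config, spike=dataclasses.replace(config.spike, n_targets=0)
    )
    sim, tracks, tr, _ = call_synthetic(config, spec)
    if tr.n_candidates == 0:
        return 0.0
    promoted = sum(
        len(candidate_runs(t, tr.y0, spec.min_probes)) for t in tracks.values()
    )
    return promoted / tr.n_candidates
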