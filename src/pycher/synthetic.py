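"""Synthetic promoter tiling-array experiments with known ground truth.

The generator emulates a two-channel promoter tiling array: every gene's
promoter region (7 kb upstream to 3 kb downstream of the TSS, strand
aware) is tiled with 60-mer probes spaced 100 bp apart.  The input
channel draws log-normal baseline intensities; the IP channel multiplies
the input by 2^(boxcar + noise), where the boxcar adds a constant log2
enrichment (default 1.5) over an 800 bp window at a subset of promoters
— the sonication-fragment-scale shape that makes in-spike expectations
analytic — and the noise is i.i.d. Gaussian on the log2 scale (default
sd 0.3).  A configurable fraction of probes is marked as multi-mapping,
motif consensus strings are written into the genome inside each spiked
region, and gene-set annotations with a planted over-represented term are
generated for the enrichment stage.  Every downstream stage can therefore
be scored against saved ground truth.

Randomness comes from independent named substreams (genome, genes,
probes, spikes, intensities, annotations) spawned from one master seed,
so any component regenerates identically whether or not the others ran.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .array_data import Probe, write_probe_table
from .annotation import GeneModel
from .cher_calling import Cher
from .enrichment import TermGraph
from .errors import ValidationError
from .motif_scan import PWM, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SpikeConfig:
    """Planted enrichment regions ("spikes") at a subset of promoters."""

    n_targets: int = 20
    height: float = 1.5  # log2 enrichment of the boxcar
    width: int = 800  # bp
    offset_min: int = -5000  # spike-center offset from the TSS, along transcription
    offset_max: int = 1500


@dataclass(frozen=True)
class AnnotationConfig:
    """Random term DAG and gene-set annotations with one planted term."""

    n_terms: int = 40
    dag_depth: int = 6
    term_size_min: int = 25
    term_size_max: int = 400
    planted_term_size: int = 250
    planted_fold: float = 3.0
    de_fraction: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    n_chroms: int = 2
    n_genes: int = 1200
    gene_spacing: int = 20000  # bp between consecutive TSSs
    first_tss: int = 10000
    gene_length_min: int = 2000
    gene_length_max: int = 8000
    promoter_upstream: int = 7000
    promoter_downstream: int = 3000
    probe_spacing: int = 100
    probe_length: int = 60
    baseline_log_mean: float = 6.2  # natural-log mean of the input channel
    baseline_log_sd: float = 0.5
    noise_sd: float = 0.3  # log2 units
    non_unique_fraction: float = 0.03
    motif_instances_per_spike: int = 1
    with_genome: bool = True
    spike: SpikeConfig = field(default_factory=SpikeConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.n_genes < 1:
            raise ValidationError("n_chroms and n_genes must be >= 1")
        if self.probe_spacing >= self.spike.width:
            raise ValidationError("probe_spacing must be smaller than the spike width")
        if self.spike.n_targets > self.n_genes:
            raise ValidationError("more spike targets than genes")
        if not 0 <= self.non_unique_fraction < 1:
            raise ValidationError("non_unique_fraction must be in [0, 1)")
        if self.spike.offset_min - self.spike.width // 2 < -self.promoter_upstream:
            raise ValidationError("spike offset range exceeds the tiled promoter window")

    @property
    def genes_per_chrom(self) -> int:
        return math.ceil(self.n_genes / self.n_chroms)

    @property
    def chrom_length(self) -> int:
        return self.first_tss + self.genes_per_chrom * self.gene_spacing + self.promoter_upstream


@dataclass
class GroundTruth:
    """What was planted: spike intervals, motif instances, DE genes, planted term."""

    spikes: list[dict] = field(default_factory=list)
    motif_positions: list[dict] = field(default_factory=list)
    de_genes: dict[str, str] = field(default_factory=dict)  # gene -> "up"/"down"
    planted_term: str | None = None


def default_motif_pwm() -> PWM:
    """A sharp 10-bp ETS-family-like matrix (GGAA core) for planting."""
    consensus = "ACCGGAAGTG"
    counts = np.full((len(consensus), 4), 1.0)
    for i, base in enumerate(consensus):
        counts[i, "ACGT".index(base)] = 97.0
    return PWM.from_counts("SIM_ETS", counts)


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    genes: list[GeneModel]
    probes: list[Probe]
    ip: pd.Series
    input_: pd.Series
    true_log_ratio: pd.Series
    genome: dict[str, str] | None
    pwm: PWM
    truth: GroundTruth

    def write(self, outdir) -> dict[str, str]:
        """Write every pipeline input format; returns the path map."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}

        paths["probes"] = os.path.join(outdir, "probes.tsv")
        write_probe_table(self.probes, paths["probes"])

        for name, series in (("ip", self.ip), ("input", self.input_)):
            paths[name] = os.path.join(outdir, f"intensity_{name}.tsv")
            with open(paths[name], "w") as fh:
                fh.write("probe_id\tsignal\n")
                for pid, val in series.items():
                    fh.write(f"{pid}\t{val:.6f}\n")

        paths["genes"] = os.path.join(outdir, "genes.gff3")
        with open(paths["genes"], "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                strand = "+" if g.strand == +1 else "-"
                fh.write(
                    f"{g.chrom}\tsim\tgene\t{g.gene_start}\t{g.gene_end}\t.\t{strand}\t.\t"
                    f"ID={g.gene_id};Name={g.symbol}\n"
                )
                for j, tss in enumerate(g.tss_list, 1):
                    t_start = tss if g.strand == +1 else g.gene_start
                    t_end = g.gene_end if g.strand == +1 else tss
                    fh.write(
                        f"{g.chrom}\tsim\tmRNA\t{t_start}\t{t_end}\t.\t{strand}\t.\t"
                        f"ID={g.gene_id}.t{j};Parent={g.gene_id}\n"
                    )

        if self.genome is not None:
            from .motif_scan import write_fasta

            paths["genome"] = os.path.join(outdir, "genome.fa")
            write_fasta(self.genome, paths["genome"])

        paths["pwm"] = os.path.join(outdir, "motif.jaspar")
        with open(paths["pwm"], "w") as fh:
            fh.write(f">{self.pwm.matrix_id} {self.pwm.consensus}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(f"{self.pwm.freqs[i, bi] * 100:.0f}" for i in range(self.pwm.length))
                fh.write(f"{base} [ {row} ]\n")

        paths["truth"] = os.path.join(outdir, "truth.json")
        with open(paths["truth"], "w") as fh:
            json.dump(asdict(self.truth), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ["genome", "genes", "probes", "spikes", "intensities", "annotations"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _simulate_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    i = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        for j in range(config.genes_per_chrom):
            if i >= config.n_genes:
                break
            tss = config.first_tss + j * config.gene_spacing
            strand = +1 if rng.random() < 0.5 else -1
            length = int(rng.integers(config.gene_length_min, config.gene_length_max + 1))
            if strand == +1:
                start, end = tss, tss + length
            else:
                start, end = max(1, tss - length), tss
            genes.append(
                GeneModel(
                    gene_id=f"g{i:04d}", symbol=f"G{i:04d}", chrom=chrom,
                    strand=strand, tss_list=[tss], gene_start=start, gene_end=end,
                )
            )
            i += 1
    return genes


def _tiled_window(gene: GeneModel, config: SimulationConfig) -> tuple[int, int]:
    tss = gene.tss_list[0]
    if gene.strand == +1:
        return tss - config.promoter_upstream, tss + config.promoter_downstream
    return tss - config.promoter_downstream, tss + config.promoter_upstream


def _simulate_probes(
    config: SimulationConfig, genes: list[GeneModel], rng: np.random.Generator
) -> list[Probe]:
    probes = []
    for gene in genes:
        lo, hi = _tiled_window(gene, config)
        lo = max(1, lo)
        for start in range(lo, hi - config.probe_length + 2, config.probe_spacing):
            probes.append(
                Probe(
                    probe_id=f"P_{gene.chrom}_{start:09d}",
                    chrom=gene.chrom,
                    start=start,
                    length=config.probe_length,
                )
            )
    n_multi = int(round(config.non_unique_fraction * len(probes)))
    if n_multi:
        from dataclasses import replace

        multi_idx = rng.choice(len(probes), size=n_multi, replace=False)
        for idx in multi_idx:
            probes[idx] = replace(probes[idx], n_genomic_hits=2)
    return probes


def _simulate_spikes(
    config: SimulationConfig, genes: list[GeneModel], rng: np.random.Generator
) -> list[dict]:
    chosen = rng.choice(len(genes), size=config.spike.n_targets, replace=False)
    spikes = []
    for idx in sorted(chosen.tolist()):
        gene = genes[idx]
        tss = gene.tss_list[0]
        offset = float(rng.uniform(config.spike.offset_min, config.spike.offset_max))
        center = tss + gene.strand * offset
        start = int(round(center - config.spike.width / 2))
        spikes.append(
            {
                "chrom": gene.chrom,
                "start": start,
                "end": start + config.spike.width - 1,
                "gene_id": gene.gene_id,
            }
        )
    return spikes


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a complete synthetic ChIP-chip experiment.

    Identical configs (including the seed) produce identical outputs,
    file-for-file and byte-for-byte.
    """
    rngs = _substreams(config.seed)
    genes = _simulate_genes(config, rngs["genes"])
    probes = _simulate_probes(config, genes, rngs["probes"])
    spikes = _simulate_spikes(config, genes, rngs["spikes"])

    mid = np.array([p.midpoint for p in probes])
    chroms = np.array([p.chrom for p in probes])
    true_lr = np.zeros(len(probes))
    for spike in spikes:
        inside = (chroms == spike["chrom"]) & (mid >= spike["start"]) & (mid <= spike["end"])
        true_lr[inside] = config.spike.height

    rng_int = rngs["intensities"]
    input_vals = np.exp(rng_int.normal(config.baseline_log_mean, config.baseline_log_sd, len(probes)))
    noise = rng_int.normal(0.0, config.noise_sd, len(probes)) if config.noise_sd > 0 else 0.0
    ip_vals = input_vals * np.exp2(true_lr + noise)

    ids = [p.probe_id for p in probes]
    truth = GroundTruth(spikes=spikes)

    pwm = default_motif_pwm()
    genome = None
    if config.with_genome:
        rng_gen = rngs["genome"]
        genome = {}
        for c in range(config.n_chroms):
            chrom = f"chr{c + 1}"
            seq = _BASES[rng_gen.integers(0, 4, config.chrom_length)].tobytes().decode()
            genome[chrom] = seq
        consensus = pwm.consensus
        for spike in spikes:
            seq = list(genome[spike["chrom"]])
            for _ in range(config.motif_instances_per_spike):
                pos = int(rng_gen.integers(spike["start"], spike["end"] - pwm.length + 2))
                strand = +1 if rng_gen.random() < 0.5 else -1
                planted = consensus if strand == +1 else revcomp(consensus)
                seq[pos - 1 : pos - 1 + pwm.length] = planted
                truth.motif_positions.append(
                    {
                        "chrom": spike["chrom"], "position": pos, "strand": strand,
                        "gene_id": spike["gene_id"],
                    }
                )
            genome[spike["chrom"]] = "".join(seq)

    return SimulatedExperiment(
        config=config,
        genes=genes,
        probes=probes,
        ip=pd.Series(ip_vals, index=ids, name="signal"),
        input_=pd.Series(input_vals, index=ids, name="signal"),
        true_log_ratio=pd.Series(true_lr, index=ids),
        genome=genome,
        pwm=pwm,
        truth=truth,
    )


def simulate_annotations(
    gene_ids: list[str],
    config: AnnotationConfig,
    rng: np.random.Generator | int,
    target_genes: set | None = None,
) -> tuple[TermGraph, dict[str, set], pd.DataFrame, GroundTruth]:
    """Random term DAG, annotations, and a DE list with one planted term.

    The DAG has ``dag_depth`` levels (root at level 1, guaranteed by a
    chain) and every non-root term draws its members uniformly — except
    the planted term, whose members are drawn with sampling weight
    ``planted_fold`` for genes in the target set (DE genes by default,
    or ``target_genes`` when given) and weight 1 otherwise.  With
    ``planted_fold=1`` the planted term is indistinguishable from its
    peers.  The planted term gets no children, so propagation leaves its
    gene set untouched.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    gene_ids = list(gene_ids)
    n_genes = len(gene_ids)
    if config.planted_term_size > n_genes:
        raise ValidationError("planted term larger than the gene universe")
    if config.planted_fold < 1:
        raise ValidationError("planted_fold must be >= 1")
    depth = config.dag_depth
    if depth < 2 or config.n_terms < depth:
        raise ValidationError("need n_terms >= dag_depth >= 2")

    root = "T0000"
    term_ids = [f"T{i + 1:04d}" for i in range(config.n_terms - 1)]
    planted = term_ids[-1]
    names = {root: "root"}
    levels: dict[str, int] = {root: 1}
    edges: list[tuple[str, str]] = []
    by_level: dict[int, list[str]] = {1: [root]}
    for i, term in enumerate(term_ids):
        if i < depth - 1:
            level = i + 2  # chain: guarantees every level is populated
        elif term == planted:
            level = depth
        else:
            level = int(rng.integers(2, depth + 1))
        levels[term] = level
        # parents never include the planted term, so it stays childless
        candidates = [t for t in by_level[level - 1] if t != planted]
        n_parents = 1 if len(candidates) == 1 else int(rng.integers(1, 3))
        parents = rng.choice(len(candidates), size=min(n_parents, len(candidates)), replace=False)
        for pi in sorted(parents.tolist()):
            edges.append((term, candidates[pi]))
        by_level.setdefault(level, []).append(term)
        names[term] = f"category {term}"
    graph = TermGraph.from_edges(edges, names)

    # DE list: a de_fraction sample of genes, plus every externally given target
    n_de = int(round(config.de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de_genes = {gene_ids[i] for i in de_idx.tolist()}
    if target_genes is not None:
        target = set(target_genes)
        de_genes |= target
    else:
        target = de_genes
    directions = {g: ("up" if rng.random() < 0.5 else "down") for g in sorted(de_genes)}
    de_table = pd.DataFrame(
        {
            "gene": sorted(de_genes),
            "log2fc": [
                (1 if directions[g] == "up" else -1) * float(rng.uniform(1.0, 3.0))
                for g in sorted(de_genes)
            ],
            "fdr": [float(rng.uniform(0.0, 0.05)) for _ in sorted(de_genes)],
        }
    )

    direct: dict[str, set] = {}
    weights = np.ones(n_genes)
    target_mask = np.array([g in target for g in gene_ids])
    weights[target_mask] = config.planted_fold
    weights /= weights.sum()
    for term in term_ids:
        if term == planted:
            members = rng.choice(n_genes, size=config.planted_term_size, replace=False, p=weights)
        else:
            size = int(rng.integers(config.term_size_min, config.term_size_max + 1))
            members = rng.choice(n_genes, size=min(size, n_genes), replace=False)
        for gi in members.tolist():
            direct.setdefault(gene_ids[gi], set()).add(term)

    truth = GroundTruth(de_genes=directions, planted_term=planted)
    return graph, direct, de_table, truth


def write_annotation_files(outdir, graph: TermGraph, direct: dict[str, set], de_table: pd.DataFrame) -> dict:
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "term_edges": os.path.join(outdir, "term_edges.tsv"),
        "term_names": os.path.join(outdir, "term_names.tsv"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "de_table": os.path.join(outdir, "de_genes.tsv"),
    }
    with open(paths["term_edges"], "w") as fh:
        fh.write("child_id\tparent_id\trelation\n")
        for child, parent in sorted(graph.graph.edges):
            fh.write(f"{child}\t{parent}\tis_a\n")
    with open(paths["term_names"], "w") as fh:
        fh.write("term_id\tname\n")
        for term in sorted(graph.terms):
            fh.write(f"{term}\t{graph.names.get(term, term)}\n")
    with open(paths["annotations"], "w") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(direct):
            for term in sorted(direct[gene]):
                fh.write(f"{gene}\t{term}\n")
    de_table.to_csv(paths["de_table"], sep="\t", index=False, float_format="%.6f")
    return paths


@dataclass
class RecoveryResult:
    sensitivity: float
    precision: float | None  # None when no regions were called
    table: pd.DataFrame


def evaluate_recovery(
    called: list[Cher],
    spikes: list[dict],
    min_overlap: float = 0.5,
) -> RecoveryResult:
    """Score called regions against planted spike intervals.

    A spike is recovered when a single called region covers at least
    ``min_overlap`` of its length; a called region is a true positive
    when it overlaps any spike at all.  With no called regions the
    precision is undefined and reported as None.
    """
    rows = []
    for spike in spikes:
        best = 0.0
        length = spike["end"] - spike["start"] + 1
        for c in called:
            if c.chrom != spike["chrom"]:
                continue
            ov = min(c.end, spike["end"]) - max(c.start, spike["start"]) + 1
            if ov > 0:
                best = max(best, ov / length)
        rows.append(
            {
                "chrom": spike["chrom"], "start": spike["start"], "end": spike["end"],
                "gene_id": spike.get("gene_id", ""), "best_overlap": best,
                "recovered": best >= min_overlap,
            }
        )
    table = pd.DataFrame(rows)
    sensitivity = float(table["recovered"].mean()) if rows else 1.0
    tp = 0
    for c in called:
        if any(
            c.chrom == s["chrom"] and min(c.end, s["end"]) - max(c.start, s["start"]) + 1 > 0
            for s in spikes
        ):
            tp += 1
    precision = (tp / len(called)) if called else None
    return RecoveryResult(sensitivity=sensitivity, precision=precision, table=table)
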