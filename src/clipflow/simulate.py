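"""Seeded generators for a toy genome, crosslink libraries, a splicing and
feature-usage time course, and a differential-expression table, each with a
recorded ground truth.

One global seed feeds named per-generator substreams (genome / iclip /
timecourse / deg) so the stages can be re-run independently and are
byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crosslinks import CrosslinkTable
from .genome import (
    FlatFeature,
    Gene,
    GenomeAnnotation,
    Transcript,
    cotranscribed_region,
    flatten_features,
)

_BASES = np.array(list("ACGT"))
_SUBSTREAMS = {"genome": 0, "iclip": 1, "timecourse": 2, "deg": 3}

DEFAULT_TIMEPOINTS = ("MEF", "d3", "d6", "d9", "d12", "iPSC")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 30
    gene_length_range: tuple[int, int] = (1500, 3000)
    motif: str = "CUCUC"  # pyrimidine-rich 5-mer, RNA alphabet
    signal_to_background: float = 50.0
    background_rate: float = 0.2  # crosslink events per nt of co-transcribed region
    n_planted_sites: int = 20
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 2
    n_clusters_planted: int = 3   # binding-enriched trajectory groups
    n_decoy_clusters: int = 3     # additional trajectory groups without enrichment
    sarf_concentration: float = 0.85
    di_fraction: float = 0.2
    n_events: int = 150
    event_depth: int = 60
    frac_events_changing: float = 0.3
    regulated_fraction: float = 0.45
    feature_baseline: tuple[float, float] = (100.0, 300.0)
    generest_baseline: tuple[float, float] = (1000.0, 3000.0)
    deg_fraction: float = 0.25
    deg_effects: dict | None = None  # gene_id -> (log2fc, fdr) override
    traj_shapes: list[list[float]] | None = None  # cumulative log2fc per group

    def rng(self, substream: str) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=self.seed,
                                    spawn_key=(_SUBSTREAMS[substream],))
        return np.random.default_rng(ss)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        data = json.loads(Path(path).read_text())
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                value = data[f.name]
                kwargs[f.name] = tuple(value) if isinstance(value, list) and f.name in (
                    "gene_length_range", "timepoints", "feature_baseline",
                    "generest_baseline") else value
        return cls(**kwargs)


@dataclass
class GroundTruth:
    motif: str = ""
    planted_sites: list[dict] = field(default_factory=list)
    di_introns: list[dict] = field(default_factory=list)
    feature_cluster: dict[str, int] = field(default_factory=dict)
    feature_bound: dict[str, bool] = field(default_factory=dict)
    event_psi: dict[str, list[float]] = field(default_factory=dict)
    deg: dict[str, dict] = field(default_factory=dict)
    traj_shapes: list[list[float]] = field(default_factory=list)

    def planted_positions(self) -> set[tuple[str, str, int]]:
        return {(s["chrom"], s["strand"], s["position"]) for s in self.planted_sites}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ------------------------------------------------------------- genome

def generate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, GroundTruth]:
    """Random multi-exon genes on both strands with planted motif instances
    at recorded exonic and intronic positions."""
    if config.n_genes < 1:
        raise ValueError("empty simulation: n_genes must be >= 1")
    rng = config.rng("genome")
    truth = GroundTruth(motif=config.motif.upper().replace("T", "U"))
    motif_dna = _rna_to_dna(config.motif)

    genes: list[Gene] = []
    chrom_cursors: dict[str, int] = {}
    genes_per_chrom = 10
    gene_meta: list[dict] = []
    for gi in range(config.n_genes):
        chrom = f"chr{gi // genes_per_chrom + 1}"
        cursor = chrom_cursors.get(chrom, 300)
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "coding" if rng.random() < 0.85 else "noncoding"
        n_exons = int(rng.integers(2, 6))
        exon_lens = rng.integers(80, 301, size=n_exons)
        span_target = int(rng.integers(*config.gene_length_range))
        min_intron = 120
        budget = max(span_target - int(exon_lens.sum()), min_intron * (n_exons - 1))
        extra = budget - min_intron * (n_exons - 1)
        fracs = rng.dirichlet(np.ones(n_exons - 1))
        intron_lens = (min_intron + np.floor(fracs * extra)).astype(int)
        exons = []
        pos = cursor
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        gene_id = f"g{gi + 1:03d}"
        tx1 = Transcript(f"{gene_id}.t1", exons, tsl=1)
        transcripts = [tx1]
        if n_exons >= 3 and rng.random() < 0.3:
            skip = int(rng.integers(1, n_exons - 1))
            tx2_exons = [iv for i, iv in enumerate(exons) if i != skip]
            transcripts.append(Transcript(f"{gene_id}.t2", tx2_exons, tsl=1))
        cds = None
        if biotype == "coding":
            first, last = exons[0], exons[-1]
            cds = (first[0] + (first[1] - first[0]) // 2,
                   last[0] + (last[1] - last[0]) // 2)
            for tx in transcripts:
                tx.cds = cds
        genes.append(Gene(gene_id, chrom, strand, transcripts, biotype=biotype))
        gene_meta.append({"gene": genes[-1], "tx1_exons": exons,
                          "tx1_introns": tx1.introns()})
        chrom_cursors[chrom] = pos + 300

    chromosomes = {
        chrom: "".join(rng.choice(_BASES, size=cursor + 300))
        for chrom, cursor in sorted(chrom_cursors.items())
    }

    # plant motifs: alternate exonic / intronic placement, gene round-robin
    seq_arrays = {c: np.array(list(s)) for c, s in chromosomes.items()}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chromosomes}
    mlen = len(motif_dna)
    margin = 20
    # crosslink site sits 8 nt 5' of the motif in transcript orientation, so
    # the motif falls inside the downstream (+5,+30) k-mer window
    site_gap = 8
    planted = 0
    attempt = 0
    while planted < config.n_planted_sites and attempt < config.n_planted_sites * 100:
        attempt += 1
        meta = gene_meta[planted % len(gene_meta)]
        gene = meta["gene"]
        want_exonic = planted % 2 == 0
        segments = meta["tx1_exons"] if want_exonic or not meta["tx1_introns"] \
            else meta["tx1_introns"]
        seg = segments[int(rng.integers(0, len(segments)))]
        if seg[1] - seg[0] < 2 * margin + mlen:
            continue
        start = int(rng.integers(seg[0] + margin, seg[1] - margin - mlen))
        if any(start < e and start + mlen > s for s, e in occupied[gene.chrom]):
            continue
        if gene.strand == "+":
            insert = motif_dna
            site = start - site_gap
        else:
            insert = _revcomp_dna(motif_dna)
            site = start + mlen - 1 + site_gap
        span = cotranscribed_region(gene)
        if not any(s <= site < e for s, e in span):
            continue
        seq_arrays[gene.chrom][start : start + mlen] = list(insert)
        occupied[gene.chrom].append((start, start + mlen))
        truth.planted_sites.append({
            "chrom": gene.chrom, "strand": gene.strand,
            "position": site, "gene_id": gene.gene_id,
            "segment": "exon" if want_exonic else "intron",
        })
        planted += 1
    chromosomes = {c: "".join(a) for c, a in seq_arrays.items()}

    # flag a di_fraction of distinct introns as detained
    for meta in gene_meta:
        gene = meta["gene"]
        introns = sorted({iv for t in gene.transcripts for iv in t.introns()})
        for s, e in introns:
            if config.di_fraction > 0 and rng.random() < config.di_fraction:
                truth.di_introns.append({
                    "gene_id": gene.gene_id, "chrom": gene.chrom,
                    "strand": gene.strand, "start": s, "end": e,
                })

    annotation = GenomeAnnotation(chromosomes, genes)
    annotation.validate()
    return annotation, truth


# ------------------------------------------------------------- iCLIP

def simulate_iclip(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[CrosslinkTable, CrosslinkTable]:
    """Poisson crosslink counts: planted positions at rate
    signal_to_background * background, everything else (and the whole
    control library) at the background rate, over co-transcribed regions."""
    if config.signal_to_background < 1:
        raise ValueError("signal_to_background must be >= 1")
    rng = config.rng("iclip")
    planted = truth.planted_positions()
    signal, control = CrosslinkTable(), CrosslinkTable()
    for gene in annotation.genes:
        for s, e in cotranscribed_region(gene):
            positions = np.arange(s, e)
            lam = np.full(e - s, config.background_rate)
            for i, p in enumerate(positions):
                if (gene.chrom, gene.strand, int(p)) in planted:
                    lam[i] = config.signal_to_background * config.background_rate
            sig_counts = rng.poisson(lam)
            ctl_counts = rng.poisson(np.full(e - s, config.background_rate))
            for p, c in zip(positions[sig_counts > 0], sig_counts[sig_counts > 0]):
                signal.add(gene.chrom, gene.strand, int(p), int(c))
            for p, c in zip(positions[ctl_counts > 0], ctl_counts[ctl_counts > 0]):
                control.add(gene.chrom, gene.strand, int(p), int(c))
    return signal, control


# ------------------------------------------------------------- time course

def default_traj_shapes(n_timepoints: int, n_groups: int = 6) -> list[list[float]]:
    """Monotone cumulative log2FC profiles (vs the first timepoint) with
    distinct onset times; the second half are the mirrored falls."""
    base = np.array([
        [0.0, 0.1, 0.3, 0.6, 1.6, 3.2],   # late rise
        [0.0, 2.2, 2.6, 2.8, 2.9, 3.0],   # early rise
        [0.0, 0.6, 1.2, 1.8, 2.4, 3.0],   # gradual rise
    ])
    grid = np.linspace(0, 1, base.shape[1])
    target = np.linspace(0, 1, n_timepoints)
    rises = [list(np.interp(target, grid, row)) for row in base]
    shapes = rises + [[-v for v in row] for row in rises]
    reps = -(-n_groups // len(shapes))
    scaled = []
    for r in range(reps):
        factor = 1.0 / (1.0 + 0.35 * r)
        scaled.extend([[v * factor for v in row] for row in shapes])
    return scaled[:n_groups]


def _feature_is_bound(feature: FlatFeature, truth: GroundTruth, window: int = 200) -> bool:
    for s in truth.planted_sites:
        if (s["chrom"], s["strand"]) != (feature.chrom, feature.strand):
            continue
        if feature.start - window <= s["position"] < feature.end + window:
            return True
    return False


def simulate_timecourse(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inclusion/exclusion counts for annotated-style AS events and flat
    feature/gene-rest counts over the time course.

    Binding-associated features are concentrated into the first
    ``n_clusters_planted`` trajectory groups; the ground truth records each
    feature's group, its bound flag, and every event's true PSI trajectory.
    """
    tps = list(config.timepoints)
    if len(tps) < 2:
        raise ValueError("need >= 2 timepoints")
    rng = config.rng("timecourse")
    n_groups = config.n_clusters_planted + config.n_decoy_clusters
    shapes = config.traj_shapes or default_traj_shapes(len(tps), n_groups)
    if any(len(row) != len(tps) for row in shapes):
        raise ValueError("traj_shapes rows must match the number of timepoints")
    truth.traj_shapes = [list(map(float, row)) for row in shapes]
    n_groups = len(shapes)

    # --- AS events ---------------------------------------------------------
    event_rows = []
    types = ("SE", "IR", "MXE", "A5SS", "A3SS")
    genes = annotation.genes
    for i in range(config.n_events):
        gene = genes[i % len(genes)]
        ev_type = types[i % len(types)]
        tx = gene.transcripts[0]
        introns = tx.introns()
        if ev_type == "IR" and introns:
            iv = introns[int(rng.integers(0, len(introns)))]
        else:
            iv = tx.exons[int(rng.integers(0, len(tx.exons)))]
        base_psi = float(rng.uniform(0.2, 0.8))
        psis = np.full(len(tps), base_psi)
        if rng.random() < config.frac_events_changing:
            onset = int(rng.integers(1, len(tps)))
            shift = float(rng.choice([-0.3, 0.3]))
            psis[onset:] = np.clip(base_psi + shift, 0.05, 0.95)
        event_id = f"ev{i + 1:04d}"
        truth.event_psi[event_id] = [float(p) for p in psis]
        row = {
            "event_id": event_id, "type": ev_type, "gene_id": gene.gene_id,
            "chrom": gene.chrom, "strand": gene.strand,
            "start": iv[0], "end": iv[1],
        }
        for ti, tp in enumerate(tps):
            for rep in range(1, config.n_replicates + 1):
                depth = int(rng.poisson(config.event_depth))
                inc = int(rng.binomial(depth, psis[ti])) if depth > 0 else 0
                row[f"inc_{tp}_{rep}"] = inc
                row[f"exc_{tp}_{rep}"] = depth - inc
        event_rows.append(row)
    events = pd.DataFrame(event_rows)

    # --- flat features -----------------------------------------------------
    features = flatten_features(annotation, tsl_max=1)
    di_keys = {(d["gene_id"], d["start"], d["end"]) for d in truth.di_introns}
    bound = {f.feature_id: _feature_is_bound(f, truth) for f in features}
    truth.feature_bound = bound

    regulated: dict[str, int] = {}
    n_target = int(round(config.regulated_fraction * len(features)))
    for f in features:
        if bound[f.feature_id]:
            if rng.random() < config.sarf_concentration:
                regulated[f.feature_id] = int(rng.integers(0, config.n_clusters_planted))
            else:
                regulated[f.feature_id] = int(rng.integers(0, n_groups))
    # detained introns follow a rising retention trajectory
    rise_group = min(2, n_groups - 1)
    for f in features:
        if f.kind == "intron" and (f.gene_id, f.start, f.end) in di_keys:
            regulated.setdefault(f.feature_id, rise_group)
    unbound_pool = [f.feature_id for f in features if f.feature_id not in regulated]
    n_extra = max(0, n_target - len(regulated))
    # extras fill the decoy groups so every trajectory group is populated
    lo = config.n_clusters_planted if config.n_decoy_clusters > 0 else 0
    for fid in rng.permutation(unbound_pool)[:n_extra]:
        regulated[str(fid)] = int(rng.integers(lo, n_groups))
    truth.feature_cluster = {
        f.feature_id: regulated.get(f.feature_id, -1) for f in features
    }

    feature_rows = []
    for f in features:
        base = float(rng.uniform(*config.feature_baseline))
        rest = float(rng.uniform(*config.generest_baseline))
        group = regulated.get(f.feature_id, -1)
        row = {
            "feature_id": f.feature_id, "gene_id": f.gene_id, "kind": f.kind,
            "chrom": f.chrom, "start": f.start, "end": f.end, "strand": f.strand,
        }
        for ti, tp in enumerate(tps):
            mean = base * (2.0 ** shapes[group][ti]) if group >= 0 else base
            for rep in range(1, config.n_replicates + 1):
                row[f"count_{tp}_{rep}"] = int(rng.poisson(mean))
                row[f"rest_{tp}_{rep}"] = int(rng.poisson(rest))
        feature_rows.append(row)
    feature_table = pd.DataFrame(feature_rows)
    return events, feature_table


# ------------------------------------------------------------- DEG table

def simulate_deg_table(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-gene log2FC/FDR table with bound and NMD labels recorded in the
    ground truth."""
    rng = config.rng("deg")
    bound_genes = {s["gene_id"] for s in truth.planted_sites}
    rows = []
    for gene in annotation.genes:
        override = (config.deg_effects or {}).get(gene.gene_id)
        if override is not None:
            log2fc, fdr = float(override[0]), float(override[1])
            is_deg = fdr < 0.05 and abs(log2fc) >= 1.0
        elif rng.random() < config.deg_fraction:
            sign = 1.0 if rng.random() < 0.6 else -1.0
            log2fc = float(sign * rng.uniform(1.2, 3.0))
            fdr = float(rng.uniform(1e-6, 0.01))
            is_deg = True
        else:
            log2fc = float(np.clip(rng.normal(0.0, 0.3), -0.9, 0.9))
            fdr = float(rng.uniform(0.06, 1.0))
            is_deg = False
        bound = gene.gene_id in bound_genes
        nmd_gene = bool(rng.random() < (0.4 if bound else 0.15))
        nmd_mrna = bool(rng.random() < (0.45 if bound else 0.1))
        truth.deg[gene.gene_id] = {
            "log2fc": log2fc, "fdr": fdr, "is_deg": is_deg,
            "bound": bound, "nmd_gene": nmd_gene, "nmd_mrna": nmd_mrna,
        }
        rows.append({
            "gene_id": gene.gene_id, "log2fc": log2fc, "fdr": fdr,
            "bound": bound, "nmd_gene": nmd_gene, "nmd_mrna": nmd_mrna,
        })
    return pd.DataFrame(rows)
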