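"""PSI/PIR estimation, closed-form beta-binomial Bayes factors, the event
filter list, and site-to-event association."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln

from .genome import GenomeAnnotation, cotranscribed_region

EVENT_TYPES = ("SE", "IR", "MXE", "A5SS", "A3SS")


@dataclass
class FilterThresholds:
    """Event filters; all bounds inclusive (per the 'at least' wording)."""

    min_inc: int = 1        # inclusion reads per sample
    min_exc: int = 1        # exclusion reads per sample
    min_sum: int = 10       # inc+exc in at least one sample
    min_dpsi: float = 0.2   # |delta PSI|
    min_bf: float = 5.0     # Bayes factor


@dataclass
class SpliceEventRecord:
    event_id: str
    type: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    a_inc: int = 0
    a_exc: int = 0
    b_inc: int = 0
    b_exc: int = 0
    psi_a: float | None = None
    psi_b: float | None = None
    delta_psi: float | None = None
    bayes_factor: float | None = None
    passed: bool | None = None
    reasons: list[str] = field(default_factory=list)


def psi_point(inclusion: int, exclusion: int) -> tuple[float | None, float]:
    """(raw ratio, posterior mean) inclusion fraction.

    The posterior mean is (inc+1)/(inc+exc+2) under a uniform prior.  When
    both counts are zero the raw ratio is undefined (None); the posterior
    mean 0.5 is still returned.
    """
    if inclusion < 0 or exclusion < 0:
        raise ValueError("counts must be non-negative")
    total = inclusion + exclusion
    raw = inclusion / total if total > 0 else None
    post = (inclusion + 1) / (total + 2)
    return raw, post


def delta_psi_bayes(
    a_inc: int, a_exc: int, b_inc: int, b_exc: int
) -> tuple[float, float]:
    """Posterior-mean delta-PSI and closed-form Bayes factor.

    BF10 compares independent inclusion fractions psi_a, psi_b ~ Beta(1,1)
    against a single shared psi ~ Beta(1,1):

        BF = B(a_inc+1, a_exc+1) * B(b_inc+1, b_exc+1)
             / B(a_inc+b_inc+1, a_exc+b_exc+1)

    (binomial coefficients cancel; B(1,1) = 1).
    """
    if a_inc + a_exc == 0 or b_inc + b_exc == 0:
        raise ValueError("untestable: zero total reads in a condition")
    log_bf = (
        betaln(a_inc + 1, a_exc + 1)
        + betaln(b_inc + 1, b_exc + 1)
        - betaln(a_inc + b_inc + 1, a_exc + b_exc + 1)
    )
    dpsi = psi_point(a_inc, a_exc)[1] - psi_point(b_inc, b_exc)[1]
    return dpsi, math.exp(log_bf)


def apply_event_filters(
    record: SpliceEventRecord,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[bool, list[str]]:
    """Pass/fail plus the names of every failed clause.

    Clauses: num-inc, num-exc (per sample), num-sum-inc-exc (>= min_sum in
    at least one sample), delta-psi, bayes-factor.
    """
    t = thresholds
    reasons = []
    if record.a_inc < t.min_inc or record.b_inc < t.min_inc:
        reasons.append("num-inc")
    if record.a_exc < t.min_exc or record.b_exc < t.min_exc:
        reasons.append("num-exc")
    if max(record.a_inc + record.a_exc, record.b_inc + record.b_exc) < t.min_sum:
        reasons.append("num-sum-inc-exc")
    if record.delta_psi is None or abs(record.delta_psi) < t.min_dpsi:
        reasons.append("delta-psi")
    if record.bayes_factor is None or record.bayes_factor < t.min_bf:
        reasons.append("bayes-factor")
    passed = not reasons
    record.passed = passed
    record.reasons = reasons
    return passed, reasons


def compare_events(
    events: list[SpliceEventRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[SpliceEventRecord]:
    """Fill psi/delta/BF and filter flags for events that already carry
    summed per-condition counts (replicates merged upstream)."""
    for ev in events:
        ev.psi_a = psi_point(ev.a_inc, ev.a_exc)[1]
        ev.psi_b = psi_point(ev.b_inc, ev.b_exc)[1]
        if ev.a_inc + ev.a_exc > 0 and ev.b_inc + ev.b_exc > 0:
            ev.delta_psi, ev.bayes_factor = delta_psi_bayes(
                ev.a_inc, ev.a_exc, ev.b_inc, ev.b_exc
            )
        else:
            ev.delta_psi = ev.bayes_factor = None
        apply_event_filters(ev, thresholds)
    return events


def _metagene_position(
    site_pos: int, exon_start: int, exon_end: int, strand: str
) -> tuple[str, float]:
    """Splice-site-relative coordinate of a site around an exon.

    In transcript orientation the exon spans the 3'SS (acceptor, coordinate
    0) to the 5'SS (donor).  Upstream intronic sites get negative distances
    to the 3'SS, downstream intronic sites positive distances from the 5'SS,
    and exonic sites a length-normalized position in [0, 1].
    """
    if strand == "+":
        d3 = site_pos - exon_start   # negative upstream of acceptor
        d5 = site_pos - (exon_end - 1)
    else:
        d3 = (exon_end - 1) - site_pos
        d5 = exon_start - site_pos
    length = exon_end - exon_start
    if d3 < 0:
        return "upstream_intron", float(d3)
    if d5 > 0:
        return "downstream_intron", float(d5)
    return "exon", d3 / max(length - 1, 1)


def event_binding_association(
    events: list[SpliceEventRecord],
    sites,
    annotation: GenomeAnnotation,
    metagene_halfwidth: int = 200,
) -> dict:
    """Per-type up/down tallies, fraction of passing events with >= 1 site in
    the host transcript region, and SE metagene site positions."""
    gene_regions = {}
    for gene in annotation.genes:
        gene_regions[gene.gene_id] = (gene.chrom, gene.strand,
                                      cotranscribed_region(gene))
    site_pos: dict[tuple[str, str], np.ndarray] = {}
    for s in sites:
        site_pos.setdefault((s.chrom, s.strand), []).append(s.position)  # type: ignore[arg-type]
    site_pos = {k: np.array(sorted(v)) for k, v in site_pos.items()}

    def sites_between(chrom, strand, lo, hi):
        arr = site_pos.get((chrom, strand))
        if arr is None:
            return np.array([], dtype=int)
        i, j = np.searchsorted(arr, [lo, hi])
        return arr[i:j]

    tallies = {t: {"up": 0, "down": 0} for t in EVENT_TYPES}
    passing = [ev for ev in events if ev.passed]
    n_bound = 0
    metagene = []
    for ev in passing:
        if ev.gene_id not in gene_regions:
            warnings.warn(f"event {ev.event_id}: no host gene; skipped", stacklevel=2)
            continue
        if ev.delta_psi is not None:
            tallies[ev.type]["up" if ev.delta_psi > 0 else "down"] += 1
        chrom, strand, ivs = gene_regions[ev.gene_id]
        if any(sites_between(chrom, strand, s, e).size > 0 for s, e in ivs):
            n_bound += 1
    for ev in events:
        if ev.type != "SE":
            continue
        for pos in sites_between(ev.chrom, ev.strand,
                                 ev.start - metagene_halfwidth,
                                 ev.end + metagene_halfwidth):
            zone, value = _metagene_position(int(pos), ev.start, ev.end, ev.strand)
            metagene.append({
                "event_id": ev.event_id, "position": int(pos),
                "zone": zone, "value": value,
                "significant": bool(ev.passed),
            })
    fraction = n_bound / len(passing) if passing else None
    return {
        "tallies": tallies,
        "fraction_bound": fraction,
        "n_passing": len(passing),
        "n_bound": n_bound,
        "se_metagene": pd.DataFrame(
            metagene, columns=["event_id", "position", "zone", "value", "significant"]
        ),
    }


# ---------------------------------------------------------------- TSV interop

def events_to_frame(events: list[SpliceEventRecord]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append({
            "event_id": ev.event_id, "type": ev.type, "gene_id": ev.gene_id,
            "chrom": ev.chrom, "strand": ev.strand, "start": ev.start, "end": ev.end,
            "a_inc": ev.a_inc, "a_exc": ev.a_exc, "b_inc": ev.b_inc, "b_exc": ev.b_exc,
            "psi_a": ev.psi_a, "psi_b": ev.psi_b, "delta_psi": ev.delta_psi,
            "bayes_factor": ev.bayes_factor, "pass": ev.passed,
            "reasons": ",".join(ev.reasons),
        })
    return pd.DataFrame(rows)
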