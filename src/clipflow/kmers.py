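"""Windowed k-mer enrichment around crosslink sites.

K-mers are counted in two transcript-orientation windows around each site
(default closed offsets (-30,-5) and (+5,+30)); by default each site
contributes at most weight 1.0 per k-mer (presence weighting), regardless of
how many times or in how many windows the k-mer occurs.  A shuffled null is
built by relocating sites uniformly within their co-transcribed regions and
z-scores are computed against the per-shuffle weights.

All k-mers are reported in the RNA alphabet (ACGU); minus-strand windows are
reverse-complemented so sequences read in transcript orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Interval, transcript_window

_COMPLEMENT = str.maketrans("ACGTU", "UGCAA")

DEFAULT_WINDOWS = ((-30, -5), (5, 30))

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("U"): "U",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AU"): "W",
    frozenset("CG"): "S", frozenset("CU"): "Y", frozenset("GU"): "K",
    frozenset("ACG"): "V", frozenset("ACU"): "H", frozenset("AGU"): "D",
    frozenset("CGU"): "B", frozenset("ACGU"): "N",
}


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _revcomp_rna(seq: str) -> str:
    return _to_rna(seq).translate(_COMPLEMENT)[::-1]


@dataclass
class KmerZTable:
    table: pd.DataFrame  # columns kmer, observed, null_mean, null_sd, z, sd_zero
    k: int
    windows: tuple
    n_shuffles: int

    def top(self, n: int) -> list[str]:
        return list(self.table.sort_values(["z", "kmer"], ascending=[False, True])
                    .head(n).kmer)


def _site_kmers(
    sequence: str,
    position: int,
    strand: str,
    k: int,
    windows,
) -> set[str]:
    """Distinct RNA k-mers in the union of the evaluated windows of one site."""
    found: set[str] = set()
    bounds = (0, len(sequence))
    for offs in windows:
        if k > offs[1] - offs[0] + 1:
            raise ValueError(f"k={k} exceeds window length {offs}")
        for gs, ge in transcript_window(position, offs, strand, bounds):
            seg = sequence[gs:ge]
            seg = _to_rna(seg) if strand == "+" else _revcomp_rna(seg)
            for i in range(len(seg) - k + 1):
                found.add(seg[i : i + k])
    return found


def site_kmer_weights(
    sequences: dict[str, str],
    sites,
    k: int = 5,
    windows=DEFAULT_WINDOWS,
    presence: bool = True,
) -> dict[str, float]:
    """Per k-mer total weight over sites.

    With ``presence=True`` (default) each site contributes 1.0 per distinct
    k-mer present in its windows; with ``presence=False`` every occurrence
    contributes 1.0.
    """
    weights: dict[str, float] = {}
    for site in sites:
        seq = sequences[site.chrom]
        if presence:
            for kmer in _site_kmers(seq, site.position, site.strand, k, windows):
                weights[kmer] = weights.get(kmer, 0.0) + 1.0
        else:
            bounds = (0, len(seq))
            for offs in windows:
                for gs, ge in transcript_window(site.position, offs, site.strand, bounds):
                    seg = seq[gs:ge]
                    seg = _to_rna(seg) if site.strand == "+" else _revcomp_rna(seg)
                    for i in range(len(seg) - k + 1):
                        kmer = seg[i : i + k]
                        weights[kmer] = weights.get(kmer, 0.0) + 1.0
    return weights


def _assign_regions(sites, regions: dict[tuple[str, str], list[Interval]]):
    """Pair each site with the co-transcribed interval containing it."""
    paired = []
    for site in sites:
        for s, e in regions.get((site.chrom, site.strand), []):
            if s <= site.position < e:
                paired.append((site, (s, e)))
                break
        else:
            raise ValueError(
                f"site {site.chrom}:{site.position}({site.strand}) not in any region"
            )
    return paired


class _Relocated:
    __slots__ = ("chrom", "strand", "position")

    def __init__(self, chrom, strand, position):
        self.chrom, self.strand, self.position = chrom, strand, position


def kmer_zscores(
    sequences: dict[str, str],
    sites,
    regions: dict[tuple[str, str], list[Interval]],
    k: int = 5,
    windows=DEFAULT_WINDOWS,
    n_shuffles: int = 100,
    seed: int | None = None,
    presence: bool = True,
) -> KmerZTable:
    """Observed k-mer weights vs a shuffled null of relocated sites.

    z(kmer) = (observed - mean_null) / sd_null (sample sd).  If sd_null is 0
    the z-score is defined as 0 and flagged in the ``sd_zero`` column.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2 (sd undefined otherwise)")
    rng = np.random.default_rng(seed)
    paired = _assign_regions(sites, regions)
    observed = site_kmer_weights(sequences, [s for s, _ in paired], k, windows, presence)

    null_rows: list[dict[str, float]] = []
    for _ in range(n_shuffles):
        relocated = [
            _Relocated(site.chrom, site.strand, int(rng.integers(s, e)))
            for site, (s, e) in paired
        ]
        null_rows.append(site_kmer_weights(sequences, relocated, k, windows, presence))

    all_kmers = sorted(set(observed) | {km for row in null_rows for km in row})
    null = np.zeros((n_shuffles, len(all_kmers)))
    for i, row in enumerate(null_rows):
        for j, km in enumerate(all_kmers):
            if km in row:
                null[i, j] = row[km]
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    obs = np.array([observed.get(km, 0.0) for km in all_kmers])
    sd_zero = sd == 0
    z = np.zeros(len(all_kmers))
    np.divide(obs - mean, sd, out=z, where=~sd_zero)
    table = pd.DataFrame({
        "kmer": all_kmers,
        "observed": obs,
        "null_mean": mean,
        "null_sd": sd,
        "z": z,
        "sd_zero": sd_zero,
    })
    return KmerZTable(table=table, k=k, windows=tuple(windows), n_shuffles=n_shuffles)


def _best_offset(seed_kmer: str, kmer: str) -> tuple[int, int]:
    """Best ungapped alignment offset of ``kmer`` against ``seed_kmer``.

    Score is the number of matching positions in the overlap; ties prefer
    offset 0, then the smallest |offset|.  Returns (offset, score).
    """
    k, m = len(seed_kmer), len(kmer)
    candidates: list[tuple[int, int]] = []
    for off in range(-(m - 1), k):
        score = 0
        overlap = 0
        for i in range(m):
            j = off + i
            if 0 <= j < k:
                overlap += 1
                if kmer[i] == seed_kmer[j]:
                    score += 1
        if overlap >= 2:
            candidates.append((off, score))
    if not candidates:
        return 0, 0
    best = max(s for _, s in candidates)
    tied = [o for o, s in candidates if s == best]
    if 0 in tied:
        return 0, best
    tied.sort(key=lambda o: (abs(o), o))
    return tied[0], best


def consensus_from_top_kmers(
    top_kmers: list[str],
    weights: dict[str, float] | None = None,
    majority: float = 0.66,
) -> tuple[pd.DataFrame, str]:
    """Greedy ungapped alignment of k-mers to the top-ranked seed.

    Returns a position-weight matrix (rows = ACGU frequencies per column)
    and an IUPAC consensus string where each column letter covers at least
    the ``majority`` fraction of the column weight.
    """
    if not top_kmers:
        raise ValueError("no k-mers given")
    kmers = [_to_rna(km) for km in top_kmers]
    klen = {len(km) for km in kmers}
    if len(klen) != 1:
        raise ValueError("k-mers must have equal length")
    if weights is None:
        weights = {km: 1.0 for km in kmers}
    else:
        weights = {_to_rna(km): w for km, w in weights.items()}
    seed = kmers[0]
    placements: list[tuple[str, int]] = [(seed, 0)]
    for km in kmers[1:]:
        off, score = _best_offset(seed, km)
        if score < 2:
            warnings.warn(f"k-mer {km} has no >=2-nt overlap with seed; stacked at 0",
                          stacklevel=2)
            off = 0
        placements.append((km, off))
    lo = min(off for _, off in placements)
    hi = max(off + len(km) for km, off in placements)
    ncol = hi - lo
    alphabet = "ACGU"
    pwm = np.zeros((ncol, 4))
    for km, off in placements:
        w = weights.get(km, 1.0)
        for i, base in enumerate(km):
            if base in alphabet:
                pwm[off - lo + i, alphabet.index(base)] += w
    totals = pwm.sum(axis=1, keepdims=True)
    freq = np.divide(pwm, totals, out=np.zeros_like(pwm), where=totals > 0)
    letters = []
    for row in freq:
        order = np.argsort(-row, kind="stable")
        chosen: set[str] = set()
        cum = 0.0
        for idx in order:
            if row[idx] <= 0 and chosen:
                break
            chosen.add(alphabet[idx])
            cum += row[idx]
            if cum >= majority:
                break
        letters.append(IUPAC[frozenset(chosen)])
    pwm_df = pd.DataFrame(freq, columns=list(alphabet))
    return pwm_df, "".join(letters)
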