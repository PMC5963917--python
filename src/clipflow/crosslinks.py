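"""Crosslink tables and significant binding-site calling.

Significance uses a randomization FDR: per co-transcribed region the
observed crosslink events are redistributed uniformly at random (with
collisions, i.e. multinomially) ``n_rand`` times, and for every observed
count height k, FDR(k) = E_null[#positions with count >= k] / obs[#positions
with count >= k], monotonized to be non-increasing in k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Interval, STRANDS

Key = tuple[str, str]  # (chrom, strand)


@dataclass
class CrosslinkTable:
    """Strand-aware per-nucleotide unique-cDNA counts."""

    counts: dict[Key, dict[int, int]] = field(default_factory=dict)

    def add(self, chrom: str, strand: str, position: int, count: int = 1) -> None:
        if strand not in STRANDS:
            raise ValueError(f"bad strand {strand!r}")
        if count < 1:
            raise ValueError("counts must be positive")
        d = self.counts.setdefault((chrom, strand), {})
        d[position] = d.get(position, 0) + count

    def get(self, chrom: str, strand: str, position: int) -> int:
        return self.counts.get((chrom, strand), {}).get(position, 0)

    def total_events(self) -> int:
        return sum(c for d in self.counts.values() for c in d.values())

    def n_positions(self) -> int:
        return sum(len(d) for d in self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, strand, pos, cnt)
            for (chrom, strand), d in sorted(self.counts.items())
            for pos, cnt in sorted(d.items())
        ]
        return pd.DataFrame(rows, columns=["chrom", "strand", "position", "count"])

    def to_bed6(self) -> pd.DataFrame:
        df = self.to_frame()
        return pd.DataFrame({
            "chrom": df.chrom,
            "start": df.position,
            "end": df.position + 1,
            "name": [f"x{i}" for i in range(len(df))],
            "score": df["count"],
            "strand": df.strand,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CrosslinkTable":
        table = cls()
        for r in df.itertuples():
            table.add(r.chrom, r.strand, int(r.position), int(r.count))
        return table

    @classmethod
    def from_bed6(cls, df: pd.DataFrame) -> "CrosslinkTable":
        table = cls()
        for r in df.itertuples():
            table.add(r.chrom, r.strand, int(r.start), int(r.score))
        return table


@dataclass
class BindingSite:
    chrom: str
    strand: str
    position: int
    count: int
    fdr: float


@dataclass
class BindingSiteSet:
    sites: list[BindingSite]
    alpha: float = 0.05

    def __iter__(self):
        return iter(self.sites)

    def __len__(self):
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.chrom, s.strand, s.position, s.count, s.fdr) for s in self.sites],
            columns=["chrom", "strand", "position", "count", "fdr"],
        )

    def to_bed6(self) -> pd.DataFrame:
        df = self.to_frame()
        return pd.DataFrame({
            "chrom": df.chrom,
            "start": df.position,
            "end": df.position + 1,
            "name": [f"site{i}" for i in range(len(df))],
            "score": df["count"],
            "strand": df.strand,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, alpha: float = 0.05) -> "BindingSiteSet":
        sites = [
            BindingSite(r.chrom, r.strand, int(r.position), int(r.count), float(r.fdr))
            for r in df.itertuples()
        ]
        return cls(sites, alpha=alpha)


def reads_to_crosslinks(read_records) -> CrosslinkTable:
    """Collapse (chrom, strand, 5'-start, umi) read records to unique-cDNA
    crosslink counts.

    Records with identical (chrom, strand, start, umi) are one cDNA.  The
    crosslink position is the nucleotide immediately 5' of the read start in
    transcript orientation: start-1 on '+', start+1 on '-'.
    """
    seen: set[tuple[str, str, int, str]] = set()
    table = CrosslinkTable()
    for chrom, strand, start, umi in read_records:
        if strand not in STRANDS:
            raise ValueError(f"bad strand {strand!r}")
        key = (chrom, strand, int(start), str(umi))
        if key in seen:
            continue
        seen.add(key)
        pos = start - 1 if strand == "+" else start + 1
        table.add(chrom, strand, pos)
    return table


def _region_fdr(
    positions: np.ndarray,
    counts: np.ndarray,
    length: int,
    n_rand: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """FDR per observed position within one region of ``length`` nt."""
    n_events = int(counts.sum())
    kmax = int(counts.max())
    # null: for each randomization, histogram of per-position stack heights
    null_ge = np.zeros(kmax + 1, dtype=np.float64)  # null_ge[k] = E[#positions >= k]
    for _ in range(n_rand):
        placed = rng.integers(0, length, size=n_events)
        # heights[h] = #positions with stack height h (h = 0 included)
        heights = np.bincount(np.bincount(placed, minlength=length), minlength=kmax + 1)
        ge = np.cumsum(heights[::-1])[::-1]  # ge[k] = #positions with height >= k
        null_ge[1:] += ge[1 : kmax + 1]
    null_ge /= n_rand

    obs_heights = np.bincount(counts, minlength=kmax + 1)
    obs_ge = np.cumsum(obs_heights[::-1])[::-1]

    fdr_by_k = np.ones(kmax + 1)
    for k in range(1, kmax + 1):
        if obs_ge[k] > 0:
            fdr_by_k[k] = min(1.0, null_ge[k] / obs_ge[k])
    # monotonize: FDR non-increasing in count height
    running = np.minimum.accumulate(fdr_by_k)
    return running[counts]


def call_significant_sites(
    xlinks: CrosslinkTable,
    regions: dict[Key, list[Interval]],
    n_rand: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
) -> BindingSiteSet:
    """Randomization-FDR site calling within co-transcribed regions.

    ``regions`` maps (chrom, strand) to interval lists; each interval list
    entry is treated as one randomization universe.  Crosslinks outside every
    region are dropped with a warning.  Sites with FDR < ``alpha`` (strict)
    are retained.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[BindingSite] = []
    n_dropped = 0
    for key in sorted(xlinks.counts):
        chrom, strand = key
        table = xlinks.counts[key]
        ivs = regions.get(key, [])
        for s, e in ivs:
            if e <= s:
                raise ValueError(f"region of length 0 at {chrom}:{s}-{e}")
        assigned: set[int] = set()
        for s, e in sorted(ivs):
            pos = np.array(sorted(p for p in table if s <= p < e), dtype=np.int64)
            if pos.size == 0:
                continue
            assigned.update(pos.tolist())
            cnt = np.array([table[p] for p in pos], dtype=np.int64)
            fdr = _region_fdr(pos, cnt, e - s, n_rand, rng)
            for p, c, f in zip(pos, cnt, fdr):
                if f < alpha:
                    out.append(BindingSite(chrom, strand, int(p), int(c), float(f)))
        n_dropped += sum(1 for p in table if p not in assigned)
    if n_dropped:
        warnings.warn(f"{n_dropped} crosslink positions outside all regions dropped",
                      stacklevel=2)
    out.sort(key=lambda s: (s.chrom, s.strand, s.position))
    return BindingSiteSet(out, alpha=alpha)


def filter_vs_control(
    sites: BindingSiteSet,
    control: CrosslinkTable,
    min_count: int = 2,
) -> BindingSiteSet:
    """Keep sites with count >= min_count and no control crosslink at the
    identical (chrom, strand, position)."""
    kept = [
        s for s in sites.sites
        if s.count >= min_count and control.get(s.chrom, s.strand, s.position) == 0
    ]
    return BindingSiteSet(kept, alpha=sites.alpha)


def site_overlap_fraction(
    a: BindingSiteSet,
    b: BindingSiteSet,
    tolerance_nt: int = 3,
) -> float:
    """Fraction of sites in ``a`` having >= 1 site in ``b`` within
    ``tolerance_nt`` on the same chrom/strand."""
    if tolerance_nt < 0:
        raise ValueError("tolerance_nt must be >= 0")
    if len(a) == 0:
        raise ValueError("undefined fraction: empty site set a")
    b_pos: dict[Key, np.ndarray] = {}
    for s in b.sites:
        b_pos.setdefault((s.chrom, s.strand), []).append(s.position)  # type: ignore[arg-type]
    b_pos = {k: np.array(sorted(v)) for k, v in b_pos.items()}
    hit = 0
    for s in a.sites:
        arr = b_pos.get((s.chrom, s.strand))
        if arr is None or arr.size == 0:
            continue
        i = np.searchsorted(arr, s.position)
        near = []
        if i < arr.size:
            near.append(abs(int(arr[i]) - s.position))
        if i > 0:
            near.append(abs(int(arr[i - 1]) - s.position))
        if near and min(near) <= tolerance_nt:
            hit += 1
    return hit / len(a)
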