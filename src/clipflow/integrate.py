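"""Integrative calls: binding-associated regulated features (SARFs),
trajectory filtering and clustering, detained-intron overlap fractions, and
DEG threshold/overlap statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .genome import FlatFeature


# ---------------------------------------------------------------- SARF

def call_sarfs(
    regulated_features: list[FlatFeature],
    sites,
    window_nt: int = 200,
) -> pd.DataFrame:
    """Flag regulated features with >= 1 site inside the feature interval or
    within ``window_nt`` of either junction anchor (strand-aware).

    Returns a table with feature_id, sarf flag, supporting site positions
    and the window used.
    """
    if window_nt < 0:
        raise ValueError("window_nt must be >= 0")
    site_pos: dict[tuple[str, str], np.ndarray] = {}
    for s in sites:
        site_pos.setdefault((s.chrom, s.strand), []).append(s.position)  # type: ignore[arg-type]
    site_pos = {k: np.array(sorted(v)) for k, v in site_pos.items()}
    rows = []
    for f in regulated_features:
        arr = site_pos.get((f.chrom, f.strand))
        support: list[int] = []
        if arr is not None and arr.size:
            lo, hi = f.start - window_nt, f.end + window_nt
            i, j = np.searchsorted(arr, [lo, hi])
            # anchors are the interval edges; [start-w, end+w) covers both
            # the feature body and the +-window around each anchor
            support = [int(p) for p in arr[i:j]]
        rows.append({
            "feature_id": f.feature_id, "gene_id": f.gene_id, "kind": f.kind,
            "sarf": bool(support),
            "support_positions": ",".join(map(str, support)),
            "window_nt": window_nt,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- trajectories

def lag1_autocorr(values: np.ndarray) -> float:
    """Pearson correlation between consecutive time points.

    Returns nan for zero-variance shifted vectors.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("trajectory shorter than 3")
    a, b = v[:-1], v[1:]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def trajectory_filter(
    trajectories: pd.DataFrame,
    min_autocorr: float = 0.1,
    min_maxfc: float = 0.5,
    max_maxfc: float = 8.5,
) -> pd.DataFrame:
    """Keep trajectories with lag-1 autocorrelation >= min_autocorr and max
    |log2FC| within [min_maxfc, max_maxfc]; zero-variance trajectories are
    dropped.  Input rows are features, columns ordered contrasts."""
    values = trajectories.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise ValueError("trajectory shorter than 3")
    ac = np.array([lag1_autocorr(row) for row in values])
    maxfc = np.abs(values).max(axis=1)
    kept = (~np.isnan(ac)) & (ac >= min_autocorr) & (maxfc >= min_maxfc) & (maxfc <= max_maxfc)
    out = trajectories.copy()
    out["autocorr"] = ac
    out["max_abs_fc"] = maxfc
    out["kept"] = kept
    return out


def cluster_trajectories(
    kept: pd.DataFrame,
    k: int = 20,
    seed: int | None = None,
    n_init: int = 10,
) -> tuple[pd.Series, np.ndarray, float]:
    """K-means (k-means++ init, ``n_init`` restarts) on trajectory vectors.

    Returns (assignments indexed like the input, centroids, inertia).
    """
    value_cols = [c for c in kept.columns if c not in ("autocorr", "max_abs_fc", "kept")]
    X = kept[value_cols].to_numpy(dtype=float)
    if len(X) < k:
        raise ValueError(f"{len(X)} trajectories < k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return (pd.Series(labels, index=kept.index, name="cluster"),
            km.cluster_centers_, float(km.inertia_))


def sarf_cluster_summary(
    assignments: pd.Series,
    sarf_flags: pd.Series,
    top_n: int = 3,
) -> dict:
    """Fraction of SARFs captured by the ``top_n`` SARF-richest clusters and
    the fraction of all clustered features those clusters hold."""
    flags = sarf_flags.reindex(assignments.index)
    if flags.isna().any():
        raise ValueError("sarf flags missing for some clustered features")
    n_sarf = int(flags.sum())
    if n_sarf == 0:
        raise ValueError("undefined summary: zero SARFs")
    per_cluster = flags.groupby(assignments).sum().sort_values(ascending=False)
    top = list(per_cluster.index[:top_n])
    in_top = assignments.isin(top)
    frac_sarf = float(flags[in_top].sum() / n_sarf)
    frac_all = float(in_top.sum() / len(assignments))
    return {
        "top_clusters": top,
        "fraction_sarfs_in_top": frac_sarf,
        "fraction_features_in_top": frac_all,
        "enrichment_ratio": frac_sarf / frac_all if frac_all > 0 else float("nan"),
        "n_sarfs": n_sarf,
        "n_features": int(len(assignments)),
    }


# ---------------------------------------------------------------- detained introns

@dataclass
class DiAnnotation:
    """Intron intervals flagged detained, keyed (chrom, strand, start, end)."""

    intervals: set[tuple[str, str, int, int]]
    source: str = "user"

    def contains(self, feature: FlatFeature) -> bool:
        return (feature.chrom, feature.strand, feature.start, feature.end) in self.intervals


def di_binding_fractions(
    features: list[FlatFeature],
    di: DiAnnotation,
    sites,
    regulated: dict[str, bool],
    sarf: dict[str, bool],
    exon_regulated: dict[str, bool],
    window_nt: int = 200,
) -> dict:
    """Four detained-intron overlap fractions (undefined denominators are
    reported as None, never as 0):

    i.   intronic SARFs that are DIs
    ii.  regulated DIs with >= 1 binding site (inside or within the window)
    iii. non-regulated DIs with >= 1 binding site
    iv.  DI SARFs immediately flanking a regulated exonic part
    """
    intron_feats = [f for f in features if f.kind == "intron"]
    has_site = dict(zip(
        (f.feature_id for f in intron_feats),
        call_sarfs(intron_feats, sites, window_nt=window_nt).sarf,
    ))

    def frac(num: int, den: int):
        return (num / den) if den > 0 else None

    intronic_sarfs = [f for f in intron_feats if sarf.get(f.feature_id, False)]
    di_introns = [f for f in intron_feats if di.contains(f)]
    reg_dis = [f for f in di_introns if regulated.get(f.feature_id, False)]
    nonreg_dis = [f for f in di_introns if not regulated.get(f.feature_id, False)]
    di_sarfs = [f for f in intronic_sarfs if di.contains(f)]

    # adjacency: an exonic part of the same gene sharing a boundary with the DI
    exon_edges: dict[str, list[tuple[int, int, str]]] = {}
    for f in features:
        if f.kind == "exonic_part":
            exon_edges.setdefault(f.gene_id, []).append((f.start, f.end, f.feature_id))

    def flanks_regulated_exon(intron: FlatFeature) -> bool:
        for s, e, fid in exon_edges.get(intron.gene_id, []):
            if (e == intron.start or s == intron.end) and exon_regulated.get(fid, False):
                return True
        return False

    n_flank = sum(flanks_regulated_exon(f) for f in di_sarfs)
    report = {
        "fraction_intronic_sarfs_di": frac(len(di_sarfs), len(intronic_sarfs)),
        "fraction_regulated_di_bound": frac(
            sum(has_site[f.feature_id] for f in reg_dis), len(reg_dis)),
        "fraction_nonregulated_di_bound": frac(
            sum(has_site[f.feature_id] for f in nonreg_dis), len(nonreg_dis)),
        "fraction_di_sarfs_flanking_regulated_exon": frac(n_flank, len(di_sarfs)),
        "counts": {
            "intronic_sarfs": len(intronic_sarfs),
            "di_sarfs": len(di_sarfs),
            "regulated_dis": len(reg_dis),
            "nonregulated_dis": len(nonreg_dis),
            "di_sarfs_flanking_regulated_exon": n_flank,
        },
    }
    return report


# ---------------------------------------------------------------- DEG overlap

def deg_overlap_stats(
    deg: pd.DataFrame,
    fdr_max: float = 0.05,
    min_abs_lfc: float = 1.0,
) -> dict:
    """Threshold a DEG table (fdr < fdr_max strict, |log2FC| >= min_abs_lfc
    inclusive) and report bound/NMD overlap fractions with hypergeometric
    enrichment p-values.

    Expects columns gene_id, log2fc, fdr, bound, nmd_gene, nmd_mrna.
    """
    deg = deg.copy()
    is_deg = (deg.fdr < fdr_max) & (deg.log2fc.abs() >= min_abs_lfc)
    degs = deg[is_deg]
    up = degs[degs.log2fc > 0]
    down = degs[degs.log2fc < 0]

    def frac(num: int, den: int):
        return (num / den) if den > 0 else None

    def hyper_p(population: pd.DataFrame, marker: str, subset: pd.DataFrame):
        # P(X >= k) for drawing len(subset) genes from the population
        M = len(population)
        K = int(population[marker].sum())
        n = len(subset)
        k = int(subset[marker].sum())
        if n == 0:
            return None
        return float(stats.hypergeom.sf(k - 1, M, K, n))

    bound_degs = degs[degs.bound]
    unbound_degs = degs[~degs.bound.astype(bool)]
    report = {
        "n_deg": int(len(degs)),
        "n_up": int(len(up)),
        "n_down": int(len(down)),
        "fraction_bound": frac(int(degs.bound.sum()), len(degs)),
        "fraction_bound_up": frac(int(up.bound.sum()), len(up)),
        "fraction_bound_down": frac(int(down.bound.sum()), len(down)),
        "fraction_bound_deg_nmd_gene": frac(int(bound_degs.nmd_gene.sum()), len(bound_degs)),
        "fraction_unbound_deg_nmd_gene": frac(int(unbound_degs.nmd_gene.sum()), len(unbound_degs)),
        "fraction_bound_deg_nmd_mrna": frac(int(bound_degs.nmd_mrna.sum()), len(bound_degs)),
        "fraction_unbound_deg_nmd_mrna": frac(int(unbound_degs.nmd_mrna.sum()), len(unbound_degs)),
        "p_bound_enrichment": hyper_p(deg, "bound", degs),
        "p_nmd_gene_enrichment": hyper_p(degs, "nmd_gene", bound_degs),
        "p_nmd_mrna_enrichment": hyper_p(degs, "nmd_mrna", bound_degs),
        "counts": {
            "population": int(len(deg)),
            "population_bound": int(deg.bound.sum()),
            "deg_bound": int(degs.bound.sum()),
            "deg_up_bound": int(up.bound.sum()),
            "deg_down_bound": int(down.bound.sum()),
        },
    }
    assert report["n_up"] + report["n_down"] == report["n_deg"] - int((degs.log2fc == 0).sum())
    return report
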