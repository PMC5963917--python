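"""Differential feature-usage testing across an ordered time course.

The differential-usage engine is a beta-binomial likelihood-ratio test on
(feature, gene-rest) count pairs pooled over replicates, with a
method-of-moments overdispersion estimate floored at a configurable minimum.
Features below the minimum-read rule in both contrasted time points are
untestable; testable features get Benjamini-Hochberg FDRs per contrast and
are regulated iff fdr < alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


def vst_log2fc(x: float, y: float, c: float = 1.0) -> float:
    """Pseudocount-stabilised log2 fold change log2((x+c)/(y+c))."""
    if c <= 0:
        raise ValueError("pseudocount must be positive")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    return math.log2((x + c) / (y + c))


@dataclass
class ContrastPlan:
    mode: str  # cumulative | sequential | omnibus
    timepoints: list[str]

    def pairs(self) -> list[tuple[str, str]]:
        tps = self.timepoints
        if len(tps) < 2:
            raise ValueError("need >= 2 timepoints")
        if self.mode == "cumulative":
            return [(t, tps[0]) for t in tps[1:]]
        if self.mode == "sequential":
            return list(zip(tps[1:], tps[:-1]))
        if self.mode == "omnibus":
            return []
        raise ValueError(f"unknown mode {self.mode!r}")


# ------------------------------------------------------------- likelihoods

def _loglik(x: np.ndarray, m: np.ndarray, p: float, rho: float) -> float:
    """Beta-binomial log-likelihood with mean p and intra-class rho; the
    binomial limit is used when rho is (numerically) zero."""
    p = min(max(p, 1e-12), 1 - 1e-12)
    if rho < 1e-8:
        return float(stats.binom.logpmf(x, m, p).sum())
    nu = (1.0 - rho) / rho
    return float(stats.betabinom.logpmf(x, m, p * nu, (1 - p) * nu).sum())


def _fit_p(x: np.ndarray, m: np.ndarray, rho: float) -> tuple[float, float]:
    """MLE of p at fixed rho; returns (p_hat, loglik)."""
    if rho < 1e-8:
        p = x.sum() / m.sum() if m.sum() > 0 else 0.5
        return p, _loglik(x, m, p, rho)
    res = optimize.minimize_scalar(
        lambda p: -_loglik(x, m, p, rho), bounds=(1e-9, 1 - 1e-9), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), -float(res.fun)


def _mom_rho(groups: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Method-of-moments intra-class correlation across replicate groups.

    Uses a pooled chi-square of replicate proportions around each group's
    pooled proportion; E[chi2] = df * (1 + (m_bar - 1) * rho).
    """
    chi2 = 0.0
    df = 0
    msum = 0.0
    nrep = 0
    for x, m in groups:
        tot = m.sum()
        if tot == 0 or len(x) < 2:
            continue
        p = x.sum() / tot
        if p <= 0 or p >= 1:
            continue
        chi2 += float((((x - m * p) ** 2) / (m * p * (1 - p))).sum())
        df += len(x) - 1
        msum += float(m.sum())
        nrep += len(x)
    if df == 0 or nrep == 0:
        return 0.0
    m_bar = msum / nrep
    if m_bar <= 1:
        return 0.0
    rho = (chi2 / df - 1.0) / (m_bar - 1.0)
    return float(min(max(rho, 0.0), 0.5))


def feature_usage_test(
    x_a: np.ndarray,
    rest_a: np.ndarray,
    x_b: np.ndarray,
    rest_b: np.ndarray,
    rho: float | None = None,
    rho_floor: float = 1e-4,
    min_reads: int = 5,
) -> dict:
    """Two-sided test of feature-vs-gene-rest proportion between conditions.

    Counts are per-replicate arrays.  Returns a dict with p_value,
    vst_log2fc (usage-ratio fold change), status, and the rho used.
    ``rho=None`` estimates overdispersion from replicate scatter (floored at
    ``rho_floor``); passing a value pins it (used by the test oracles).
    """
    x_a, rest_a = np.asarray(x_a, dtype=float), np.asarray(rest_a, dtype=float)
    x_b, rest_b = np.asarray(x_b, dtype=float), np.asarray(rest_b, dtype=float)
    m_a, m_b = x_a + rest_a, x_b + rest_b
    lfc = (vst_log2fc(x_a.sum(), rest_a.sum()) - vst_log2fc(x_b.sum(), rest_b.sum()))
    if x_a.sum() < min_reads and x_b.sum() < min_reads:
        return {"p_value": None, "vst_log2fc": lfc, "status": "untestable", "rho": None}
    if rest_a.sum() == 0 or rest_b.sum() == 0:
        return {"p_value": None, "vst_log2fc": lfc, "status": "untestable", "rho": None}
    if rho is None:
        rho = max(_mom_rho([(x_a, m_a), (x_b, m_b)]), rho_floor)
    x = np.concatenate([x_a, x_b])
    m = np.concatenate([m_a, m_b])
    _, ll0 = _fit_p(x, m, rho)
    _, ll_a = _fit_p(x_a, m_a, rho)
    _, ll_b = _fit_p(x_b, m_b, rho)
    lrt = max(0.0, 2.0 * (ll_a + ll_b - ll0))
    p_value = float(stats.chi2.sf(lrt, df=1))
    return {"p_value": p_value, "vst_log2fc": lfc, "status": "testable", "rho": rho}


def omnibus_usage_test(
    xs: list[np.ndarray],
    rests: list[np.ndarray],
    rho: float | None = None,
    rho_floor: float = 1e-4,
    min_reads: int = 5,
) -> dict:
    """Any-effect-of-timepoint test: free proportion per timepoint vs one
    shared proportion (df = T - 1)."""
    xs = [np.asarray(x, dtype=float) for x in xs]
    rests = [np.asarray(r, dtype=float) for r in rests]
    ms = [x + r for x, r in zip(xs, rests)]
    if all(x.sum() < min_reads for x in xs) or any(r.sum() == 0 for r in rests):
        return {"p_value": None, "status": "untestable", "rho": None}
    if rho is None:
        rho = max(_mom_rho(list(zip(xs, ms))), rho_floor)
    x_all, m_all = np.concatenate(xs), np.concatenate(ms)
    _, ll0 = _fit_p(x_all, m_all, rho)
    ll1 = sum(_fit_p(x, m, rho)[1] for x, m in zip(xs, ms))
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p_value = float(stats.chi2.sf(lrt, df=len(xs) - 1))
    return {"p_value": p_value, "status": "testable", "rho": rho}


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def classify_features(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Add BH fdr (over testable features only) and regulated/unregulated/
    untestable status to a per-contrast result table with a p_value column."""
    results = results.copy()
    testable = results.p_value.notna()
    fdr = np.full(len(results), np.nan)
    if testable.any():
        fdr[testable.to_numpy()] = bh_fdr(results.loc[testable, "p_value"].to_numpy())
    results["fdr"] = fdr
    status = np.where(~testable, "untestable",
                      np.where(fdr < alpha, "regulated", "unregulated"))
    results["status"] = status
    return results


# ------------------------------------------------------------- table-level API

def _group_columns(df: pd.DataFrame, timepoint: str, prefix: str) -> list[str]:
    cols = [c for c in df.columns if c.startswith(f"{prefix}_{timepoint}_")]
    if not cols:
        raise KeyError(f"no {prefix} columns for timepoint {timepoint}")
    return cols


def run_contrasts(
    features: pd.DataFrame,
    plan: ContrastPlan,
    alpha: float = 0.05,
    rho_floor: float = 1e-4,
    min_reads: int = 5,
) -> dict:
    """Run every contrast of a plan over a wide feature-count table.

    ``features`` must have feature_id/gene_id/kind columns plus
    ``count_<tp>_<rep>`` and ``rest_<tp>_<rep>`` count columns.  Returns
    per-contrast classified tables, a summary of regulated counts, and a
    trajectory matrix of usage vst-log2fc per contrast.
    """
    meta_cols = ["feature_id", "gene_id", "kind"]
    if plan.mode == "omnibus":
        rows = []
        tps = plan.timepoints
        for r in features.itertuples():
            xs = [np.array([getattr(r, c) for c in _group_columns(features, tp, "count")])
                  for tp in tps]
            rests = [np.array([getattr(r, c) for c in _group_columns(features, tp, "rest")])
                     for tp in tps]
            res = omnibus_usage_test(xs, rests, rho_floor=rho_floor, min_reads=min_reads)
            rows.append({"feature_id": r.feature_id, "p_value": res["p_value"]})
        table = classify_features(pd.DataFrame(rows), alpha=alpha)
        table = features[meta_cols].merge(table, on="feature_id")
        return {"contrasts": {"omnibus": table},
                "summary": pd.DataFrame([{
                    "contrast": "omnibus",
                    "n_regulated": int((table.status == "regulated").sum()),
                    "n_unregulated": int((table.status == "unregulated").sum()),
                    "n_untestable": int((table.status == "untestable").sum()),
                }]),
                "trajectories": None}

    contrasts: dict[str, pd.DataFrame] = {}
    summary_rows = []
    traj: dict[str, list[float]] = {fid: [] for fid in features.feature_id}
    for t_num, t_den in plan.pairs():
        name = f"{t_num}_vs_{t_den}"
        cols_xa = _group_columns(features, t_num, "count")
        cols_ra = _group_columns(features, t_num, "rest")
        cols_xb = _group_columns(features, t_den, "count")
        cols_rb = _group_columns(features, t_den, "rest")
        rows = []
        for r in features.itertuples():
            res = feature_usage_test(
                np.array([getattr(r, c) for c in cols_xa]),
                np.array([getattr(r, c) for c in cols_ra]),
                np.array([getattr(r, c) for c in cols_xb]),
                np.array([getattr(r, c) for c in cols_rb]),
                rho_floor=rho_floor, min_reads=min_reads,
            )
            rows.append({"feature_id": r.feature_id, "p_value": res["p_value"],
                         "vst_log2fc": res["vst_log2fc"]})
            traj[r.feature_id].append(res["vst_log2fc"])
        table = classify_features(pd.DataFrame(rows), alpha=alpha)
        table = features[meta_cols].merge(table, on="feature_id")
        contrasts[name] = table
        summary_rows.append({
            "contrast": name,
            "n_regulated": int((table.status == "regulated").sum()),
            "n_unregulated": int((table.status == "unregulated").sum()),
            "n_untestable": int((table.status == "untestable").sum()),
        })
    traj_df = pd.DataFrame.from_dict(traj, orient="index",
                                     columns=[f"{a}_vs_{b}" for a, b in plan.pairs()])
    traj_df.index.name = "feature_id"
    return {"contrasts": contrasts, "summary": pd.DataFrame(summary_rows),
            "trajectories": traj_df}
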