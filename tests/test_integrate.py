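import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from sklearn.metrics import adjusted_rand_score

from clipflow.crosslinks import BindingSite, BindingSiteSet
from clipflow.genome import FlatFeature
from clipflow.integrate import (
    DiAnnotation,
    call_sarfs,
    cluster_trajectories,
    deg_overlap_stats,
    di_binding_fractions,
    lag1_autocorr,
    sarf_cluster_summary,
    trajectory_filter,
)


def _feat(fid, start, end, kind="junction", strand="+", gene="g1"):
    return FlatFeature(fid, gene, kind, "chr1", start, end, strand)


def _sites(positions, strand="+"):
    return BindingSiteSet([BindingSite("chr1", strand, p, 2, 0.01) for p in positions])


class TestCallSarfs:
    def test_site_within_window_downstream(self):
        out = call_sarfs([_feat("f1", 1000, 1200)], _sites([1350]), window_nt=200)
        assert bool(out.sarf.iloc[0])

    def test_site_beyond_window(self):
        out = call_sarfs([_feat("f1", 1000, 1200)], _sites([1450]), window_nt=200)
        assert not bool(out.sarf.iloc[0])

    def test_site_inside_feature(self):
        out = call_sarfs([_feat("f1", 1000, 5000, kind="intron")], _sites([3000]),
                         window_nt=0)
        assert bool(out.sarf.iloc[0])

    def test_strand_aware(self):
        out = call_sarfs([_feat("f1", 1000, 1200)], _sites([1100], strand="-"))
        assert not bool(out.sarf.iloc[0])

    def test_brute_force_equivalence_random(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            window = int(rng.integers(0, 300))
            feats = []
            for i in range(rng.integers(1, 15)):
                s = int(rng.integers(0, 5000))
                e = s + int(rng.integers(1, 400))
                strand = "+" if rng.random() < 0.5 else "-"
                feats.append(_feat(f"f{i}", s, e, strand=strand))
            positions = rng.integers(0, 5500, size=rng.integers(0, 25))
            strands = ["+" if rng.random() < 0.5 else "-" for _ in positions]
            sites = BindingSiteSet([
                BindingSite("chr1", st, int(p), 2, 0.01)
                for p, st in zip(positions, strands)
            ])
            out = call_sarfs(feats, sites, window_nt=window)
            called = set(out[out.sarf].feature_id)
            brute = {
                f.feature_id
                for f in feats
                for s in sites
                if s.strand == f.strand and s.chrom == f.chrom
                and f.start - window <= s.position < f.end + window
            }
            assert called == brute, f"trial {trial}"


class TestTrajectoryFilter:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=[f"c{i}" for i in range(len(rows[0]))])

    def test_all_zero_dropped(self):
        out = trajectory_filter(self._df([[0.0, 0.0, 0.0, 0.0, 0.0]]))
        assert not out.kept.iloc[0]

    def test_increasing_kept(self):
        traj = [0.2, 0.6, 1.2, 2.0, 3.0]
        out = trajectory_filter(self._df([traj]))
        # hand lag-1 Pearson: corr([.2,.6,1.2,2.0],[.6,1.2,2.0,3.0])
        a, b = np.array(traj[:-1]), np.array(traj[1:])
        hand = float(np.corrcoef(a, b)[0, 1])
        assert out.autocorr.iloc[0] == pytest.approx(hand)
        assert hand > 0.1
        assert out.kept.iloc[0]

    def test_alternating_dropped(self):
        out = trajectory_filter(self._df([[1.0, -1.0, 1.0, -1.0, 1.0]]))
        assert out.autocorr.iloc[0] == pytest.approx(-1.0)
        assert not out.kept.iloc[0]

    def test_excessive_fc_dropped(self):
        out = trajectory_filter(self._df([[1.0, 2.0, 4.0, 6.0, 9.0]]))
        assert not out.kept.iloc[0]

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            trajectory_filter(self._df([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="shorter"):
            lag1_autocorr(np.array([1.0, 2.0]))


class TestClusterTrajectories:
    def _two_groups(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        a = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        b = -a
        rows, labels = [], []
        for i in range(n):
            truth = i % 2
            base = a if truth == 0 else b
            rows.append(base + rng.normal(0, 0.1, size=5))
            labels.append(truth)
        df = pd.DataFrame(rows, columns=[f"c{i}" for i in range(5)],
                          index=[f"f{i}" for i in range(n)])
        return df, labels

    def test_separated_groups_ari_one(self):
        df, labels = self._two_groups()
        assign, centroids, inertia = cluster_trajectories(df, k=2, seed=1)
        assert adjusted_rand_score(labels, assign.to_numpy()) == 1.0
        assert centroids.shape == (2, 5)
        assert inertia >= 0

    def test_seed_determinism(self):
        df, _ = self._two_groups()
        a1, _, _ = cluster_trajectories(df, k=4, seed=9)
        a2, _, _ = cluster_trajectories(df, k=4, seed=9)
        assert (a1 == a2).all()

    def test_k_exceeds_n(self):
        df, _ = self._two_groups(n=10)
        with pytest.raises(ValueError):
            cluster_trajectories(df, k=11, seed=0)


class TestSarfClusterSummary:
    def test_all_sarfs_one_cluster(self):
        assignments = pd.Series([0] * 10 + [1] * 45 + [2] * 45,
                                index=[f"f{i}" for i in range(100)])
        flags = pd.Series([True] * 10 + [False] * 90,
                          index=[f"f{i}" for i in range(100)])
        out = sarf_cluster_summary(assignments, flags, top_n=1)
        assert out["fraction_sarfs_in_top"] == 1.0
        assert out["fraction_features_in_top"] == pytest.approx(0.10)
        assert out["enrichment_ratio"] == pytest.approx(10.0)

    def test_uniform_sarfs_fraction_topn_over_k(self):
        k, per = 10, 30
        assignments = pd.Series(np.repeat(np.arange(k), per),
                                index=[f"f{i}" for i in range(k * per)])
        flags = pd.Series(
            [i % per < 3 for i in range(k * per)],
            index=assignments.index,
        )  # 3 SARFs in every cluster
        out = sarf_cluster_summary(assignments, flags, top_n=3)
        assert out["fraction_sarfs_in_top"] == pytest.approx(3 / k)
        assert out["fraction_features_in_top"] == pytest.approx(3 / k)

    def test_zero_sarfs_undefined(self):
        assignments = pd.Series([0, 1], index=["a", "b"])
        flags = pd.Series([False, False], index=["a", "b"])
        with pytest.raises(ValueError, match="undefined"):
            sarf_cluster_summary(assignments, flags)


class TestDiBindingFractions:
    def _fixture(self):
        # gene with exonic parts flanking two introns
        feats = [
            _feat("e1", 0, 100, kind="exonic_part"),
            _feat("i1", 100, 600, kind="intron"),
            _feat("e2", 600, 700, kind="exonic_part"),
            _feat("i2", 700, 1200, kind="intron"),
            _feat("e3", 1200, 1300, kind="exonic_part"),
            _feat("i3", 1300, 1800, kind="intron"),
            _feat("i4", 1900, 2400, kind="intron"),
        ]
        di = DiAnnotation({("chr1", "+", 100, 600), ("chr1", "+", 700, 1200),
                           ("chr1", "+", 1300, 1800), ("chr1", "+", 1900, 2400)})
        return feats, di

    def test_regulated_di_bound_fraction(self):
        feats, di = self._fixture()
        sites = _sites([300, 800])  # inside i1 and i2
        regulated = {"i1": True, "i2": True, "i3": True, "i4": True}
        out = di_binding_fractions(feats, di, sites, regulated, {}, {}, window_nt=0)
        assert out["fraction_regulated_di_bound"] == pytest.approx(2 / 4)

    def test_zero_denominator_undefined(self):
        feats, di = self._fixture()
        out = di_binding_fractions(feats, di, _sites([]),
                                   {f.feature_id: True for f in feats}, {}, {})
        assert out["fraction_nonregulated_di_bound"] is None
        assert out["fraction_intronic_sarfs_di"] is None

    def test_flanking_regulated_exon(self):
        feats, di = self._fixture()
        sarf = {"i1": True}
        # i1 flanks e1 (unregulated) and e2 (regulated) -> counts as flanking
        out = di_binding_fractions(feats, di, _sites([300]), {}, sarf,
                                   {"e2": True, "e1": False})
        assert out["fraction_di_sarfs_flanking_regulated_exon"] == 1.0

    def test_intronic_sarf_di_fraction(self):
        feats, di = self._fixture()
        sarf = {"i1": True, "i2": True}
        di_small = DiAnnotation({("chr1", "+", 100, 600)})
        out = di_binding_fractions(feats, di_small, _sites([300, 800]), {}, sarf, {})
        assert out["fraction_intronic_sarfs_di"] == pytest.approx(0.5)


class TestDegOverlap:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2fc", "fdr", "bound",
                                           "nmd_gene", "nmd_mrna"])

    def test_bound_fraction_hand_count(self):
        rows = []
        for i in range(10):
            rows.append((f"g{i}", 2.0, 0.01, i < 4, False, False))
        out = deg_overlap_stats(self._table(rows))
        assert out["n_deg"] == 10
        assert out["fraction_bound"] == pytest.approx(0.40)

    def test_threshold_boundaries(self):
        rows = [
            ("g1", 1.0, 0.049, False, False, False),  # included: |lfc| == 1
            ("g2", 2.0, 0.05, False, False, False),   # excluded: fdr not < 0.05
            ("g3", 0.99, 0.01, False, False, False),  # excluded: |lfc| < 1
            ("g4", -1.0, 0.01, False, False, False),  # included (down)
        ]
        out = deg_overlap_stats(self._table(rows))
        assert out["n_deg"] == 2
        assert out["n_up"] == 1 and out["n_down"] == 1

    def test_hypergeometric_exact_oracle(self):
        # population 20 genes, 10 bound; the 5 DEGs are all bound
        rows = []
        for i in range(20):
            is_deg = i < 5
            rows.append((f"g{i}", 2.0 if is_deg else 0.0,
                         0.01 if is_deg else 0.9, i < 10, False, False))
        out = deg_overlap_stats(self._table(rows))
        oracle = comb(10, 5, exact=True) / comb(20, 5, exact=True)
        assert oracle == pytest.approx(0.0163, abs=1e-4)
        assert out["p_bound_enrichment"] == pytest.approx(oracle, rel=1e-12)

    def test_direction_split_sums(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"g{i}", float(rng.normal(0, 2)), float(rng.uniform(0, 0.2)),
             bool(rng.random() < 0.5), bool(rng.random() < 0.3),
             bool(rng.random() < 0.3))
            for i in range(200)
        ]
        out = deg_overlap_stats(self._table(rows))
        assert out["n_up"] + out["n_down"] == out["n_deg"]

    def test_fractions_in_unit_interval(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"g{i}", float(rng.normal(0, 2)), float(rng.uniform()),
             bool(rng.random() < 0.5), bool(rng.random() < 0.3),
             bool(rng.random() < 0.3))
            for i in range(100)
        ]
        out = deg_overlap_stats(self._table(rows))
        for key, value in out.items():
            if key.startswith("fraction") and value is not None:
                assert 0.0 <= value <= 1.0
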