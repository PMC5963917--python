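import numpy as np
import pytest

from clipflow.genome import flatten_features
from clipflow.simulate import (
    SimulationConfig,
    generate_genome,
    simulate_deg_table,
    simulate_iclip,
    simulate_timecourse,
)


class TestGenerateGenome:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=11, n_genes=8)
        a_ann, a_truth = generate_genome(cfg)
        b_ann, b_truth = generate_genome(cfg)
        assert a_ann.chromosomes == b_ann.chromosomes
        assert a_truth.planted_sites == b_truth.planted_sites
        assert a_truth.di_introns == b_truth.di_introns

    def test_empty_simulation_rejected(self):
        with pytest.raises(ValueError, match="empty simulation"):
            generate_genome(SimulationConfig(n_genes=0))

    def test_zero_di_fraction(self):
        _, truth = generate_genome(SimulationConfig(seed=2, di_fraction=0.0))
        assert truth.di_introns == []

    def test_di_count_reproducible_and_plausible(self):
        cfg = SimulationConfig(seed=3, di_fraction=0.5)
        ann, truth = generate_genome(cfg)
        n_introns = sum(
            len({iv for t in g.transcripts for iv in t.introns()}) for g in ann.genes
        )
        n_di = len(truth.di_introns)
        # binomial(n, 0.5): allow 4 sigma around the mean
        sd = np.sqrt(n_introns * 0.25)
        assert abs(n_di - 0.5 * n_introns) <= 4 * sd
        _, truth2 = generate_genome(cfg)
        assert len(truth2.di_introns) == n_di

    def test_motif_planted_in_sequence(self):
        cfg = SimulationConfig(seed=4)
        ann, truth = generate_genome(cfg)
        motif_dna = cfg.motif.replace("U", "T")
        rc = motif_dna.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        for site in truth.planted_sites:
            seq = ann.chromosomes[site["chrom"]]
            if site["strand"] == "+":
                # motif sits 8 nt transcript-downstream of the crosslink site
                start = site["position"] + 8
                assert seq[start : start + 5] == motif_dna
            else:
                end = site["position"] - 7
                assert seq[end - 5 : end] == rc

    def test_planted_sites_inside_genes(self):
        ann, truth = generate_genome(SimulationConfig(seed=5))
        spans = {g.gene_id: (g.chrom, g.strand, g.span) for g in ann.genes}
        for site in truth.planted_sites:
            chrom, strand, (s, e) = spans[site["gene_id"]]
            assert chrom == site["chrom"] and strand == site["strand"]
            assert s <= site["position"] < e


class TestSimulateIclip:
    def test_invalid_ratio(self):
        cfg = SimulationConfig(seed=1, signal_to_background=0.5)
        ann, truth = generate_genome(SimulationConfig(seed=1))
        with pytest.raises(ValueError, match="signal_to_background"):
            simulate_iclip(ann, truth, cfg)

    def test_planted_rate_scaling(self, default_sim):
        sim = default_sim
        cfg, truth, signal = sim["config"], sim["truth"], sim["signal"]
        planted = truth.planted_positions()
        planted_mean = np.mean([signal.get(c, s, p) for c, s, p in planted])
        expected = cfg.signal_to_background * cfg.background_rate
        # Poisson mean with n=20: 4 sigma tolerance
        assert abs(planted_mean - expected) <= 4 * np.sqrt(expected / len(planted))

    def test_control_has_no_excess_at_planted(self, default_sim):
        sim = default_sim
        cfg, truth, control = sim["config"], sim["truth"], sim["control"]
        planted = truth.planted_positions()
        control_mean = np.mean([control.get(c, s, p) for c, s, p in planted])
        assert control_mean <= cfg.background_rate + 4 * np.sqrt(
            cfg.background_rate / len(planted)
        )

    def test_counts_positive_integers(self, default_sim):
        df = default_sim["signal"].to_frame()
        assert (df["count"] >= 1).all()
        assert df["count"].dtype.kind == "i"

    def test_background_rate_chi_square(self):
        # marginal goodness of fit of background counts vs Poisson(rate)
        from scipy import stats

        cfg = SimulationConfig(seed=9, n_genes=20, n_planted_sites=0)
        ann, truth = generate_genome(cfg)
        signal, _ = simulate_iclip(ann, truth, cfg)
        from clipflow.genome import cotranscribed_region

        counts = []
        for gene in ann.genes:
            for s, e in cotranscribed_region(gene):
                for p in range(s, e):
                    counts.append(signal.get(gene.chrom, gene.strand, p))
        counts = np.array(counts)
        observed = np.bincount(counts, minlength=5)[:5]
        n = len(counts)
        probs = stats.poisson.pmf(np.arange(4), cfg.background_rate)
        expected = np.append(probs * n, n * stats.poisson.sf(3, cfg.background_rate))
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=4)
        assert p > 0.01


class TestSimulateTimecourse:
    def test_too_few_timepoints(self):
        cfg = SimulationConfig(seed=1, timepoints=("MEF",))
        ann, truth = generate_genome(SimulationConfig(seed=1))
        with pytest.raises(ValueError, match="timepoints"):
            simulate_timecourse(ann, truth, cfg)

    def test_constant_psi_binomial_ci(self):
        cfg = SimulationConfig(seed=6, frac_events_changing=0.0, event_depth=1000,
                               n_events=100)
        ann, truth = generate_genome(cfg)
        events, _ = simulate_timecourse(ann, truth, cfg)
        ok = 0
        for row in events.itertuples():
            true_psi = truth.event_psi[row.event_id][0]
            inc = sum(getattr(row, f"inc_{tp}_1") for tp in cfg.timepoints)
            exc = sum(getattr(row, f"exc_{tp}_1") for tp in cfg.timepoints)
            if abs(inc / (inc + exc) - true_psi) <= 0.05:
                ok += 1
        assert ok >= 95

    def test_planted_cluster_rise(self, default_sim):
        cfg = default_sim["config"]
        ann, truth = generate_genome(cfg)
        _, features = simulate_timecourse(ann, truth, cfg)
        shapes = truth.traj_shapes
        from clipflow.usage import vst_log2fc

        last_tp, first_tp = cfg.timepoints[-1], cfg.timepoints[0]
        for group in range(len(shapes)):
            fids = [f for f, c in truth.feature_cluster.items() if c == group]
            if not fids:
                continue
            sub = features[features.feature_id.isin(fids)]
            lfcs = [
                vst_log2fc(r, l)
                for r, l in zip(sub[f"count_{last_tp}_1"], sub[f"count_{first_tp}_1"])
            ]
            expected = shapes[group][-1] - shapes[group][0]
            assert np.mean(lfcs) == pytest.approx(expected, abs=0.5)

    def test_zero_depth_event_zero_counts(self):
        # depth is Poisson; with event_depth 0 every draw is zero
        cfg = SimulationConfig(seed=7, event_depth=0, n_events=10)
        ann, truth = generate_genome(cfg)
        events, _ = simulate_timecourse(ann, truth, cfg)
        count_cols = [c for c in events.columns if c.startswith(("inc_", "exc_"))]
        assert (events[count_cols].to_numpy() == 0).all()

    def test_bound_features_reference_annotation(self, default_sim):
        cfg = default_sim["config"]
        ann, truth = generate_genome(cfg)
        simulate_timecourse(ann, truth, cfg)
        fids = {f.feature_id for f in flatten_features(ann)}
        assert set(truth.feature_bound) == fids
        assert set(truth.feature_cluster) == fids


class TestSimulateDeg:
    def test_zero_effects_no_pass(self):
        cfg = SimulationConfig(seed=1, deg_fraction=0.0)
        ann, truth = generate_genome(cfg)
        deg = simulate_deg_table(ann, truth, cfg)
        passing = deg[(deg.fdr < 0.05) & (deg.log2fc.abs() >= 1)]
        assert len(passing) == 0

    def test_planted_effects_pass_exactly(self):
        base = SimulationConfig(seed=1)
        ann, truth = generate_genome(base)
        chosen = [g.gene_id for g in ann.genes[:10]]
        cfg = SimulationConfig(seed=1, deg_fraction=0.0,
                               deg_effects={g: (2.0, 0.01) for g in chosen})
        deg = simulate_deg_table(ann, truth, cfg)
        passing = deg[(deg.fdr < 0.05) & (deg.log2fc.abs() >= 1)]
        assert sorted(passing.gene_id) == sorted(chosen)

    def test_bound_flag_consistency(self, default_sim):
        cfg = default_sim["config"]
        ann, truth = generate_genome(cfg)
        deg = simulate_deg_table(ann, truth, cfg)
        bound_genes = {s["gene_id"] for s in truth.planted_sites}
        assert set(deg[deg.bound].gene_id) == bound_genes
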