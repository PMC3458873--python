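"""Island-model null simulation, calibration, envelopes and outlier classification."""

import numpy as np
import msprime
import pytest

from clinescan.datasets import ClineDataset, Locus, PopulationSite
from clinescan.fst_outlier import (
    FstOutlierClassifier,
    IslandNullConfig,
    build_null_envelope,
    classify_fst_outliers,
    infinite_alleles_partition,
    island_fst_closed_form,
    simulate_island_genealogy,
    simulate_island_pairs,
)
from clinescan.stats import expected_heterozygosity, wc_fst


class TestConfig:
    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError):
            IslandNullConfig(target_fst=0.0)

    def test_replicate_floor_for_envelopes(self):
        with pytest.raises(ValueError):
            IslandNullConfig(n_replicates=500)

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            IslandNullConfig(n_demes_total=5, n_demes_sampled=11)

    def test_closed_form_inversion_brackets_target(self):
        # the infinite-island closed form provides the calibration start
        d = 100
        four_n_m = (1 / 0.33 - 1) / (d / (d - 1)) ** 2
        assert island_fst_closed_form(four_n_m, d) == pytest.approx(0.33, abs=1e-12)


class TestCoalescentCore:
    def test_genealogy_is_a_binary_tree(self):
        rng = np.random.default_rng(0)
        parent, times = simulate_island_genealogy(10, 100.0, 1e-3, 4, 3, rng)
        n_samples = 12
        assert len(parent) == 2 * n_samples - 1
        assert np.sum(parent == -1) == 1  # single root
        assert np.all(np.diff(times[n_samples:]) >= 0)  # coalescences in time order
        counts = np.bincount(parent[parent >= 0])
        assert np.all(counts[counts > 0] == 2)

    def test_zero_mutation_rate_is_monomorphic(self):
        rng = np.random.default_rng(1)
        parent, times = simulate_island_genealogy(10, 100.0, 1e-3, 4, 3, rng)
        alleles = infinite_alleles_partition(parent, times, 0.0, 12, rng)
        assert len(np.unique(alleles)) == 1

    def test_agrees_with_independent_coalescent_simulator(self):
        # same small island model run through msprime with infinite-alleles
        # mutations: mean FST and He must agree within Monte-Carlo error
        d, ne, m_total, copies, k = 8, 300.0, 2e-3, 10, 4
        cfg = IslandNullConfig(
            n_demes_total=d,
            n_demes_sampled=k,
            sample_individuals_per_deme=copies // 2,
            ne_per_deme=ne,
            theta_range=(0.5, 0.5),
            n_replicates=1000,
            seed=1,
        )
        ours = simulate_island_pairs(cfg, m_total, 1200, seed=5)

        dem = msprime.Demography.island_model([ne] * d, migration_rate=m_total / (d - 1))
        samples = {f"pop_{i}": copies for i in range(k)}
        mu = 0.5 / (4 * d * ne)
        fsts, hes = [], []
        reps = msprime.sim_ancestry(
            samples=samples, demography=dem, ploidy=1, sequence_length=1,
            num_replicates=1800, random_seed=7,
        )
        for i, ts in enumerate(reps):
            mts = msprime.sim_mutations(
                ts, rate=mu, model=msprime.InfiniteAlleles(), random_seed=1000 + i
            )
            var = next(mts.variants(), None)
            if var is None:
                continue
            g = var.genotypes
            if len(np.unique(g)) < 2:
                continue
            pop = mts.tables.nodes.population[mts.samples()]
            kk = g.max() + 1
            counts = np.stack([np.bincount(g[pop == dd], minlength=kk) for dd in range(k)])
            f = wc_fst(counts)
            if np.isnan(f):
                continue
            fsts.append(f)
            hes.append(expected_heterozygosity(counts.sum(0) / counts.sum()))
        se = np.hypot(ours["fst"].std() / np.sqrt(len(ours)), np.std(fsts) / np.sqrt(len(fsts)))
        assert ours["fst"].mean() == pytest.approx(np.mean(fsts), abs=4 * se + 0.005)
        assert ours["he"].mean() == pytest.approx(np.mean(hes), abs=0.03)

    def test_panmixia_limit_fst_vanishes(self):
        cfg = IslandNullConfig(
            n_demes_total=10,
            n_demes_sampled=5,
            sample_individuals_per_deme=2,
            ne_per_deme=100.0,
            theta_range=(1.0, 1.0),
            n_replicates=1000,
            seed=2,
        )
        pairs = simulate_island_pairs(cfg, m_total=1.0, n_replicates=400, seed=9)
        assert pairs["fst"].mean() < 0.02

    def test_isolation_limit_fst_high(self):
        cfg = IslandNullConfig(
            n_demes_total=10,
            n_demes_sampled=3,
            sample_individuals_per_deme=5,
            ne_per_deme=50.0,
            theta_range=(5.0, 5.0),
            n_replicates=1000,
            seed=3,
        )
        pairs = simulate_island_pairs(cfg, m_total=1e-5, n_replicates=200, seed=11)
        assert pairs["fst"].mean() > 0.6


class TestCalibration:
    def test_mean_fst_hits_target(self, island_null):
        cfg, m, pairs = island_null
        assert pairs["fst"].mean() == pytest.approx(cfg.target_fst, abs=0.01)

    def test_null_spans_heterozygosity_axis(self, island_null):
        _, _, pairs = island_null
        assert pairs["he"].quantile(0.05) < 0.1
        assert pairs["he"].quantile(0.95) > 0.6


class TestEnvelope:
    def test_heldout_coverage_near_nominal(self, island_null):
        _, _, pairs = island_null
        build = pairs.iloc[:4000]
        hold = pairs.iloc[4000:]
        env = build_null_envelope(build)
        bins = np.clip(
            np.searchsorted(env.bin_edges, hold["he"], side="right") - 1,
            0,
            len(env.curves) - 1,
        )
        lo = env.curves["q_lo95"].to_numpy()[bins]
        hi = env.curves["q_hi95"].to_numpy()[bins]
        inside = ((hold["fst"] >= lo) & (hold["fst"] <= hi)).mean()
        assert inside == pytest.approx(0.95, abs=0.025)

    def test_quantile_monotonicity_per_bin(self, null_envelope):
        c = null_envelope.curves
        assert np.all(c["q_lo99"] <= c["q_lo95"] + 1e-12)
        assert np.all(c["q_lo95"] <= c["median"] + 1e-12)
        assert np.all(c["median"] <= c["q_hi95"] + 1e-12)
        assert np.all(c["q_hi95"] <= c["q_hi99"] + 1e-12)

    def test_envelope_stable_under_fewer_replicates(self, island_null):
        # scaled version of the replicate-stability property: curves from
        # the full 5,000 pairs vs a 2,000-pair subsample
        _, _, pairs = island_null
        full = build_null_envelope(pairs)
        sub = build_null_envelope(pairs.sample(2000, random_state=0))
        # compare on the common He midpoints via interpolation
        for col in ("median", "q_hi95"):
            a = np.interp(
                full.curves["he_mid"], sub.curves["he_mid"], sub.curves[col]
            )
            assert np.max(np.abs(a - full.curves[col])) < 0.08

    def test_too_few_pairs_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            build_null_envelope(pd.DataFrame({"he": [0.1] * 10, "fst": [0.1] * 10}))


def _dataset_from_counts(count_list):
    n_demes = len(count_list[0])
    sites = [PopulationSite(f"d{i}", float(i + 1)) for i in range(n_demes)]
    loci = []
    counts = {}
    for j, c in enumerate(count_list):
        c = np.asarray(c)
        loci.append(Locus(f"L{j}", "simulated", tuple(str(a + 1) for a in range(c.shape[1]))))
        counts[f"L{j}"] = c
    return ClineDataset(sites, loci, counts)


class TestClassification:
    def test_planted_extreme_locus_detected_at_99(self, null_envelope):
        # 11 demes fixed for alternative alleles at the two ends: maximal
        # FST for its heterozygosity
        planted = np.array([[40, 0]] * 6 + [[0, 40]] * 5)
        ds = _dataset_from_counts([planted])
        out = classify_fst_outliers(ds, null_envelope)
        assert bool(out["outlier_high_99"].iloc[0])
        assert out["empirical_p"].iloc[0] < 0.01

    def test_null_data_calibrated_rates(self, island_null, null_envelope):
        # fresh draws from the null itself: ~2.5% above the 95% envelope,
        # empirical p-values centred on 0.5
        cfg, m, _ = island_null
        fresh = simulate_island_pairs(cfg, m, 800, seed=999)
        null_he = null_envelope.pairs["he"].to_numpy()
        null_fst = null_envelope.pairs["fst"].to_numpy()
        bins = np.clip(
            np.searchsorted(null_envelope.bin_edges, fresh["he"], side="right") - 1,
            0,
            len(null_envelope.curves) - 1,
        )
        hi = null_envelope.curves["q_hi95"].to_numpy()[bins]
        rate = float((fresh["fst"].to_numpy() > hi).mean())
        assert rate == pytest.approx(0.025, abs=0.015)

    def test_median_locus_is_unremarkable(self, null_envelope):
        # a locus sitting exactly on the conditional median draws p ~ 0.5
        b = len(null_envelope.curves) // 2
        med = null_envelope.curves["median"].iloc[b]
        sub = null_envelope.pairs
        # pick an actual null pair closest to the bin median
        bins = np.clip(
            np.searchsorted(null_envelope.bin_edges, sub["he"], side="right") - 1,
            0,
            len(null_envelope.curves) - 1,
        )
        cand = sub[(bins == b)]
        row = cand.iloc[(cand["fst"] - med).abs().argmin()]
        he, fst = row["he"], row["fst"]
        sel = cand["fst"].to_numpy()
        p = (sel >= fst).mean()
        assert p == pytest.approx(0.5, abs=0.1)

    def test_monomorphic_loci_skipped(self, null_envelope):
        ds = _dataset_from_counts([[[40, 0]] * 11])
        out = classify_fst_outliers(ds, null_envelope)
        assert len(out) == 0


class TestEstimator:
    def test_fit_from_cached_pairs_and_roundtrip(self, island_null, tmp_path):
        cfg, m, pairs = island_null
        clf = FstOutlierClassifier(
            n_replicates=cfg.n_replicates, seed=cfg.seed
        ).fit(null_pairs=pairs)
        clf.config_ = cfg
        clf.save_null(tmp_path / "null.csv")
        clf2 = FstOutlierClassifier(n_replicates=cfg.n_replicates, seed=cfg.seed)
        clf2.load_null(tmp_path / "null.csv")
        assert clf2.mean_null_fst_ == pytest.approx(clf.mean_null_fst_)

    def test_cache_config_mismatch_rejected(self, island_null, tmp_path):
        cfg, m, pairs = island_null
        clf = FstOutlierClassifier(n_replicates=cfg.n_replicates, seed=cfg.seed).fit(
            null_pairs=pairs
        )
        clf.config_ = cfg
        clf.save_null(tmp_path / "null.csv")
        other = FstOutlierClassifier(n_replicates=cfg.n_replicates, target_fst=0.2, seed=cfg.seed)
        with pytest.raises(ValueError):
            other.load_null(tmp_path / "null.csv")
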