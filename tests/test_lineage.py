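import math

import numpy as np
import pandas as pd
import pytest

import notchtrack as nt
from notchtrack.errors import InsufficientDataError
from notchtrack.lineage import (align_cell_cycle, build_trees,
                                classify_gmc_persistence, classify_roles,
                                detect_reactivation, export_barchart, fit_gmc_decay,
                                nb_cycle_profile)

from helpers import role_accuracy, trace_level_forest, track_to_cell


def trace(times, values, diam=9.0):
    return pd.DataFrame({"time_h": times, "mean_green_norm": values,
                         "equiv_diameter_px": np.full(len(times), diam)})


def wt_truth_forest(seed=0, duration=10.0, cycle=3.0):
    cfg = nt.SimulationConfig(duration_hours=duration, frame_interval_min=15.0,
                              condition="WT", nb_cycle_hours=cycle,
                              nb_cycle_jitter_hours=0.0, noise=nt.NoiseParams.off(),
                              rng_seed=seed)
    lineages = [nt.simulate_lineage(cfg, 0)]
    forest, node_to_cell = trace_level_forest(lineages, cfg)
    return cfg, lineages, forest, node_to_cell


class TestBuildTrees:
    def test_node_count_matches_division_arithmetic(self):
        # 10 h movie, 3 h NB cycle, no jitter: the NB divides at 3/6/9 h and
        # one GMC (born 3 h, dividing 7 h) completes with visible daughters.
        # Every division adds two tracks: 1 + 2*(3 + 1) = 9 nodes; merging
        # the self-renewing NB chain gives 1 NB + 3 GMCs + 2 neurons = 6 cells.
        cfg, lineages, forest, _ = wt_truth_forest(duration=10.0, cycle=3.0)
        assert len(forest) == 1
        tree = forest[0]
        assert len(tree.nodes()) == 9
        roles = classify_roles(tree)
        chain_merges = sum(1 for n in tree.nodes()
                           if roles[n] == "NB" and tree.parent(n) is not None)
        assert len(tree.nodes()) - chain_merges == 6

    def test_no_divisions_gives_singleton_forest(self):
        obs = pd.DataFrame({
            "frame": [0, 0, 1], "label": [1, 2, 1], "time_h": [0.0, 0.0, 0.25],
            "z": 0.0, "y": [10.0, 60.0, 10.2], "x": 10.0,
            "volume_voxels": 200, "equiv_diameter_px": 9.0,
            "mean_red": 100.0, "mean_green": 1.0, "mean_green_norm": 1.0})
        links = nt.link_frames(obs, nt.TrackingParams())
        forest = build_trees(links, obs)
        assert len(forest) == 2
        assert all(len(t.nodes()) == 1 for t in forest)

    def test_tree_isomorphic_to_ground_truth(self, rendered_small):
        lineages = rendered_small["lineages"]
        obs = nt.normalize_green(rendered_small["obs"])
        links = rendered_small["links"]
        cfg = rendered_small["cfg"]
        mapping, _ = track_to_cell(links, obs, lineages)
        forest = build_trees(links, obs)
        cells = {c.cell_id: c for lin in lineages for c in lin.cells.values()}
        seen = set()
        for tree in forest:
            for n in tree.nodes():
                cell = cells[mapping[n]]
                seen.add(cell.cell_id)
                parent = tree.parent(n)
                if parent is not None:
                    assert mapping[parent] == cell.parent_id
                    assert abs(tree.birth(n) - cell.birth_time_h) \
                        <= cfg.frame_interval_hours + 1e-9
        rendered = {c.cell_id for c in cells.values() if c.frames.size}
        assert seen == rendered


class TestClassifyRoles:
    def test_larger_daughter_inherits_stem_identity(self):
        cfg, lineages, forest, node_to_cell = wt_truth_forest()
        tree = forest[0]
        for n in tree.nodes():
            kids = tree.children(n)
            if kids and tree.role(n) == "NB":
                diam = {k: tree.trace(k)["equiv_diameter_px"].median() for k in kids}
                big = max(kids, key=diam.get)
                assert tree.role(big) == "NB"
                assert tree.role(min(kids, key=diam.get)) == "GMC"

    def test_wt_roles_match_ground_truth_exactly(self, rendered_small):
        lineages = rendered_small["lineages"]
        obs = nt.normalize_green(rendered_small["obs"])
        links = rendered_small["links"]
        forest = build_trees(links, obs)
        assert role_accuracy(forest, links, obs, lineages) == 1.0

    def test_nb_like_calls_are_true_reactivations_older_than_gate(self):
        cfg = nt.SimulationConfig(condition="NACT", reactivation_probability=1.0,
                                  noise=nt.NoiseParams.off(), rng_seed=5)
        for i in range(6):
            lin = nt.simulate_lineage(cfg, i)
            forest, node_to_cell = trace_level_forest([lin], cfg, green_noise_sd=0.05,
                                                      rng=np.random.default_rng(i))
            truth = {c.cell_id: c for c in lin.cells.values()}
            called = 0
            for tree in forest:
                for n in tree.nodes():
                    if tree.role(n) == "NB_LIKE":
                        cell = truth[node_to_cell[n]]
                        called += 1
                        assert cell.role == "NB_LIKE"
                        if cell.conversion_time_h is not None:
                            assert cell.age_at_conversion_h > cfg.reactivation_min_age_hours
            assert called > 0


class TestDecayFit:
    def test_exact_exponential_recovered(self):
        t = np.arange(0.0, 3.01, 0.25)
        fit = fit_gmc_decay(trace(t, np.exp(-0.693 * t)), floor=0.0)
        assert fit.rate_per_h == pytest.approx(0.693, abs=1e-9)
        assert fit.half_life_h == pytest.approx(math.log(2) / 0.693, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_trace_has_no_half_life(self):
        t = np.arange(0.0, 2.01, 0.25)
        fit = fit_gmc_decay(trace(t, np.full(t.size, 3.0)))
        assert abs(fit.rate_per_h) < 1e-9
        assert fit.half_life_h is None

    def test_insufficient_samples_raise(self):
        with pytest.raises(InsufficientDataError):
            fit_gmc_decay(trace([0.0, 1.0, 2.0], [1.0, 0.5, 0.25]), floor=0.0)

    def test_noisy_simulated_gmc_rate_recovered_within_ten_percent(self):
        rates = []
        for seed in range(15):
            cfg = nt.SimulationConfig(duration_hours=10.0, frame_interval_min=10.0,
                                      condition="WT", noise=nt.NoiseParams.off(),
                                      rng_seed=seed)
            lineages = [nt.simulate_lineage(cfg, 0)]
            forest, _ = trace_level_forest(lineages, cfg, green_noise_sd=0.05,
                                           rng=np.random.default_rng(seed))
            for tree in forest:
                for n in tree.nodes():
                    if tree.role(n) == "GMC" and len(tree.trace(n)) >= 8:
                        rates.append(fit_gmc_decay(tree.trace(n)).rate_per_h)
        assert rates
        assert abs(np.median(rates) - 0.5) / 0.5 < 0.10


class TestCellCycleAlignment:
    def test_constant_trace_gives_flat_profile(self):
        t = np.arange(0.0, 2.01, 0.1)
        prof = align_cell_cycle(trace(t, np.full(t.size, 2.5)), [0.0, 2.0], n_bins=10)
        filled = prof.mean_green[~np.isnan(prof.mean_green)]
        assert np.allclose(filled, 2.5)

    def test_two_identical_cycles_equal_single_cycle(self):
        t1 = np.arange(1, 33) / 16.0  # binary fractions: t + 2 - 2 is exact
        v = 1.0 + np.cos(2 * np.pi * t1 / 2.0)
        one = align_cell_cycle(trace(t1, v), [0.0, 2.0], n_bins=10)
        t2 = np.concatenate([t1, t1 + 2.0])
        two = align_cell_cycle(trace(t2, np.concatenate([v, v])), [0.0, 2.0, 4.0], n_bins=10)
        assert two.n_cycles == 2
        assert np.allclose(one.mean_green, two.mean_green, equal_nan=True)

    def test_no_complete_cycle_raises(self):
        with pytest.raises(InsufficientDataError):
            align_cell_cycle(trace([0.1], [1.0]), [0.0])

    def test_simulated_nb_profile_peaks_at_cycle_edges(self):
        cfg, lineages, forest, _ = wt_truth_forest(seed=2, duration=10.0, cycle=2.0)
        tree = max(forest, key=lambda t: len(t.nodes()))
        prof = nb_cycle_profile(tree)
        peak = prof.bin_centers[np.nanargmax(prof.mean_green)]
        assert peak < 0.1 or peak > 0.9
        assert prof.n_cycles >= 2


class TestPersistence:
    def test_decaying_gmc_is_not_persistent(self):
        cfg, lineages, forest, _ = wt_truth_forest()
        flags, percent = classify_gmc_persistence(forest)
        assert percent == 0.0

    def test_planted_fraction_recovered_exactly_when_noiseless(self):
        cfg = nt.SimulationConfig(condition="NACT_MI2I", noise=nt.NoiseParams.off(),
                                  rng_seed=3)
        lineages, ids = [], 1
        for i in range(36):
            lin = nt.simulate_lineage(cfg, i, id_start=ids, force_persistent=(i < 10))
            ids += len(lin.cells)
            lineages.append(lin)
        forest, _ = trace_level_forest(lineages, cfg)
        flags, percent = classify_gmc_persistence(forest)
        assert percent == pytest.approx(100.0 * 10 / 36, abs=1e-9)
        assert round(percent, 1) == 27.8

    def test_threshold_rule_on_synthetic_trace(self):
        # a GMC dropping below theta within an hour of birth must not count
        import networkx as nx
        graph = nx.DiGraph()
        t_nb = np.arange(0.0, 8.01, 0.25)
        graph.add_node(0, trace=trace(t_nb, np.full(t_nb.size, 2.0), diam=14.0),
                       birth_time_h=0.0, end_time_h=8.0)
        t_g = np.arange(2.25, 6.26, 0.25)
        fast = 2.0 * np.exp(-3.0 * (t_g - 2.0))
        graph.add_node(1, trace=trace(t_g, fast, diam=9.0), birth_time_h=2.0,
                       end_time_h=6.25)
        graph.add_node(2, trace=trace(t_nb + 0.25, np.full(t_nb.size, 2.0), diam=14.0),
                       birth_time_h=2.0, end_time_h=8.25)
        graph.add_edge(0, 1)
        graph.add_edge(0, 2)
        tree = nt.LineageTree(graph=graph, root=0)
        classify_roles(tree)
        flags, percent = classify_gmc_persistence([tree])
        assert percent == 0.0


class TestReactivation:
    def test_monotone_decay_returns_none(self):
        t = np.arange(0.0, 6.01, 0.25)
        assert detect_reactivation(trace(t, 3.0 * np.exp(-t)), 0.0) is None

    def test_high_from_birth_is_persistence_not_reactivation(self):
        t = np.arange(0.0, 6.01, 0.25)
        assert detect_reactivation(trace(t, np.full(t.size, 2.0)), 0.0) is None

    def test_programmed_onset_detected_within_one_frame(self):
        cfg = nt.SimulationConfig(condition="NACT", noise=nt.NoiseParams.off(),
                                  rng_seed=0)
        dt = cfg.frame_interval_hours
        t = np.arange(0.0, 12.0 + 1e-9, dt)
        onset_true = 7.0 + dt  # green ramp starts one frame after conversion
        v = np.where(t < onset_true, 0.05,
                     np.minimum(0.05 + (t - onset_true) * 4.0 / cfg.nb_like_ramp_hours, 4.0))
        onset = detect_reactivation(trace(t, v), birth_time_h=-2.0)
        assert onset is not None
        assert abs(onset - onset_true) <= dt + 1e-9

    def test_simulated_reactivations_all_pass_age_gate(self):
        cfg = nt.SimulationConfig(condition="NACT", reactivation_probability=1.0,
                                  noise=nt.NoiseParams.off(), rng_seed=9)
        n_detected = 0
        for i in range(5):
            lin = nt.simulate_lineage(cfg, i)
            forest, node_to_cell = trace_level_forest([lin], cfg, green_noise_sd=0.05,
                                                      rng=np.random.default_rng(100 + i))
            truth = {c.cell_id: c for c in lin.cells.values()}
            for tree in forest:
                for n in tree.nodes():
                    onset = detect_reactivation(tree.trace(n), tree.birth(n))
                    if onset is not None:
                        cell = truth[node_to_cell[n]]
                        n_detected += 1
                        assert onset - cell.birth_time_h > cfg.reactivation_min_age_hours
        assert n_detected > 0


class TestBarChartExport:
    def test_rows_sorted_root_first(self):
        cfg, lineages, forest, _ = wt_truth_forest()
        table = export_barchart(forest)
        assert len(table) == sum(len(t.nodes()) for t in forest)
        assert table.loc[0, "parent_id"] == -1
        assert table["start_h"].is_monotonic_increasing

    def test_csv_round_trip_identical(self, tmp_path):
        cfg, lineages, forest, _ = wt_truth_forest()
        table = export_barchart(forest)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        table.to_csv(p1, index=False)
        back = pd.read_csv(p1)
        back.to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()
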