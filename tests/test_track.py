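import numpy as np
import pandas as pd
import pytest

import notchtrack as nt
from notchtrack.errors import DegenerateInputError, EditError, InputError
from notchtrack.track import (AddLink, LinkTable, RemoveLink, SetDivision,
                              TrackingParams, apply_edits, detect_divisions,
                              link_frames, link_frames_exhaustive, normalize_green,
                              partition_signature, random_link_instance)

from helpers import link_recovery


def obs_table(rows):
    """rows: (frame, label, z, y, x[, diameter])"""
    recs = []
    for r in rows:
        f, l, z, y, x = r[:5]
        d = r[5] if len(r) > 5 else 10.0
        recs.append((f, l, f / 6.0, z, y, x, 500, d, 100.0, 1.0, np.nan))
    return pd.DataFrame(recs, columns=["frame", "label", "time_h", "z", "y", "x",
                                       "volume_voxels", "equiv_diameter_px",
                                       "mean_red", "mean_green", "mean_green_norm"])


class TestLinkFrames:
    def test_inclusive_radius_boundary(self):
        obs = obs_table([(0, 1, 5, 10, 10), (1, 1, 5, 10, 22)])
        links = link_frames(obs, TrackingParams())
        assert len(links) == 1 and links.df.loc[0, "distance_px"] == pytest.approx(12.0)

    def test_just_outside_radius_opens_new_track(self):
        obs = obs_table([(0, 1, 5, 10, 10), (1, 1, 5, 10, 23)])
        links = link_frames(obs, TrackingParams())
        assert len(links) == 0
        tracks = links.track_ids(obs)
        assert tracks["track_id"].nunique() == 2

    def test_gap_closing_up_to_five_frames(self):
        obs = obs_table([(10, 1, 0, 50, 50), (15, 1, 0, 50, 53)])
        links = link_frames(obs, TrackingParams())
        assert len(links) == 1 and links.df.loc[0, "gap"] == 5
        obs6 = obs_table([(10, 1, 0, 50, 50), (16, 1, 0, 50, 53)])
        assert len(link_frames(obs6, TrackingParams())) == 0

    def test_z_scale_applied_to_distances(self):
        obs = obs_table([(0, 1, 5, 10, 10), (1, 1, 10, 10, 10)])
        assert len(link_frames(obs, TrackingParams(z_scale=1.0))) == 1  # dz = 5
        assert len(link_frames(obs, TrackingParams(z_scale=3.0))) == 0  # dz = 15

    def test_duplicate_observation_rejected(self):
        obs = obs_table([(0, 1, 0, 0, 0), (0, 1, 0, 5, 5)])
        with pytest.raises(InputError):
            link_frames(obs, TrackingParams())

    def test_all_emitted_records_respect_radius_and_gap(self, rendered_small):
        links, obs = rendered_small["links"], rendered_small["obs"]
        params = rendered_small["tracking_params"]
        links.validate(obs, params)  # distance <= radius, gap <= max, degrees
        assert (links.df["distance_px"] <= params.radius_px + 1e-9).all()
        assert links.df["gap"].between(1, params.max_gap_frames).all()

    def test_greedy_matches_exhaustive_oracle_on_small_instances(self):
        params = TrackingParams()
        agree = 0
        for seed in range(30):
            obs = random_link_instance(seed, n_cells=5, n_frames=10)
            greedy = partition_signature(link_frames(obs, params), obs)
            exact = partition_signature(link_frames_exhaustive(obs, params), obs)
            agree += greedy == exact
        assert agree >= 28


class TestGapRobustness:
    def _steady_obs(self, n_frames=20):
        rows = [(f, 1, 0.0, 50.0 + 0.3 * f, 50.0) for f in range(n_frames)]
        rows += [(f, 2, 0.0, 120.0, 120.0) for f in range(n_frames)]
        return obs_table(rows)

    @pytest.mark.parametrize("k", [1, 3, 4])
    def test_holes_within_the_search_window_are_bridged(self, k):
        # k missing detections leave a link spanning k+1 frames; the 5-frame
        # search bridges spans of up to 5 frames
        obs = self._steady_obs()
        keep = ~((obs["label"] == 1) & obs["frame"].between(8, 7 + k))
        obs = obs[keep].reset_index(drop=True)
        tracks = link_frames(obs, TrackingParams()).track_ids(obs)
        assert tracks["track_id"].nunique() == 2

    def test_hole_beyond_the_search_window_splits_track_in_two(self):
        obs = self._steady_obs()
        keep = ~((obs["label"] == 1) & obs["frame"].between(8, 12))  # 5 missing
        obs = obs[keep].reset_index(drop=True)
        tracks = link_frames(obs, TrackingParams()).track_ids(obs)
        assert tracks["track_id"].nunique() == 3
        assert tracks[tracks["label"] == 1]["track_id"].nunique() == 2


class TestDetectDivisions:
    def test_unmatched_end_with_two_orphans(self):
        obs = obs_table([(0, 1, 0, 50, 50, 16.0),
                         (1, 2, 0, 44, 50, 11.0), (1, 3, 0, 58, 50, 11.0)])
        links = detect_divisions(LinkTable(), obs, TrackingParams())
        div = links.division_edges()
        assert len(div) == 2
        assert sorted(div["label_b"]) == [2, 3]

    def test_three_orphans_two_nearest_chosen(self):
        obs = obs_table([(0, 1, 0, 50, 50, 16.0),
                         (1, 2, 0, 45, 50, 11.0), (1, 3, 0, 56, 50, 11.0),
                         (1, 4, 0, 50, 61, 11.0)])
        links = detect_divisions(LinkTable(), obs, TrackingParams())
        assert sorted(links.division_edges()["label_b"]) == [2, 3]
        tracks = links.track_ids(obs)
        assert tracks.loc[tracks["label"] == 4, "track_id"].nunique() == 1

    def test_oversized_daughters_do_not_divide(self):
        obs = obs_table([(0, 1, 0, 50, 50, 10.0),
                         (1, 2, 0, 44, 50, 9.9), (1, 3, 0, 56, 50, 9.9)])
        links = detect_divisions(LinkTable(), obs, TrackingParams())
        assert len(links.division_edges()) == 0

    def test_linked_successor_with_size_drop_reinterpreted_as_division(self):
        obs = obs_table([(0, 1, 0, 50, 50, 16.0),
                         (1, 2, 0, 46, 50, 13.0), (1, 3, 0, 58, 50, 9.0)])
        params = TrackingParams()
        links = link_frames(obs, params)
        assert len(links.links()) == 1  # the nearer daughter was linked through
        links = detect_divisions(links, obs, params)
        assert len(links.links()) == 0
        assert sorted(links.division_edges()["label_b"]) == [2, 3]

    def test_divisions_on_simulated_movie_match_truth(self, rendered_small):
        from helpers import track_to_cell, truth_divisions
        lineages = rendered_small["lineages"]
        links, obs = rendered_small["links"], rendered_small["obs"]
        cfg = rendered_small["cfg"]
        mapping, obs_t = track_to_cell(links, obs, lineages)
        truth = truth_divisions(lineages)
        measured = {}
        for ev in links.divisions(obs_t):
            mother = mapping[ev["mother_track"]]
            kids = frozenset(mapping[d] for d in ev["daughter_tracks"])
            measured[mother] = (ev["frame"] * cfg.frame_interval_hours, kids)
        assert set(measured) == set(truth)
        for mother, (t_div, kids) in truth.items():
            t_meas, kids_meas = measured[mother]
            assert kids_meas == kids
            assert abs(t_meas - t_div) <= cfg.frame_interval_hours + 1e-9


class TestApplyEdits:
    def _base(self):
        obs = obs_table([(0, 1, 0, 50, 50), (1, 2, 0, 52, 50), (2, 3, 0, 54, 50),
                         (7, 4, 0, 54, 52)])
        params = TrackingParams()
        return obs, params, link_frames(obs, params)

    def test_remove_then_add_is_identity(self):
        obs, params, links = self._base()
        edits = [RemoveLink(0, 1, 1, 2), AddLink(0, 1, 1, 2)]
        assert apply_edits(links, edits, obs, params) == links

    def test_gap_exceeding_window_rejected_by_name(self):
        obs, params, links = self._base()
        with pytest.raises(EditError, match="gap exceeds max_gap_frames"):
            apply_edits(links, [AddLink(1, 2, 7, 4)], obs, params)

    def test_empty_edit_list_is_identity(self):
        obs, params, links = self._base()
        assert apply_edits(links, [], obs, params) == links

    def test_set_division_replaces_outgoing_link(self):
        obs = obs_table([(0, 1, 0, 50, 50, 16.0),
                         (1, 2, 0, 46, 50, 11.0), (1, 3, 0, 56, 50, 11.0)])
        params = TrackingParams()
        links = link_frames(obs, params)
        edited = apply_edits(links, [SetDivision(0, 1, 1, 2, 1, 3)], obs, params)
        assert len(edited.links()) == 0 and len(edited.division_edges()) == 2

    def test_second_incoming_link_rejected(self):
        obs, params, links = self._base()
        with pytest.raises(EditError, match="incoming"):
            apply_edits(links, [AddLink(0, 1, 2, 3)], obs, params)


class TestNormalizeGreen:
    def test_normalisation_against_movie_mean(self):
        obs = obs_table([(0, 1, 0, 0, 0), (0, 2, 0, 0, 5), (0, 3, 0, 0, 9)])
        obs["mean_green"] = [2.0, 4.0, 6.0]
        out = normalize_green(obs)
        assert list(out["mean_green_norm"]) == [0.5, 1.0, 1.5]

    def test_scale_invariance_and_unit_mean(self):
        rng = np.random.default_rng(0)
        obs = obs_table([(f, l, 0, 10 * l, 10 * f) for f in range(4) for l in range(1, 6)])
        obs["mean_green"] = rng.uniform(1, 50, len(obs))
        a = normalize_green(obs)
        scaled = obs.copy()
        scaled["mean_green"] *= 10.0
        b = normalize_green(scaled)
        assert np.allclose(a["mean_green_norm"], b["mean_green_norm"])
        assert a["mean_green_norm"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_zero_mean_rejected(self):
        obs = obs_table([(0, 1, 0, 0, 0)])
        obs["mean_green"] = [0.0]
        with pytest.raises(DegenerateInputError):
            normalize_green(obs)


class TestEndToEndRecovery:
    def test_noiseless_link_recovery_is_perfect_across_seeds(self):
        """Segmentation + linking + division detection on small noiseless
        movies recovers every ground-truth temporal connection."""
        params = TrackingParams()
        for seed in range(10):
            cfg = nt.SimulationConfig(duration_hours=4.0, frame_interval_min=15.0,
                                      condition="WT", n_lineages=1,
                                      volume_shape_zyx=(22, 128, 128),
                                      noise=nt.NoiseParams.off(), rng_seed=seed)
            lineages = nt.simulate_movie(cfg)
            movie, _ = nt.render_movie(lineages, cfg)
            _, obs = nt.segment_movie(movie, nt.SegmentationParams())
            links = detect_divisions(link_frames(obs, params), obs, params)
            precision, recall = link_recovery(lineages, obs, links)
            assert precision == 1.0 and recall == 1.0, f"seed {seed}"
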