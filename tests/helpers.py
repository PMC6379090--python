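"""Shared evaluation helpers: measured results vs simulator ground truth."""

from __future__ import annotations

import notchtrack as nt

TRUTH_TO_MEASURED_ROLE = {"PERSISTENT_GMC": "GMC"}


def obs_to_cell_map(observations, lineages) -> dict:
    """(frame, label) -> ground-truth cell id by nearest true centroid."""
    matched = nt.simulate.match_to_truth(observations, lineages)
    return {(int(r.frame), int(r.label)): int(r.true_cell) for r in matched.itertuples()}


def link_recovery(lineages, observations, links) -> tuple[float, float]:
    """Precision / recall of all temporal connections (links + divisions)."""
    key2cell = obs_to_cell_map(observations, lineages)
    measured = {((r.frame_a, key2cell[(r.frame_a, r.label_a)]),
                 (r.frame_b, key2cell[(r.frame_b, r.label_b)]))
                for r in links.df.itertuples()}
    true = nt.simulate.true_link_set(lineages)
    inter = len(true & measured)
    return (inter / len(measured) if measured else 0.0,
            inter / len(true) if true else 1.0)


def track_to_cell(links, observations, lineages) -> tuple[dict, "object"]:
    """track id -> majority ground-truth cell, plus the obs-with-tracks table."""
    obs_t = links.track_ids(observations)
    matched = nt.simulate.match_to_truth(obs_t, lineages)
    mapping = matched.groupby("track_id")["true_cell"] \
        .agg(lambda s: int(s.mode().iloc[0])).to_dict()
    return mapping, obs_t


def truth_roles(lineages) -> dict:
    return {c.cell_id: TRUTH_TO_MEASURED_ROLE.get(c.role, c.role)
            for lin in lineages for c in lin.cells.values()}


def truth_divisions(lineages) -> dict:
    """mother cell id -> (division time, frozenset of daughter cell ids)."""
    out = {}
    for lin in lineages:
        for c in lin.cells.values():
            if c.end_kind == "divides" and c.frames.size:
                kids = frozenset(k.cell_id for k in lin.children_of(c.cell_id)
                                 if k.frames.size)
                if len(kids) == 2:
                    out[c.cell_id] = (c.end_time_h, kids)
    return out


def role_accuracy(forest, links, observations, lineages, params=None) -> float:
    mapping, _ = track_to_cell(links, observations, lineages)
    truth = truth_roles(lineages)
    ok = tot = 0
    for tree in forest:
        roles = nt.classify_roles(tree, params)
        for node, role in roles.items():
            tot += 1
            ok += role == truth[mapping[node]]
    return ok / tot if tot else 0.0


def trace_level_forest(lineages, config, green_noise_sd=0.0, rng=None):
    """Forest built from the simulator's own observations and link table
    (ideal detector), with normalised traces and classified roles."""
    obs = nt.observations_from_truth(lineages, config, green_noise_sd=green_noise_sd, rng=rng)
    obs = nt.normalize_green(obs)
    links = nt.links_from_truth(lineages, config)
    obs_t = links.track_ids(obs)
    forest = nt.build_trees(links, obs_t)
    for tree in forest:
        nt.classify_roles(tree)
    node_to_cell = obs_t.groupby("track_id")["label"].first().to_dict()
    return forest, node_to_cell
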