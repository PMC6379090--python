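"""Nearest-neighbour cell tracking with gap closing and division detection.

Observations are linked frame to frame by nearest neighbour within a fixed
radius (12 px by default), searching up to five previous frames so that a
cell missed by the detector for a few frames keeps its track.  Distances are
Euclidean on (z * z_scale, y, x) centroids, the radius boundary is inclusive,
and within one gap level assignments are made greedily in ascending distance.
Divisions are detected from the size signature of mitosis (nuclei round up
before an abrupt split into two smaller daughters); mother-daughter edges are
stored as ``division_edge`` records.  Manual corrections enter as an ordered
edit list, and green intensities are normalised to the movie average so
different movies are comparable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, EditError, InputError

LINK_COLUMNS = ["frame_a", "label_a", "frame_b", "label_b", "distance_px", "gap", "kind"]
_TOL = 1e-9


@dataclass(frozen=True)
class TrackingParams:
    radius_px: float = 12.0
    max_gap_frames: int = 5
    z_scale: float = 1.0
    division_size_ratio_max: float = 0.95

    def __post_init__(self) -> None:
        if not self.radius_px > 0:
            raise InputError("radius_px must be > 0")
        if self.max_gap_frames < 1:
            raise InputError("max_gap_frames must be >= 1")
        if not 0 < self.division_size_ratio_max <= 1:
            raise InputError("division_size_ratio_max must be in (0, 1]")
        if not self.z_scale > 0:
            raise InputError("z_scale must be > 0")


def _scaled_positions(obs: pd.DataFrame, z_scale: float) -> np.ndarray:
    pos = obs[["z", "y", "x"]].to_numpy(dtype=float).copy()
    pos[:, 0] *= z_scale
    return pos


class LinkTable:
    """Temporal links and division edges between observations.

    Each record is (frame_a, label_a) -> (frame_b, label_b) with its distance,
    gap length and kind ("link" or "division_edge").  Per observation: at most
    one incoming record, and either at most one outgoing ``link`` or exactly
    two outgoing ``division_edge`` records (a mitosis).
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=LINK_COLUMNS)
        self.df = df.reset_index(drop=True)[LINK_COLUMNS].astype(
            {"frame_a": int, "label_a": int, "frame_b": int, "label_b": int,
             "distance_px": float, "gap": int, "kind": str})

    @classmethod
    def from_records(cls, rows: Iterable[tuple]) -> "LinkTable":
        return cls(pd.DataFrame(list(rows), columns=LINK_COLUMNS))

    def copy(self) -> "LinkTable":
        return LinkTable(self.df.copy())

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LinkTable):
            return NotImplemented
        a = self.df.sort_values(LINK_COLUMNS).reset_index(drop=True)
        b = other.df.sort_values(LINK_COLUMNS).reset_index(drop=True)
        return a.equals(b)

    # -- derived structure -------------------------------------------------
    def links(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "link"]

    def division_edges(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "division_edge"]

    def track_ids(self, observations: pd.DataFrame) -> pd.DataFrame:
        """Partition observations into tracks (maximal chains of ``link``
        records).  Returns the observation table with a ``track_id`` column;
        ids are ordered by (first frame, first label) of the track."""
        obs = observations.sort_values(["frame", "label"], kind="stable").reset_index(drop=True)
        key_to_idx = {(int(f), int(l)): i
                      for i, (f, l) in enumerate(zip(obs["frame"], obs["label"]))}
        parent = list(range(len(obs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for rec in self.links().itertuples():
            a = key_to_idx.get((rec.frame_a, rec.label_a))
            b = key_to_idx.get((rec.frame_b, rec.label_b))
            if a is None or b is None:
                raise InputError(f"link references unknown observation "
                                 f"({rec.frame_a},{rec.label_a})->({rec.frame_b},{rec.label_b})")
            parent[find(a)] = find(b)
        roots = [find(i) for i in range(len(obs))]
        first_of_root: dict[int, int] = {}
        for i, r in enumerate(roots):
            first_of_root.setdefault(r, i)  # obs sorted by (frame, label)
        order = sorted(first_of_root, key=lambda r: first_of_root[r])
        root_to_tid = {r: t for t, r in enumerate(order)}
        obs = obs.copy()
        obs["track_id"] = [root_to_tid[r] for r in roots]
        return obs

    def divisions(self, obs_with_tracks: pd.DataFrame) -> list[dict]:
        """Division events as mother/daughter track ids plus the mitosis frame."""
        tid = {(int(f), int(l)): int(t) for f, l, t in
               zip(obs_with_tracks["frame"], obs_with_tracks["label"], obs_with_tracks["track_id"])}
        events = []
        for (fa, la), grp in self.division_edges().groupby(["frame_a", "label_a"]):
            daughters = sorted(tid[(int(r.frame_b), int(r.label_b))] for r in grp.itertuples())
            events.append({"frame": int(fa), "mother_track": tid[(int(fa), int(la))],
                           "daughter_tracks": daughters})
        return sorted(events, key=lambda e: (e["frame"], e["mother_track"]))

    # -- validation ---------------------------------------------------------
    def validate(self, observations: pd.DataFrame, params: TrackingParams) -> None:
        obs_keys = set(zip(observations["frame"].astype(int), observations["label"].astype(int)))
        incoming: dict[tuple, int] = {}
        out_links: dict[tuple, int] = {}
        out_div: dict[tuple, int] = {}
        for rec in self.df.itertuples():
            a, b = (rec.frame_a, rec.label_a), (rec.frame_b, rec.label_b)
            if a not in obs_keys or b not in obs_keys:
                raise InputError(f"record references unknown observation {a}->{b}")
            if not 1 <= rec.gap <= params.max_gap_frames:
                raise InputError(f"gap {rec.gap} outside [1, {params.max_gap_frames}] for {a}->{b}")
            if rec.gap != rec.frame_b - rec.frame_a:
                raise InputError(f"gap field inconsistent with frames for {a}->{b}")
            if rec.distance_px > params.radius_px + _TOL:
                raise InputError(f"distance {rec.distance_px:.3f} exceeds radius "
                                 f"{params.radius_px} for {a}->{b}")
            incoming[b] = incoming.get(b, 0) + 1
            if rec.kind == "link":
                out_links[a] = out_links.get(a, 0) + 1
            elif rec.kind == "division_edge":
                out_div[a] = out_div.get(a, 0) + 1
            else:
                raise InputError(f"unknown record kind {rec.kind!r}")
        for b, n in incoming.items():
            if n > 1:
                raise InputError(f"observation {b} has {n} incoming records")
        for a in set(out_links) | set(out_div):
            nl, nd = out_links.get(a, 0), out_div.get(a, 0)
            if nd and (nd != 2 or nl):
                raise InputError(f"observation {a} has {nl} links and {nd} division edges; "
                                 "a mitosis requires exactly 2 division edges and no link")
            if nl > 1:
                raise InputError(f"observation {a} has {nl} outgoing links")

    # -- CSV ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LinkTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_frames(observations: pd.DataFrame, params: TrackingParams) -> LinkTable:
    """Greedy nearest-neighbour linking with gap closing.

    Frames are processed in increasing order.  At frame t the candidate
    predecessors are open track ends at frames t-1 ... t-max_gap_frames;
    nearer frames are exhausted before farther ones, and within one gap level
    pairs are assigned greedily in ascending (distance, label) order.  The
    radius is inclusive (distance == radius still links).  Unmatched
    observations open new tracks.
    """
    obs = observations.reset_index(drop=True)
    dup = obs.duplicated(subset=["frame", "label"])
    if dup.any():
        first = obs[dup].iloc[0]
        raise InputError(f"duplicate observation (frame={int(first['frame'])}, "
                         f"label={int(first['label'])})")
    pos = _scaled_positions(obs, params.z_scale)
    frames = obs["frame"].to_numpy(dtype=int)
    labels = obs["label"].to_numpy(dtype=int)
    by_frame: dict[int, np.ndarray] = {f: np.flatnonzero(frames == f)
                                       for f in np.unique(frames)}
    open_ends: dict[int, list[int]] = {}  # end frame -> row indices
    rows = []
    for t in sorted(by_frame):
        cand = by_frame[t]
        unmatched = set(cand.tolist())
        for g in range(1, params.max_gap_frames + 1):
            ends = open_ends.get(t - g, [])
            if not ends or not unmatched:
                continue
            pairs = []
            um = sorted(unmatched)
            for e in ends:
                d = np.linalg.norm(pos[um] - pos[e], axis=1)
                for j, o in enumerate(um):
                    if d[j] <= params.radius_px + _TOL:
                        pairs.append((float(d[j]), labels[o], labels[e], e, o))
            used_ends: set[int] = set()
            for dist, _, _, e, o in sorted(pairs):
                if e in used_ends or o not in unmatched:
                    continue
                rows.append((int(frames[e]), int(labels[e]), t, int(labels[o]),
                             dist, g, "link"))
                used_ends.add(e)
                unmatched.discard(o)
            open_ends[t - g] = [e for e in ends if e not in used_ends]
        open_ends.setdefault(t, [])
        open_ends[t].extend(int(i) for i in cand)  # matched obs become the new ends
    return LinkTable.from_records(rows)


def detect_divisions(links: LinkTable, observations: pd.DataFrame,
                     params: TrackingParams) -> LinkTable:
    """Detect mitoses and add mother->daughter ``division_edge`` records.

    Two complementary signatures are recognised, both requiring each daughter
    to be within the search radius and window of the mother's last
    observation and to satisfy the asymmetric-size rule
    (daughter equivalent diameter <= division_size_ratio_max x mother's,
    mitotic nuclei having rounded up):

    * an unmatched track end with at least two orphan candidates -> the two
      nearest orphans become daughters;
    * a track end whose forward link shows the mitotic size drop, with one
      additional orphan candidate -> the link is reinterpreted as a division
      (the link is replaced by two division edges).

    Ties in distance are broken by lower gap, then lower label.
    """
    obs = observations.reset_index(drop=True)
    pos = _scaled_positions(obs, params.z_scale)
    key_to_idx = {(int(f), int(l)): i
                  for i, (f, l) in enumerate(zip(obs["frame"], obs["label"]))}
    diam = obs["equiv_diameter_px"].to_numpy(dtype=float)
    frames = obs["frame"].to_numpy(dtype=int)
    labels = obs["label"].to_numpy(dtype=int)

    df = links.df.copy()
    has_incoming = {(int(r.frame_b), int(r.label_b)) for r in df.itertuples()}
    outgoing: dict[tuple, list[int]] = {}
    for ridx, r in enumerate(df.itertuples()):
        outgoing.setdefault((int(r.frame_a), int(r.label_a)), []).append(ridx)

    by_frame: dict[int, np.ndarray] = {f: np.flatnonzero(frames == f)
                                       for f in np.unique(frames)}

    def orphan_candidates(m: int) -> list[tuple]:
        """(distance, gap, label, obs index) of size-qualifying orphans near m."""
        out = []
        ratio_max = params.division_size_ratio_max * diam[m]
        for g in range(1, params.max_gap_frames + 1):
            sel = by_frame.get(frames[m] + g, ())
            for o in sel:
                if (int(frames[o]), int(labels[o])) in has_incoming:
                    continue
                d = float(np.linalg.norm(pos[o] - pos[m]))
                if d <= params.radius_px + _TOL and diam[o] <= ratio_max + _TOL:
                    out.append((d, g, int(labels[o]), int(o)))
        return sorted(out)

    new_rows = []
    drop_rows: set[int] = set()
    order = sorted(range(len(obs)), key=lambda i: (frames[i], labels[i]))
    for m in order:
        key = (int(frames[m]), int(labels[m]))
        out_rows = [ridx for ridx in outgoing.get(key, []) if ridx not in drop_rows]
        if not out_rows:
            cands = orphan_candidates(m)
            if len(cands) >= 2:
                for d, g, lab, o in cands[:2]:
                    new_rows.append((key[0], key[1], int(frames[o]), lab, d, g,
                                     "division_edge"))
                    has_incoming.add((int(frames[o]), lab))
        elif len(out_rows) == 1 and df.iloc[out_rows[0]]["kind"] == "link":
            rec = df.iloc[out_rows[0]]
            s = key_to_idx[(int(rec["frame_b"]), int(rec["label_b"]))]
            if diam[s] > params.division_size_ratio_max * diam[m] + _TOL:
                continue
            cands = orphan_candidates(m)
            if cands:
                d, g, lab, o = cands[0]
                drop_rows.add(out_rows[0])
                new_rows.append((key[0], key[1], int(frames[s]), int(labels[s]),
                                 float(rec["distance_px"]), int(rec["gap"]), "division_edge"))
                new_rows.append((key[0], key[1], int(frames[o]), lab, d, g, "division_edge"))
                has_incoming.add((int(frames[o]), lab))
    kept = df.drop(index=sorted(drop_rows)).reset_index(drop=True)
    out = pd.concat([kept, pd.DataFrame(new_rows, columns=LINK_COLUMNS)], ignore_index=True)
    result = LinkTable(out)
    result.validate(obs, params)
    return result


# ---------------------------------------------------------------------------
# manual edits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AddLink:
    frame_a: int
    label_a: int
    frame_b: int
    label_b: int


@dataclass(frozen=True)
class RemoveLink:
    frame_a: int
    label_a: int
    frame_b: int
    label_b: int


@dataclass(frozen=True)
class SetDivision:
    mother_frame: int
    mother_label: int
    d1_frame: int
    d1_label: int
    d2_frame: int
    d2_label: int


Edit = AddLink | RemoveLink | SetDivision


def apply_edits(links: LinkTable, edits: Sequence[Edit], observations: pd.DataFrame,
                params: TrackingParams) -> LinkTable:
    """Apply manual corrections in order; the result is re-validated against
    every link-table invariant and an offending edit is rejected with an
    error naming the invariant."""
    obs = observations.reset_index(drop=True)
    pos = _scaled_positions(obs, params.z_scale)
    key_to_idx = {(int(f), int(l)): i
                  for i, (f, l) in enumerate(zip(obs["frame"], obs["label"]))}

    def make_row(a: tuple, b: tuple, kind: str) -> tuple:
        if a not in key_to_idx or b not in key_to_idx:
            raise EditError(f"edit references unknown observation {a} or {b}")
        gap = b[0] - a[0]
        if not 1 <= gap <= params.max_gap_frames:
            raise EditError(f"gap exceeds max_gap_frames ({gap} > {params.max_gap_frames})"
                            if gap > params.max_gap_frames else f"gap {gap} must be >= 1")
        d = float(np.linalg.norm(pos[key_to_idx[b]] - pos[key_to_idx[a]]))
        if d > params.radius_px + _TOL:
            raise EditError(f"distance {d:.3f} exceeds radius_px {params.radius_px}")
        return (a[0], a[1], b[0], b[1], d, gap, kind)

    df = links.df.copy()
    for edit in edits:
        if isinstance(edit, AddLink):
            row = make_row((edit.frame_a, edit.label_a), (edit.frame_b, edit.label_b), "link")
            df = pd.concat([df, pd.DataFrame([row], columns=LINK_COLUMNS)], ignore_index=True)
        elif isinstance(edit, RemoveLink):
            sel = ((df["frame_a"] == edit.frame_a) & (df["label_a"] == edit.label_a)
                   & (df["frame_b"] == edit.frame_b) & (df["label_b"] == edit.label_b))
            if not sel.any():
                raise EditError(f"no record ({edit.frame_a},{edit.label_a})->"
                                f"({edit.frame_b},{edit.label_b}) to remove")
            df = df[~sel].reset_index(drop=True)
        elif isinstance(edit, SetDivision):
            m = (edit.mother_frame, edit.mother_label)
            sel = (df["frame_a"] == m[0]) & (df["label_a"] == m[1])
            df = df[~sel].reset_index(drop=True)  # a mother has no other outgoing records
            r1 = make_row(m, (edit.d1_frame, edit.d1_label), "division_edge")
            r2 = make_row(m, (edit.d2_frame, edit.d2_label), "division_edge")
            df = pd.concat([df, pd.DataFrame([r1, r2], columns=LINK_COLUMNS)],
                           ignore_index=True)
        else:
            raise EditError(f"unknown edit {edit!r}")
        table = LinkTable(df)
        try:
            table.validate(obs, params)
        except InputError as exc:
            raise EditError(f"edit {edit!r} violates a link-table invariant: {exc}") from exc
        df = table.df
    return LinkTable(df)


def edits_from_frame(df: pd.DataFrame) -> list[Edit]:
    """Parse an edit list from a table with columns (op, a1..a6)."""
    out: list[Edit] = []
    for r in df.itertuples(index=False):
        vals = [int(v) for v in r[1:] if pd.notna(v)]
        op = r[0]
        if op == "add_link":
            out.append(AddLink(*vals[:4]))
        elif op == "remove_link":
            out.append(RemoveLink(*vals[:4]))
        elif op == "set_division":
            out.append(SetDivision(*vals[:6]))
        else:
            raise EditError(f"unknown edit op {op!r}")
    return out


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize_green(observations: pd.DataFrame) -> pd.DataFrame:
    """Fill ``mean_green_norm`` = mean_green / (movie-wide mean of the
    per-cell green means), so normalised values average exactly 1 and are
    invariant to global intensity scaling between movies."""
    if len(observations) == 0:
        raise DegenerateInputError("no observations to normalise")
    m = float(observations["mean_green"].mean())
    if not m > 0:
        raise DegenerateInputError(f"movie-average green is {m}; normalisation undefined")
    out = observations.copy()
    out["mean_green_norm"] = out["mean_green"] / m
    return out


# ---------------------------------------------------------------------------
# exhaustive reference linker (validation oracle)
# ---------------------------------------------------------------------------

def link_frames_exhaustive(observations: pd.DataFrame, params: TrackingParams) -> LinkTable:
    """Reference linker for validation: at each frame and gap level it
    enumerates *all* feasible one-to-one assignments between open ends and
    unmatched observations and keeps a maximum-cardinality assignment of
    minimum total distance.  Exponential; only usable on small instances."""
    obs = observations.reset_index(drop=True)
    pos = _scaled_positions(obs, params.z_scale)
    frames = obs["frame"].to_numpy(dtype=int)
    labels = obs["label"].to_numpy(dtype=int)
    by_frame = {f: np.flatnonzero(frames == f) for f in np.unique(frames)}
    open_ends: dict[int, list[int]] = {}
    rows = []
    for t in sorted(by_frame):
        unmatched = sorted(by_frame[t].tolist())
        for g in range(1, params.max_gap_frames + 1):
            ends = open_ends.get(t - g, [])
            if not ends or not unmatched:
                continue
            dist = {(e, o): float(np.linalg.norm(pos[o] - pos[e]))
                    for e in ends for o in unmatched}
            feasible = {k: v for k, v in dist.items() if v <= params.radius_px + _TOL}
            best: tuple[int, float, tuple] | None = None
            k = min(len(ends), len(unmatched))
            for size in range(k, -1, -1):
                for ends_sub in itertools.combinations(ends, size):
                    for obs_sub in itertools.permutations(unmatched, size):
                        pairs = tuple(zip(ends_sub, obs_sub))
                        if any(p not in feasible for p in pairs):
                            continue
                        cost = sum(feasible[p] for p in pairs)
                        if best is None or (-size, cost) < (-best[0], best[1]):
                            best = (size, cost, pairs)
                if best is not None and best[0] == size:
                    break  # maximum cardinality found at this size
            if best is None:
                continue
            used_e = set()
            for e, o in best[2]:
                rows.append((int(frames[e]), int(labels[e]), t, int(labels[o]),
                             feasible[(e, o)], g, "link"))
                used_e.add(e)
                unmatched.remove(o)
            open_ends[t - g] = [e for e in ends if e not in used_e]
        open_ends.setdefault(t, [])
        open_ends[t].extend(int(i) for i in by_frame[t])
    return LinkTable.from_records(rows)


def random_link_instance(seed: int, n_cells: int = 5, n_frames: int = 10,
                         box_px: float = 100.0, step_sd_px: float = 1.5,
                         dropout: float = 0.08, min_sep_px: float = 12.0) -> pd.DataFrame:
    """Small synthetic observation table for linker validation: ``n_cells``
    random walkers in a 2D box (z = 0) with detection dropout.  Initial
    positions respect a minimum separation (nuclei cannot interpenetrate) and
    per-frame steps are small relative to the nuclear diameter, as in the
    movies this package analyses."""
    rng = np.random.default_rng(seed)
    pos: list[np.ndarray] = []
    while len(pos) < n_cells:
        p = rng.uniform(10.0, box_px - 10.0, 2)
        if all(np.linalg.norm(p - q) >= min_sep_px for q in pos):
            pos.append(p)
    pts = np.array(pos)
    rows = []
    label = 1
    for f in range(n_frames):
        for c in range(n_cells):
            if f > 0:
                pts[c] = np.clip(pts[c] + rng.normal(0.0, step_sd_px, 2), 0.0, box_px)
            if rng.uniform() < dropout:
                continue
            rows.append((f, label, f / 6.0, 0.0, pts[c, 0], pts[c, 1],
                         180, 7.0, 100.0, 1.0, np.nan))
            label += 1
    return pd.DataFrame(rows, columns=["frame", "label", "time_h", "z", "y", "x",
                                       "volume_voxels", "equiv_diameter_px",
                                       "mean_red", "mean_green", "mean_green_norm"])


def partition_signature(links: LinkTable, observations: pd.DataFrame) -> frozenset:
    """Canonical form of a track partition for comparing two linkers."""
    tracks = links.track_ids(observations)
    groups: dict[int, list] = {}
    for r in tracks.itertuples():
        groups.setdefault(int(r.track_id), []).append((int(r.frame), int(r.label)))
    return frozenset(frozenset(g) for g in groups.values())
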