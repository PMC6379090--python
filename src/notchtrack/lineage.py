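"""Lineage-tree reconstruction and reporter read-outs.

Tracks become tree nodes, division events become mother->daughter edges,
and each node carries an intensity trace (time, normalised green, equivalent
diameter).  Roles are classified from size and division pattern: at each
division of a stem cell the larger daughter keeps the stem identity and the
smaller is a GMC; a GMC whose two daughters are terminal and similar-sized
produced neurons; a small cell that grows past the GMC/NB midpoint and then
divides asymmetrically has re-acquired the stem-cell programme (NB-like).
On top of the trees sit the trace-level read-outs: exponential GMC decay
fits, cell-cycle-aligned NB profiles, per-lineage persistence of GMC
reporter expression, and reactivation-onset detection.

The persistence and reactivation thresholds are explicit, tunable decisions
(the underlying biology was originally scored by eye): a lineage counts as
persistent when a GMC born during the movie holds >= theta x its root NB's
median level for at least a minimum duration after birth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError, InsufficientDataError

ROLE_NB = "NB"
ROLE_GMC = "GMC"
ROLE_NEURON = "NEURON"
ROLE_NB_LIKE = "NB_LIKE"
ROLE_UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds for the trace-level classifiers.

    persistence_level_theta   GMC green must stay >= theta x (root NB median)
    persistence_min_duration_h  ... for at least this long after birth (h)
    reactivation_on_theta     normalised level whose upward crossing marks onset
    reactivation_off_theta    quiet level; must be < on_theta
    reactivation_min_quiet_h  minimum observed quiet time before an onset
    n_phase_bins              bins of the cell-cycle phase grid
    nb_diameter_px / gmc_diameter_px  reference diameters; their midpoint is
                              the "intermediate size" boundary for NB-like calls
    similarity_ratio          daughter-diameter ratio at/above which a division
                              counts as symmetric (neuron-producing)
    """

    persistence_level_theta: float = 0.5
    persistence_min_duration_h: float = 4.0
    reactivation_on_theta: float = 0.3
    reactivation_off_theta: float = 0.15
    reactivation_min_quiet_h: float = 2.0
    n_phase_bins: int = 20
    nb_diameter_px: float = 14.0
    gmc_diameter_px: float = 9.0
    similarity_ratio: float = 0.8

    def __post_init__(self) -> None:
        for name in ("persistence_level_theta", "persistence_min_duration_h",
                     "reactivation_on_theta", "reactivation_off_theta",
                     "reactivation_min_quiet_h", "nb_diameter_px", "gmc_diameter_px"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be > 0")
        if not self.reactivation_off_theta < self.reactivation_on_theta:
            raise InputError("reactivation_off_theta must be < reactivation_on_theta")
        if self.n_phase_bins < 1:
            raise InputError("n_phase_bins must be >= 1")

    @property
    def intermediate_diameter_px(self) -> float:
        return 0.5 * (self.nb_diameter_px + self.gmc_diameter_px)


@dataclass
class LineageTree:
    """One rooted tree of tracks.  Node attributes: ``trace`` (DataFrame with
    time_h, mean_green_norm, equiv_diameter_px), ``birth_time_h``,
    ``end_time_h``, ``role``."""

    graph: nx.DiGraph
    root: int

    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def children(self, node: int) -> list[int]:
        return sorted(self.graph.successors(node))

    def parent(self, node: int) -> int | None:
        preds = list(self.graph.predecessors(node))
        return preds[0] if preds else None

    def trace(self, node: int) -> pd.DataFrame:
        return self.graph.nodes[node]["trace"]

    def role(self, node: int) -> str:
        return self.graph.nodes[node].get("role", ROLE_UNKNOWN)

    def birth(self, node: int) -> float:
        return self.graph.nodes[node]["birth_time_h"]

    def validate(self) -> None:
        if not nx.is_arborescence(self.graph.subgraph(
                nx.descendants(self.graph, self.root) | {self.root})):
            raise InputError("lineage tree is not a rooted tree")
        for n in self.graph.nodes:
            kids = list(self.graph.successors(n))
            if kids and len(kids) != 2:
                raise InputError(f"node {n} divides into {len(kids)} != 2 daughters")
            t = self.trace(n)
            if len(t) and not np.all(np.diff(t["time_h"].to_numpy()) > 0):
                raise InputError(f"trace of node {n} has non-increasing times")


@dataclass
class CellCycleProfile:
    """Mean normalised reporter level on a phase grid over [0, 1]; phase 0 is
    just after mitosis and 1 just before the next."""

    bin_edges: np.ndarray
    mean_green: np.ndarray
    n_cycles: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class DecayFit:
    rate_per_h: float
    half_life_h: float | None
    r2: float
    n_used: int


# ---------------------------------------------------------------------------
# tree building
# ---------------------------------------------------------------------------

def build_trees(links, observations: pd.DataFrame) -> list[LineageTree]:
    """Assemble the forest: nodes are tracks, edges are division events,
    traces come from the (normalised) observations."""
    obs_t = links.track_ids(observations)
    g = nx.DiGraph()
    frame_time = dict(zip(obs_t["frame"].astype(int), obs_t["time_h"].astype(float)))
    for tid, grp in obs_t.groupby("track_id"):
        grp = grp.sort_values("time_h")
        trace = grp[["time_h", "mean_green_norm", "equiv_diameter_px"]].reset_index(drop=True)
        g.add_node(int(tid), trace=trace,
                   birth_time_h=float(grp["time_h"].iloc[0]),
                   end_time_h=float(grp["time_h"].iloc[-1]))
    for ev in links.divisions(obs_t):
        t_div = frame_time[ev["frame"]]
        for d in ev["daughter_tracks"]:
            if g.in_degree(d) > 0:
                raise InputError(f"track {d} has more than one parent")
            g.add_edge(ev["mother_track"], d)
            g.nodes[d]["birth_time_h"] = t_div  # daughters are born at the mitosis frame
    forest = []
    for comp in nx.weakly_connected_components(g):
        sub = g.subgraph(comp).copy()
        roots = [n for n in sub.nodes if sub.in_degree(n) == 0]
        if len(roots) != 1:
            raise InputError(f"component {sorted(comp)} has {len(roots)} roots")
        forest.append(LineageTree(graph=sub, root=roots[0]))
    return sorted(forest, key=lambda t: t.root)


# ---------------------------------------------------------------------------
# role classification
# ---------------------------------------------------------------------------

def _median_diameter(tree: LineageTree, node: int) -> float:
    d = tree.trace(node)["equiv_diameter_px"].to_numpy(dtype=float)
    return float(np.median(d)) if d.size else 0.0


def _rises_above(tree: LineageTree, node: int, threshold: float) -> bool:
    d = tree.trace(node)["equiv_diameter_px"].to_numpy(dtype=float)
    if d.size < 3:
        return bool(d.size and d.max() > threshold)
    smooth = pd.Series(d).rolling(3, center=True, min_periods=1).median().to_numpy()
    return bool(np.max(smooth) > threshold)


def classify_roles(tree: LineageTree, params: AnalysisParams | None = None) -> dict[int, str]:
    """Assign NB / GMC / NEURON / NB_LIKE / UNKNOWN per node (see module
    docstring for the rules).  Roots that start large are the NB; small roots
    (progeny born before imaging) start UNKNOWN and can be upgraded to
    NB_LIKE by the intermediate-size + asymmetric-division rule."""
    params = params or AnalysisParams()
    mid = params.intermediate_diameter_px
    roles: dict[int, str] = {}

    def initial_root_role(node: int) -> str:
        d = tree.trace(node)["equiv_diameter_px"].to_numpy(dtype=float)
        head = float(np.median(d[: min(3, d.size)])) if d.size else 0.0
        return ROLE_NB if head >= mid else ROLE_UNKNOWN

    def divides_asym(node: int) -> bool:
        kids = tree.children(node)
        if len(kids) != 2:
            return False
        dd = sorted(_median_diameter(tree, k) for k in kids)
        return dd[1] > 0 and dd[0] / dd[1] < params.similarity_ratio

    def assign(node: int, provisional: str) -> None:
        role = provisional
        if role != ROLE_NB and _rises_above(tree, node, mid) and divides_asym(node):
            role = ROLE_NB_LIKE
        kids = tree.children(node)
        if len(kids) == 2:
            k_big, k_small = sorted(kids, key=lambda k: -_median_diameter(tree, k))
            if role in (ROLE_NB, ROLE_NB_LIKE):
                assign(k_big, role)
                assign(k_small, ROLE_GMC)
            elif role == ROLE_GMC:
                dd = sorted(_median_diameter(tree, k) for k in kids)
                terminal = all(not tree.children(k) for k in kids)
                similar = dd[1] > 0 and dd[0] / dd[1] >= params.similarity_ratio
                nxt = ROLE_NEURON if terminal and similar else ROLE_UNKNOWN
                assign(k_big, nxt)
                assign(k_small, nxt)
            else:
                assign(k_big, ROLE_UNKNOWN)
                assign(k_small, ROLE_UNKNOWN)
        roles[node] = role

    assign(tree.root, initial_root_role(tree.root))
    nx.set_node_attributes(tree.graph, roles, "role")
    return roles


# ---------------------------------------------------------------------------
# trace-level read-outs
# ---------------------------------------------------------------------------

def fit_gmc_decay(trace: pd.DataFrame, floor: float | None = None,
                  value_column: str = "mean_green_norm") -> DecayFit:
    """Log-linear least-squares fit of exponential reporter decay.

    Samples at or below ``floor`` (default: the trace's own 5th percentile)
    are excluded as detector/background floor.  Returns the decay rate (1/h),
    the half-life ln2/rate (None for non-decaying traces) and the r^2 of the
    log-linear fit.
    """
    t = trace["time_h"].to_numpy(dtype=float)
    v = trace[value_column].to_numpy(dtype=float)
    if floor is None:
        floor = float(np.percentile(v, 5.0))
    use = v >= max(floor, 1e-300)
    if use.sum() < 4:
        raise InsufficientDataError(f"only {int(use.sum())} samples above the floor; need >= 4")
    tt, vv = t[use] - t[use][0], np.log(v[use])
    slope, intercept = np.polyfit(tt, vv, 1)
    pred = slope * tt + intercept
    ss_res = float(np.sum((vv - pred) ** 2))
    ss_tot = float(np.sum((vv - vv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rate = -float(slope)
    half = math.log(2.0) / rate if rate > 1e-9 else None
    return DecayFit(rate_per_h=rate, half_life_h=half, r2=r2, n_used=int(use.sum()))


def align_cell_cycle(trace: pd.DataFrame, division_times_h, n_bins: int = 20,
                     value_column: str = "mean_green_norm") -> CellCycleProfile:
    """Map samples of an NB trace onto cell-cycle phase and average per bin.

    Phase of a sample at time t inside a complete inter-division interval
    (t_prev, t_next] is (t - t_prev) / (t_next - t_prev); incomplete first
    and last cycles are excluded.
    """
    div = sorted(float(d) for d in division_times_h)
    if len(div) < 2:
        raise InsufficientDataError("need >= 1 complete inter-division interval")
    t = trace["time_h"].to_numpy(dtype=float)
    v = trace[value_column].to_numpy(dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    n_cycles = 0
    for t0, t1 in zip(div[:-1], div[1:]):
        sel = (t > t0) & (t <= t1)
        if not sel.any():
            continue
        n_cycles += 1
        phase = (t[sel] - t0) / (t1 - t0)
        idx = np.minimum((phase * n_bins).astype(int), n_bins - 1)
        np.add.at(sums, idx, v[sel])
        np.add.at(counts, idx, 1)
    if n_cycles == 0:
        raise InsufficientDataError("no samples fall inside a complete cycle")
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return CellCycleProfile(bin_edges=edges, mean_green=mean, n_cycles=n_cycles)


def nb_chain(tree: LineageTree) -> list[int]:
    """The self-renewing stem-cell path: root plus, at each division, the
    daughter that kept the NB / NB-like role."""
    chain = [tree.root]
    while True:
        kids = [k for k in tree.children(chain[-1])
                if tree.role(k) in (ROLE_NB, ROLE_NB_LIKE)]
        if not kids:
            return chain
        chain.append(max(kids, key=lambda k: _median_diameter(tree, k)))


def nb_cycle_profile(tree: LineageTree, params: AnalysisParams | None = None) -> CellCycleProfile:
    """Cell-cycle-aligned reporter profile of a lineage's NB, concatenating
    the traces along the NB chain; division times are the chain's node ends."""
    params = params or AnalysisParams()
    chain = nb_chain(tree)
    if len(chain) < 2:
        raise InsufficientDataError("NB divides fewer than 2 times; no complete cycle")
    traces = pd.concat([tree.trace(n) for n in chain], ignore_index=True)
    div_times = [tree.graph.nodes[n]["end_time_h"] for n in chain[:-1]]
    # phase 0 anchored at each mitosis frame (the node boundary)
    return align_cell_cycle(traces, div_times, params.n_phase_bins)


def classify_gmc_persistence(forest: list[LineageTree],
                             params: AnalysisParams | None = None
                             ) -> tuple[dict[int, bool], float]:
    """Per-lineage flag and percentage of lineages in which a newly born GMC
    retains the reporter.

    A lineage (a tree rooted at an NB) is persistent iff some GMC node born
    during the movie keeps mean_green_norm >= theta x (the NB chain's median
    level) for at least the configured duration after birth.  Trees not
    rooted at an NB (pre-existing progeny) are not lineages and are ignored.
    """
    params = params or AnalysisParams()
    lineages = [t for t in forest if t.role(t.root) == ROLE_NB]
    if not lineages:
        raise DegenerateInputError("no NB-rooted lineages to classify")
    flags: dict[int, bool] = {}
    for tree in lineages:
        ref_values = pd.concat([tree.trace(n) for n in nb_chain(tree)])["mean_green_norm"]
        ref = float(np.median(ref_values.to_numpy(dtype=float)))
        theta = params.persistence_level_theta * ref
        persistent = False
        for n in tree.nodes():
            if tree.role(n) != ROLE_GMC or tree.parent(n) is None:
                continue
            tr = tree.trace(n)
            t = tr["time_h"].to_numpy(dtype=float)
            v = tr["mean_green_norm"].to_numpy(dtype=float)
            if t.size < 2:
                continue
            birth = tree.birth(n)
            dt = float(np.median(np.diff(t)))
            horizon = birth + params.persistence_min_duration_h
            if t[-1] < horizon - dt - 1e-9:
                continue  # not observed long enough to qualify
            window = v[t <= horizon + 1e-9]
            if window.size and np.all(window >= theta):
                persistent = True
                break
        flags[tree.root] = persistent
    percent = 100.0 * sum(flags.values()) / len(flags)
    return flags, percent


def detect_reactivation(trace: pd.DataFrame, birth_time_h: float,
                        params: AnalysisParams | None = None) -> float | None:
    """Onset time of reporter re-expression, or None.

    The onset is the first sample at/above ``reactivation_on_theta`` that
    follows an observed quiet period of at least ``reactivation_min_quiet_h``
    spent below ``reactivation_off_theta``.  Traces that are high from birth
    (persistence) or that only decay return None.
    """
    params = params or AnalysisParams()
    t = trace["time_h"].to_numpy(dtype=float)
    v = trace["mean_green_norm"].to_numpy(dtype=float)
    quiet_start: float | None = None
    for ti, vi in zip(t, v):
        if vi >= params.reactivation_on_theta:
            if quiet_start is not None and ti - quiet_start >= params.reactivation_min_quiet_h:
                return float(ti)
            quiet_start = None
        elif vi >= params.reactivation_off_theta:
            quiet_start = None
        elif quiet_start is None:
            quiet_start = float(ti)
    return None


def export_barchart(forest: list[LineageTree]) -> pd.DataFrame:
    """Flatten a forest into one row per cell for bar-chart-style plots:
    lifetime, median size, and the full normalised green trace (times and
    values as ';'-joined strings), with division linkage via parent_id."""
    rows = []
    for tree in forest:
        for n in tree.nodes():
            tr = tree.trace(n)
            parent = tree.parent(n)
            rows.append({
                "cell_id": int(n),
                "parent_id": -1 if parent is None else int(parent),
                "start_h": float(tree.birth(n)),
                "end_h": float(tree.graph.nodes[n]["end_time_h"]),
                "median_diameter_px": _median_diameter(tree, n),
                "role": tree.role(n),
                "times_h": ";".join(f"{x:.6g}" for x in tr["time_h"]),
                "green_norm": ";".join(f"{x:.6g}" for x in tr["mean_green_norm"]),
            })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["start_h", "cell_id"], kind="stable").reset_index(drop=True)
    return df


def analyze_forest(forest: list[LineageTree], params: AnalysisParams | None = None) -> dict:
    """Convenience bundle of the trace-level read-outs for a whole forest."""
    params = params or AnalysisParams()
    for tree in forest:
        classify_roles(tree, params)
    flags, percent = classify_gmc_persistence(forest, params)
    reactivations = []
    decay_fits = []
    for tree in forest:
        for n in tree.nodes():
            role = tree.role(n)
            tr = tree.trace(n)
            if role == ROLE_GMC and len(tr) >= 4:
                try:
                    fit = fit_gmc_decay(tr)
                except InsufficientDataError:
                    continue
                decay_fits.append({"node": n, "rate_per_h": fit.rate_per_h,
                                   "half_life_h": fit.half_life_h, "r2": fit.r2})
            if role in (ROLE_NEURON, ROLE_UNKNOWN, ROLE_NB_LIKE):
                onset = detect_reactivation(tr, tree.birth(n), params)
                if onset is not None:
                    reactivations.append({"node": n, "onset_h": onset,
                                          "birth_h": tree.birth(n),
                                          "onset_age_h": onset - tree.birth(n)})
    return {"persistence_flags": flags, "persistence_percent": percent,
            "reactivations": reactivations,
            "gmc_decay_fits": pd.DataFrame(decay_fits)}
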