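"""Synthetic neuroblast-lineage movies with known ground truth.

Drosophila type I neuroblasts (NBs) divide asymmetrically every few hours,
self-renewing as the larger daughter and budding off a smaller ganglion
mother cell (GMC) that divides exactly once, ~4 h after birth, into two
equal-sized post-mitotic neurons.  A Notch-reporter (green channel) is high
in the NB — modulated over the cell cycle with peaks just after and just
before mitosis — and decays exponentially in newly born GMCs.  Under
constitutive Notch activity, progeny born more than 8 h earlier can
re-acquire the stem-cell programme (grow to an intermediate size, re-express
the reporter, and resume asymmetric divisions); because a 10–14 h movie is
too short for progeny born during imaging to both pass the 8 h age gate and
divide again, reactivation-competent progeny are seeded at negative birth
times, mirroring the fact that reactivation is only observed in cells born
before the onset of imaging.  Under additional Mi-2 depletion, a configurable
fraction of lineages is "planted persistent": their GMCs keep the reporter
high from birth and, when they divide within the movie, both daughters
retain it.

Every simulated lineage is a rooted tree of :class:`GroundTruthCell` with
per-frame positions, radii and programmed reporter levels; lineages are
rendered into two-channel movies (red = ubiquitous nuclear marker used for
segmentation and tracking, green = reporter) with PSF blur, background,
Poisson shot noise and Gaussian read noise.  All randomness is derived from
``(config.rng_seed, lineage_seed)`` so movies are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigurationError, DomainError, PlacementError

CONDITIONS = ("WT", "NACT", "NACT_MI2I")
ROLES = ("NB", "GMC", "NEURON", "NB_LIKE", "PERSISTENT_GMC")

_EPS = 1e-9


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseParams:
    """Image-corruption model applied after rasterisation.

    background_offset  additive constant (camera offset), arbitrary units
    gaussian_sd        additive read-noise SD; default 5 = 5% of the nuclear
                       red density (100)
    poisson_gain       photons per intensity unit for shot noise; 0 disables
    psf_sigma_zyx      Gaussian PSF sigma per axis in voxels; 0 disables
    """

    background_offset: float = 10.0
    gaussian_sd: float = 5.0
    poisson_gain: float = 1.0
    psf_sigma_zyx: tuple[float, float, float] = (0.8, 0.8, 0.8)

    @staticmethod
    def off() -> "NoiseParams":
        return NoiseParams(0.0, 0.0, 0.0, (0.0, 0.0, 0.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic movie.

    Durations are hours, the frame interval minutes, lengths pixels (voxels
    are isotropic by default; ``voxel_size_um_zyx`` only sets the recorded
    geometry).  Intensity units are arbitrary: only ratios and shapes are
    meaningful.
    """

    duration_hours: float = 12.0
    frame_interval_min: float = 10.0
    nb_cycle_hours: float = 2.0
    nb_cycle_jitter_hours: float = 0.25
    gmc_division_delay_hours: float = 4.0
    reactivation_min_age_hours: float = 8.0
    reactivation_probability: float = 0.5
    persistence_fraction: float = 0.278
    condition: str = "WT"
    n_lineages: int = 1
    volume_shape_zyx: tuple[int, int, int] = (28, 256, 256)
    voxel_size_um_zyx: tuple[float, float, float] = (0.5, 0.5, 0.5)
    nb_radius_px: float = 7.0
    gmc_radius_px: float = 4.5
    neuron_radius_px: float = 3.5
    nb_like_radius_px: float = 6.0
    gmc_decay_rate_per_hour: float = 0.5
    gmc_decay_rate_nact_per_hour: float | None = None
    nb_baseline_green: float = 50.0
    cycle_amplitude: float = 0.8
    cycle_bump_width: float = 0.1
    green_floor: float = 1.0
    nb_like_ramp_hours: float = 1.5
    reactivation_delay_hours: tuple[float, float] = (0.3, 1.5)
    n_preborn_progeny: int = 4
    preborn_age_range_hours: tuple[float, float] = (1.0, 10.0)
    mitotic_swell: float = 1.2
    red_density: float = 100.0
    walk_sd_px: float = 0.25
    separation_factor: float = 3.0
    region_radius_px: float = 34.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "duration_hours": self.duration_hours,
            "frame_interval_min": self.frame_interval_min,
            "nb_cycle_hours": self.nb_cycle_hours,
            "gmc_division_delay_hours": self.gmc_division_delay_hours,
            "reactivation_min_age_hours": self.reactivation_min_age_hours,
            "nb_radius_px": self.nb_radius_px,
            "gmc_radius_px": self.gmc_radius_px,
            "neuron_radius_px": self.neuron_radius_px,
            "nb_like_radius_px": self.nb_like_radius_px,
            "gmc_decay_rate_per_hour": self.gmc_decay_rate_per_hour,
            "nb_baseline_green": self.nb_baseline_green,
            "nb_like_ramp_hours": self.nb_like_ramp_hours,
            "red_density": self.red_density,
            "region_radius_px": self.region_radius_px,
            "separation_factor": self.separation_factor,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {value!r}")
        for name, value in (
            ("reactivation_probability", self.reactivation_probability),
            ("persistence_fraction", self.persistence_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        if self.nb_cycle_jitter_hours < 0:
            raise ConfigurationError("nb_cycle_jitter_hours must be >= 0")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not self.gmc_radius_px < self.nb_radius_px:
            raise ConfigurationError("gmc_radius_px must be smaller than nb_radius_px (asymmetric division)")
        if self.n_lineages < 1:
            raise ConfigurationError("n_lineages must be >= 1")
        if self.n_frames < 2:
            raise ConfigurationError("frame_interval_min must divide the duration into at least 2 frames")

    @property
    def frame_interval_hours(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration_hours / self.frame_interval_hours + _EPS)) + 1

    @property
    def frame_times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_hours

    @property
    def gmc_decay_rate(self) -> float:
        if self.condition != "WT" and self.gmc_decay_rate_nact_per_hour is not None:
            return self.gmc_decay_rate_nact_per_hour
        return self.gmc_decay_rate_per_hour

    def radius_for_role(self, role: str) -> float:
        return {
            "NB": self.nb_radius_px,
            "GMC": self.gmc_radius_px,
            "PERSISTENT_GMC": self.gmc_radius_px,
            "NEURON": self.neuron_radius_px,
            "NB_LIKE": self.nb_like_radius_px,
        }[role]


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthCell:
    """One cell (one cell-cycle segment for cycling cells) of a lineage.

    ``frames``/``centroids_zyx``/``radii_px``/``green`` cover exactly the
    movie frames at which the cell exists.  A dividing NB is represented as
    a chain of such segments, one per cycle, so each segment's lifetime is
    one inter-division interval.  ``conversion_time_h`` is set on cells that
    switch role to NB_LIKE (the same cell converts; its birth age at the
    switch always exceeds the reactivation age gate).
    """

    cell_id: int
    parent_id: int | None
    birth_time_h: float
    end_time_h: float
    end_kind: str  # "divides" | "survives_to_end"
    role: str
    lineage_id: int = 0
    preborn: bool = False
    retains_green: bool = False
    i0_green: float = 0.0
    conversion_time_h: float | None = None
    frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    centroids_zyx: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    radii_px: np.ndarray = field(default_factory=lambda: np.empty(0))
    green: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def age_at_conversion_h(self) -> float | None:
        if self.conversion_time_h is None:
            return None
        return self.conversion_time_h - self.birth_time_h


@dataclass
class GroundTruthLineage:
    """A rooted tree of cells plus (for Notch-active conditions) pre-born
    parentless progeny that belong to the same biological lineage."""

    cells: dict[int, GroundTruthCell]
    root_id: int
    lineage_id: int
    planted_persistent: bool

    def children_of(self, cell_id: int) -> list[GroundTruthCell]:
        return [c for c in self.cells.values() if c.parent_id == cell_id]

    def validate(self) -> None:
        roots = [c for c in self.cells.values() if c.parent_id is None]
        nb_roots = [c for c in roots if c.cell_id == self.root_id]
        if len(nb_roots) != 1 or nb_roots[0].role not in ("NB",):
            raise AssertionError("lineage must have exactly one NB root")
        for c in roots:
            if c.cell_id != self.root_id and not c.preborn:
                raise AssertionError(f"parentless cell {c.cell_id} is neither the root nor pre-born")
        for c in self.cells.values():
            if c.parent_id is not None and c.parent_id not in self.cells:
                raise AssertionError("parent reference escapes the lineage")
            if not c.birth_time_h < c.end_time_h:
                raise AssertionError("birth must precede end")
            kids = self.children_of(c.cell_id)
            if c.end_kind == "divides":
                if len(kids) != 2 or any(abs(k.birth_time_h - c.end_time_h) > 1e-6 for k in kids):
                    raise AssertionError("a dividing cell must have two daughters born at its end time")
            elif kids:
                raise AssertionError("a non-dividing cell must be childless")
            if c.role == "NB_LIKE" and c.conversion_time_h is not None:
                if not c.age_at_conversion_h > 0:
                    raise AssertionError("conversion must postdate birth")
        # acyclicity: walk each cell to a root
        for c in self.cells.values():
            seen, cur = set(), c
            while cur.parent_id is not None:
                if cur.cell_id in seen:
                    raise AssertionError("cycle in lineage")
                seen.add(cur.cell_id)
                cur = self.cells[cur.parent_id]


@dataclass
class MovieStack:
    """Two-channel 4D movie; ``data`` has axes (T, C, Z, Y, X), C = (red, green)."""

    data: np.ndarray
    frame_interval_min: float
    voxel_size_um_zyx: tuple[float, float, float]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def red(self, frame: int) -> np.ndarray:
        return self.data[frame, 0]

    def green(self, frame: int) -> np.ndarray:
        return self.data[frame, 1]


# ---------------------------------------------------------------------------
# reporter program
# ---------------------------------------------------------------------------

def _cycle_modulation(phase: float, amplitude: float, width: float) -> float:
    """Bimodal raised-cosine bump over a flat interphase plateau.

    Peaks at phase 0 (just after mitosis, early G1) and phase 1 (just before
    mitosis, late G2); the plateau between the bumps is 1.
    """
    p = min(max(phase, 0.0), 1.0)
    edge = min(p, 1.0 - p)
    if edge < width:
        return 1.0 + amplitude * 0.5 * (1.0 + math.cos(math.pi * edge / width))
    return 1.0


def green_program(cell: GroundTruthCell, time_h: float, config: SimulationConfig) -> float:
    """True reporter level of ``cell`` at ``time_h``.

    NB: baseline x cell-cycle modulation.  GMC: exponential decay from the
    mother's level at division.  Persistent GMC (and green-retaining
    daughters): constant.  Neuron: continues the GMC decay down to a floor.
    Reactivating NB_LIKE cells decay as neurons until conversion, then ramp
    monotonically to the NB baseline (the green ramp starts one frame after
    the size ramp).
    """
    if time_h < cell.birth_time_h - 1e-6 or time_h > cell.end_time_h + 1e-6:
        raise DomainError(
            f"time {time_h} h outside lifetime [{cell.birth_time_h}, {cell.end_time_h}] of cell {cell.cell_id}"
        )
    base = config.nb_baseline_green
    k = config.gmc_decay_rate
    role = cell.role
    if role in ("NB",) or (role == "NB_LIKE" and cell.conversion_time_h is None):
        span = cell.end_time_h - cell.birth_time_h
        if cell.end_kind == "survives_to_end":
            span = config.nb_cycle_hours
        phase = (time_h - cell.birth_time_h) / max(span, _EPS)
        return base * _cycle_modulation(phase, config.cycle_amplitude, config.cycle_bump_width)
    if role == "PERSISTENT_GMC":
        return cell.i0_green
    if role == "NB_LIKE":  # converting progeny
        ramp_start = cell.conversion_time_h + config.frame_interval_hours
        decayed = max(cell.i0_green * math.exp(-k * (min(time_h, ramp_start) - cell.birth_time_h)),
                      config.green_floor)
        if time_h <= ramp_start:
            return decayed
        frac = min((time_h - ramp_start) / config.nb_like_ramp_hours, 1.0)
        return decayed + (base - decayed) * frac
    if role == "NEURON" and cell.retains_green:
        return cell.i0_green
    if role in ("GMC", "NEURON"):
        return max(cell.i0_green * math.exp(-k * (time_h - cell.birth_time_h)), config.green_floor)
    raise DomainError(f"unknown role {role!r}")


def _radius_program(cell: GroundTruthCell, time_h: float, is_last_frame: bool,
                    config: SimulationConfig) -> float:
    if cell.role == "NB_LIKE" and cell.conversion_time_h is not None:
        if time_h < cell.conversion_time_h:
            r = config.neuron_radius_px
        else:
            frac = min((time_h - cell.conversion_time_h) / config.nb_like_ramp_hours, 1.0)
            r = config.neuron_radius_px + (config.nb_like_radius_px - config.neuron_radius_px) * frac
    else:
        r = config.radius_for_role(cell.role)
    if is_last_frame and cell.end_kind == "divides":
        r *= config.mitotic_swell  # mitotic rounding before the abrupt split
    return r


# ---------------------------------------------------------------------------
# lineage event simulation
# ---------------------------------------------------------------------------

def _cell_frame_indices(cell: GroundTruthCell, times: np.ndarray) -> np.ndarray:
    lo = cell.birth_time_h + _EPS
    if cell.parent_id is None:
        lo = cell.birth_time_h - _EPS  # roots and pre-born cells include their birth frame
    return np.flatnonzero((times > lo) & (times <= cell.end_time_h + _EPS))


def simulate_lineage(
    config: SimulationConfig,
    lineage_seed: int,
    anchor_zyx: tuple[float, float, float] | None = None,
    id_start: int = 1,
    force_persistent: bool | None = None,
) -> GroundTruthLineage:
    """Simulate one NB lineage: division events, roles, reporter programs
    and per-frame trajectories, deterministically from
    ``(config, lineage_seed)``.

    ``force_persistent`` overrides the Bernoulli persistence planting (used
    to construct cohorts with an exact planted count); ``id_start`` offsets
    cell ids so several lineages can share one movie.
    """
    rng = np.random.default_rng([int(config.rng_seed) & 0x7FFFFFFF, int(lineage_seed) & 0x7FFFFFFF])
    duration = config.duration_hours
    notch_active = config.condition in ("NACT", "NACT_MI2I")
    if force_persistent is not None:
        planted = bool(force_persistent)
        rng.uniform()  # keep the stream aligned with the Bernoulli branch
    else:
        planted = config.condition == "NACT_MI2I" and rng.uniform() < config.persistence_fraction

    cells: dict[int, GroundTruthCell] = {}
    next_id = id_start

    def new_cell(**kw) -> GroundTruthCell:
        nonlocal next_id
        c = GroundTruthCell(cell_id=next_id, lineage_id=lineage_seed, **kw)
        cells[c.cell_id] = c
        next_id += 1
        return c

    def draw_cycle() -> float:
        j = config.nb_cycle_jitter_hours
        dt = config.nb_cycle_hours + (rng.uniform(-j, j) if j > 0 else 0.0)
        return max(dt, 0.25 * config.nb_cycle_hours)

    def survive_end(birth: float) -> float:
        # a cell born exactly at the final timepoint still needs birth < end
        if duration - birth > 1e-6:
            return duration
        return birth + config.frame_interval_hours

    def mother_level_at_end(cell: GroundTruthCell) -> float:
        return green_program(cell, cell.end_time_h, config)

    def spawn_gmc(parent: GroundTruthCell, birth: float) -> None:
        i0 = mother_level_at_end(parent)
        end = birth + config.gmc_division_delay_hours
        if end <= duration + _EPS:
            gmc = new_cell(parent_id=parent.cell_id, birth_time_h=birth, end_time_h=end,
                           end_kind="divides", role="PERSISTENT_GMC" if planted else "GMC",
                           i0_green=i0)
            spawn_neuron_pair(gmc, end)
        else:
            new_cell(parent_id=parent.cell_id, birth_time_h=birth,
                     end_time_h=survive_end(birth), end_kind="survives_to_end",
                     role="PERSISTENT_GMC" if planted else "GMC", i0_green=i0)

    def spawn_neuron_pair(gmc: GroundTruthCell, birth: float) -> None:
        i0 = mother_level_at_end(gmc)
        for _ in range(2):
            spawn_progeny(parent_id=gmc.cell_id, birth=birth, i0=i0,
                          retains=gmc.role == "PERSISTENT_GMC")

    def spawn_progeny(parent_id: int | None, birth: float, i0: float,
                      retains: bool, preborn: bool = False) -> None:
        """A post-mitotic cell; under active Notch it may reactivate."""
        convert_at: float | None = None
        if notch_active and not retains:
            eligible = birth + config.reactivation_min_age_hours
            take = rng.uniform() < config.reactivation_probability
            lo, hi = config.reactivation_delay_hours
            delay = rng.uniform(lo, hi)
            if take and eligible + delay < duration - _EPS and eligible + delay > 0:
                convert_at = eligible + delay
        if convert_at is None:
            new_cell(parent_id=parent_id, birth_time_h=birth, end_time_h=survive_end(birth),
                     end_kind="survives_to_end", role="NEURON", i0_green=i0,
                     retains_green=retains, preborn=preborn)
            return
        div = convert_at + draw_cycle()
        if div <= duration + _EPS:
            nbl = new_cell(parent_id=parent_id, birth_time_h=birth, end_time_h=div,
                           end_kind="divides", role="NB_LIKE", i0_green=i0,
                           conversion_time_h=convert_at, preborn=preborn)
            spawn_nb_like_chain(nbl, div)
        else:
            new_cell(parent_id=parent_id, birth_time_h=birth, end_time_h=survive_end(birth),
                     end_kind="survives_to_end", role="NB_LIKE", i0_green=i0,
                     conversion_time_h=convert_at, preborn=preborn)

    def spawn_nb_like_chain(parent: GroundTruthCell, birth: float) -> None:
        """After conversion the cell cycles like an NB: the larger daughter
        keeps the NB-like state and the reporter, the smaller is a GMC."""
        t = birth
        mother = parent
        while True:
            spawn_gmc(mother, t)
            t_next = t + draw_cycle()
            if t_next <= duration + _EPS:
                seg = new_cell(parent_id=mother.cell_id, birth_time_h=t, end_time_h=t_next,
                               end_kind="divides", role="NB_LIKE")
                mother = seg
                t = t_next
            else:
                new_cell(parent_id=mother.cell_id, birth_time_h=t, end_time_h=survive_end(t),
                         end_kind="survives_to_end", role="NB_LIKE")
                return

    # --- root NB chain -----------------------------------------------------
    root = None
    t_prev, mother = 0.0, None
    while True:
        t_next = t_prev + draw_cycle()
        if t_next <= duration + _EPS:
            seg = new_cell(parent_id=None if mother is None else mother.cell_id,
                           birth_time_h=t_prev, end_time_h=t_next, end_kind="divides", role="NB")
            if root is None:
                root = seg
            spawn_gmc(seg, t_next)
            mother, t_prev = seg, t_next
        else:
            seg = new_cell(parent_id=None if mother is None else mother.cell_id,
                           birth_time_h=t_prev, end_time_h=survive_end(t_prev),
                           end_kind="survives_to_end", role="NB")
            if root is None:
                root = seg
            break

    # --- pre-born progeny (Notch-active conditions only) --------------------
    if notch_active:
        lo, hi = config.preborn_age_range_hours
        for _ in range(config.n_preborn_progeny):
            age = rng.uniform(lo, hi)
            spawn_progeny(parent_id=None, birth=-age, i0=config.green_floor,
                          retains=False, preborn=True)

    lineage = GroundTruthLineage(cells=cells, root_id=root.cell_id,
                                 lineage_id=lineage_seed, planted_persistent=planted)
    _assign_trajectories(lineage, config, rng, anchor_zyx)
    return lineage


# ---------------------------------------------------------------------------
# trajectories: placement, drift, repulsion
# ---------------------------------------------------------------------------

def _separation(config: SimulationConfig, r_a: float, r_b: float) -> float:
    return config.separation_factor * 0.5 * (r_a + r_b)


def _clamp(pos: np.ndarray, r: float, anchor: np.ndarray, config: SimulationConfig) -> np.ndarray:
    zdim, ydim, xdim = config.volume_shape_zyx
    swell = config.mitotic_swell
    out = pos.copy()
    out[0] = np.clip(out[0], r * swell + 1.5, zdim - 2.5 - r * swell)
    for ax, dim in ((1, ydim), (2, xdim)):
        lo = max(r * swell + 1.5, anchor[ax] - config.region_radius_px)
        hi = min(dim - 2.5 - r * swell, anchor[ax] + config.region_radius_px)
        out[ax] = np.clip(out[ax], lo, hi)
    return out


def _assign_trajectories(lineage: GroundTruthLineage, config: SimulationConfig,
                         rng: np.random.Generator,
                         anchor_zyx: tuple[float, float, float] | None) -> None:
    times = config.frame_times_h
    zdim, ydim, xdim = config.volume_shape_zyx
    anchor = np.asarray(anchor_zyx if anchor_zyx is not None
                        else (zdim / 2.0, ydim / 2.0, xdim / 2.0), dtype=float)
    cells = lineage.cells

    frame_idx: dict[int, np.ndarray] = {}
    for cid, cell in cells.items():
        idx = _cell_frame_indices(cell, times)
        frame_idx[cid] = idx
        n = idx.size
        cell.frames = idx
        cell.centroids_zyx = np.zeros((n, 3))
        cell.radii_px = np.zeros(n)
        cell.green = np.zeros(n)

    def base_radius(cell: GroundTruthCell) -> float:
        if cell.role == "NB_LIKE":
            return config.nb_like_radius_px
        return config.radius_for_role(cell.role)

    def rand_dir() -> np.ndarray:
        v = rng.normal(size=3)
        v[0] *= 0.3  # stay roughly in the imaging plane
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.array([0.0, 1.0, 0.0])

    live_pos: dict[int, np.ndarray] = {}

    def min_margin(p: np.ndarray, r: float, exclude: set[int]) -> float:
        m = np.inf
        for cid, q in live_pos.items():
            if cid in exclude:
                continue
            m = min(m, float(np.linalg.norm(p - q)) - _separation(config, r, base_radius(cells[cid])))
        return m

    first_frame = {cid: (idx[0] if idx.size else -1) for cid, idx in frame_idx.items()}

    for f, t in enumerate(times):
        # drift existing cells
        for cid in list(live_pos):
            cell = cells[cid]
            if frame_idx[cid].size and f > frame_idx[cid][-1]:
                del live_pos[cid]
                continue
            if f in frame_idx[cid]:
                step = rng.normal(0.0, config.walk_sd_px, size=3)
                step[0] *= 0.5
                live_pos[cid] = live_pos[cid] + step
        # place cells whose first frame is f
        starters = sorted(cid for cid, ff in first_frame.items() if ff == f)
        by_parent: dict[int | None, list[int]] = {}
        for cid in starters:
            by_parent.setdefault(cells[cid].parent_id, []).append(cid)
        for parent_id, kids in sorted(by_parent.items(), key=lambda kv: (kv[0] is None, kv[0])):
            if parent_id is not None and parent_id in cells and cells[parent_id].frames.size:
                mother = cells[parent_id]
                mpos = mother.centroids_zyx[-1]
                kids = sorted(kids, key=lambda cid: -base_radius(cells[cid]))
                r_big, r_small = (base_radius(cells[k]) for k in kids[:2]) if len(kids) == 2 \
                    else (base_radius(cells[kids[0]]), base_radius(cells[kids[0]]))
                sep = _separation(config, r_big, r_small)
                d_big = min(sep * r_small / (r_big + r_small), 9.0)
                d_small = min(sep - d_big, 10.5)
                best, best_score = None, -np.inf
                for _ in range(48):
                    u = rand_dir()
                    # score on the clamped positions: the boundary clamp must
                    # not crush the daughter-daughter separation
                    p_big = _clamp(mpos + u * d_big, r_big, anchor, config)
                    p_small = _clamp(mpos - u * d_small, r_small, anchor, config)
                    pair_margin = float(np.linalg.norm(p_big - p_small)) \
                        - _separation(config, r_big, r_small)
                    score = min(min_margin(p_big, r_big, set(kids)),
                                min_margin(p_small, r_small, set(kids)),
                                pair_margin)
                    if score > best_score:
                        best, best_score = (p_big, p_small), score
                placements = dict(zip(kids, best)) if len(kids) == 2 else {kids[0]: best[0]}
                for cid, p in placements.items():
                    live_pos[cid] = p
            else:
                for cid in kids:
                    r = base_radius(cells[cid])
                    best, best_score = None, -np.inf
                    for _ in range(200):
                        if cid == lineage.root_id:
                            p = anchor + np.array([0.0, 0.0, 0.0])
                            if not live_pos:
                                best = p
                                break
                        rad = rng.uniform(10.0, 0.9 * config.region_radius_px)
                        ang = rng.uniform(0.0, 2 * math.pi)
                        p = anchor + np.array([rng.uniform(-4.0, 4.0),
                                               rad * math.sin(ang), rad * math.cos(ang)])
                        score = min_margin(p, r, {cid})
                        if score > best_score:
                            best, best_score = p, score
                        if score > 0:
                            break
                    live_pos[cid] = best
        # gentle pairwise repulsion keeps drifting cells apart; clamping is
        # interleaved so boundary pile-ups get pushed apart again
        ids = sorted(live_pos)
        for _ in range(4):
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    d = live_pos[a] - live_pos[b]
                    dist = float(np.linalg.norm(d))
                    target = _separation(config, base_radius(cells[a]), base_radius(cells[b]))
                    if dist < target and dist > 0:
                        push = min(0.5, (target - dist) / 4.0)
                        u = d / dist
                        live_pos[a] = live_pos[a] + u * push
                        live_pos[b] = live_pos[b] - u * push
            for cid in ids:
                live_pos[cid] = _clamp(live_pos[cid], base_radius(cells[cid]), anchor, config)
        # record
        for cid in ids:
            cell = cells[cid]
            idx = frame_idx[cid]
            where = np.searchsorted(idx, f)
            if where >= idx.size or idx[where] != f:
                continue
            is_last = f == idx[-1]
            cell.centroids_zyx[where] = live_pos[cid]
            cell.radii_px[where] = _radius_program(cell, t, is_last, config)
            cell.green[where] = green_program(cell, t, config)


# ---------------------------------------------------------------------------
# multi-lineage movies
# ---------------------------------------------------------------------------

_ANCHOR_LAYOUTS = {
    1: [(0.5, 0.5)],
    2: [(0.3, 0.3), (0.7, 0.7)],
    3: [(0.25, 0.25), (0.25, 0.75), (0.75, 0.5)],
    4: [(0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75)],
    5: [(0.23, 0.23), (0.23, 0.77), (0.77, 0.23), (0.77, 0.77), (0.5, 0.5)],
}


def _lineage_anchors(config: SimulationConfig) -> list[tuple[float, float, float]]:
    zdim, ydim, xdim = config.volume_shape_zyx
    zmid = zdim / 2.0
    n = config.n_lineages
    if n in _ANCHOR_LAYOUTS:
        out = [(zmid, fy * ydim, fx * xdim) for fy, fx in _ANCHOR_LAYOUTS[n]]
    else:
        pitch = 2 * config.region_radius_px + 3.0 * config.nb_radius_px
        per_row = max(int((xdim - 2 * config.region_radius_px) // pitch), 1)
        out = []
        for i in range(n):
            gy, gx = divmod(i, per_row)
            out.append((zmid,
                        config.region_radius_px + 12 + gy * pitch,
                        config.region_radius_px + 12 + gx * pitch))
    m = config.region_radius_px + config.nb_radius_px * config.mitotic_swell
    min_pair = 2 * config.region_radius_px + _separation(
        config, config.nb_radius_px, config.nb_radius_px)
    for i, (_, ay, ax) in enumerate(out):
        if not (m <= ay <= ydim - m and m <= ax <= xdim - m):
            raise PlacementError(
                f"volume {config.volume_shape_zyx} too small for {n} lineages "
                f"with region radius {config.region_radius_px}")
        for (_, by, bx) in out[i + 1:]:
            if math.hypot(ay - by, ax - bx) < min_pair:
                raise PlacementError(
                    f"lineage anchors closer than {min_pair:.0f} px in volume "
                    f"{config.volume_shape_zyx}; enlarge the volume or reduce n_lineages")
    return out


def simulate_movie(config: SimulationConfig,
                   force_persistent: Sequence[bool] | None = None) -> list[GroundTruthLineage]:
    """Simulate ``config.n_lineages`` lineages placed on non-overlapping
    anchors inside the volume."""
    anchors = _lineage_anchors(config)
    lineages, id_start = [], 1
    for i in range(config.n_lineages):
        fp = None if force_persistent is None else force_persistent[i]
        lin = simulate_lineage(config, lineage_seed=i, anchor_zyx=anchors[i],
                               id_start=id_start, force_persistent=fp)
        id_start += len(lin.cells)
        lineages.append(lin)
    return lineages


def _cells_at_frame(lineages: Iterable[GroundTruthLineage], frame: int):
    for lin in lineages:
        for cell in lin.cells.values():
            where = np.searchsorted(cell.frames, frame)
            if where < cell.frames.size and cell.frames[where] == frame:
                yield lin, cell, where


def rasterize_frame(lineages: Sequence[GroundTruthLineage], config: SimulationConfig,
                    frame: int) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free rendering of one frame: (channels (2, Z, Y, X), labels).

    Touching nuclei within one lineage are legal (the segmentation watershed
    must separate them); contested voxels go to the nearer centroid.  Overlap
    between cells of *different* lineages means the placement regions collide
    and raises a :class:`PlacementError`.
    """
    shape = config.volume_shape_zyx
    chans = np.zeros((2,) + shape, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.uint16)
    lineage_of: dict[int, int] = {}
    info: dict[int, tuple[np.ndarray, float, float]] = {}
    for lin, cell, where in _cells_at_frame(lineages, frame):
        p = cell.centroids_zyx[where]
        r = float(cell.radii_px[where])
        lineage_of[cell.cell_id] = lin.lineage_id
        info[cell.cell_id] = (p, r, float(cell.green[where]))
        lo = np.maximum(np.floor(p - r - 1).astype(int), 0)
        hi = np.minimum(np.ceil(p + r + 1).astype(int) + 1, shape)
        if np.any(hi <= lo):
            raise PlacementError(f"cell {cell.cell_id} outside the volume at frame {frame}")
        zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        mask = ((zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2) <= r * r
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        clash = mask & (sub > 0)
        if clash.any():
            others = np.unique(sub[clash])
            for other in others:
                if lineage_of.get(int(other)) != lin.lineage_id:
                    raise PlacementError(
                        f"frame {frame}: cell {cell.cell_id} of lineage {lin.lineage_id} "
                        f"overlaps cell {int(other)} of lineage {lineage_of.get(int(other))}")
            # same lineage: contested voxels go to the nearer centroid
            zi, yi, xi = np.nonzero(clash)
            pts = np.stack([zi + lo[0], yi + lo[1], xi + lo[2]], axis=1).astype(float)
            d_new = np.linalg.norm(pts - p, axis=1) / r
            for other in others:
                po, ro, _ = info[int(other)]
                d_old = np.linalg.norm(pts - po, axis=1) / ro
                keep_old = (sub[clash] == other) & (d_old <= d_new)
                mask_idx = np.zeros(mask.shape, dtype=bool)
                mask_idx[zi[keep_old], yi[keep_old], xi[keep_old]] = True
                mask &= ~mask_idx
        sub[mask] = cell.cell_id
        chans[0, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][mask] = config.red_density
        chans[1, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][mask] = cell.green[where]
    return chans, labels


def render_movie(lineages: Sequence[GroundTruthLineage], config: SimulationConfig
                 ) -> tuple[MovieStack, np.ndarray]:
    """Render lineages into a noisy two-channel movie.

    Returns the movie (T, C, Z, Y, X, float32) and the pre-noise ground-truth
    label volumes (T, Z, Y, X, uint16) keyed by cell id.  Deterministic given
    ``config.rng_seed``.
    """
    n = config.n_frames
    shape = config.volume_shape_zyx
    movie = np.zeros((n, 2) + shape, dtype=np.float32)
    labels = np.zeros((n,) + shape, dtype=np.uint16)
    noise = config.noise
    rng = np.random.default_rng([int(config.rng_seed) & 0x7FFFFFFF, 0x5EED])
    for f in range(n):
        chans, lab = rasterize_frame(lineages, config, f)
        labels[f] = lab
        for c in range(2):
            img = chans[c]
            if any(s > 0 for s in noise.psf_sigma_zyx):
                img = ndi.gaussian_filter(img, sigma=noise.psf_sigma_zyx)
            img = img + noise.background_offset
            if noise.poisson_gain > 0:
                img = rng.poisson(np.maximum(img, 0.0) * noise.poisson_gain).astype(np.float32) \
                    / noise.poisson_gain
            if noise.gaussian_sd > 0:
                img = img + rng.normal(0.0, noise.gaussian_sd, size=img.shape).astype(np.float32)
            movie[f, c] = img
    return MovieStack(movie, config.frame_interval_min, config.voxel_size_um_zyx), labels


# ---------------------------------------------------------------------------
# ground-truth adapters (perfect-detector observations, true link tables)
# ---------------------------------------------------------------------------

def observations_from_truth(lineages: Sequence[GroundTruthLineage], config: SimulationConfig,
                            green_noise_sd: float = 0.0,
                            rng: np.random.Generator | None = None):
    """Observation table as an ideal detector would produce it, straight from
    the ground truth (no rendering): one row per cell per frame, labelled by
    cell id.  Optional multiplicative Gaussian noise on the green means."""
    import pandas as pd

    if green_noise_sd > 0 and rng is None:
        rng = np.random.default_rng(int(config.rng_seed) & 0x7FFFFFFF)
    times = config.frame_times_h
    rows = []
    for lin in lineages:
        for cell in lin.cells.values():
            for i, f in enumerate(cell.frames):
                r = cell.radii_px[i]
                vol = 4.0 / 3.0 * math.pi * r ** 3
                g = cell.green[i]
                if green_noise_sd > 0:
                    g = max(g * (1.0 + rng.normal(0.0, green_noise_sd)), 0.0)
                rows.append((int(f), int(cell.cell_id), float(times[f]),
                             *map(float, cell.centroids_zyx[i]), float(vol),
                             float(2 * r), float(config.red_density), float(g), np.nan))
    df = pd.DataFrame(rows, columns=["frame", "label", "time_h", "z", "y", "x",
                                     "volume_voxels", "equiv_diameter_px",
                                     "mean_red", "mean_green", "mean_green_norm"])
    return df.sort_values(["frame", "label"], kind="stable").reset_index(drop=True)


def links_from_truth(lineages: Sequence[GroundTruthLineage], config: SimulationConfig):
    """The true link table: consecutive-frame identity links within each cell
    and mother->daughter division edges at each division."""
    from .track import LinkTable

    rows = []
    for lin in lineages:
        for cell in lin.cells.values():
            f, p = cell.frames, cell.centroids_zyx
            for i in range(len(f) - 1):
                d = float(np.linalg.norm(p[i + 1] - p[i]))
                rows.append((int(f[i]), cell.cell_id, int(f[i + 1]), cell.cell_id,
                             d, int(f[i + 1] - f[i]), "link"))
            if cell.end_kind == "divides" and len(f):
                for kid in lin.children_of(cell.cell_id):
                    if kid.frames.size:
                        d = float(np.linalg.norm(kid.centroids_zyx[0] - p[-1]))
                        rows.append((int(f[-1]), cell.cell_id, int(kid.frames[0]), kid.cell_id,
                                     d, int(kid.frames[0] - f[-1]), "division_edge"))
    return LinkTable.from_records(rows)


def true_link_set(lineages: Sequence[GroundTruthLineage]) -> set:
    """All ground-truth temporal connections as ((frame, cell), (frame, cell))."""
    out = set()
    for lin in lineages:
        for cell in lin.cells.values():
            f = cell.frames
            for i in range(len(f) - 1):
                out.add(((int(f[i]), cell.cell_id), (int(f[i + 1]), cell.cell_id)))
            if cell.end_kind == "divides" and len(f):
                for kid in lin.children_of(cell.cell_id):
                    if kid.frames.size:
                        out.add(((int(f[-1]), cell.cell_id), (int(kid.frames[0]), kid.cell_id)))
    return out


def match_to_truth(observations, lineages: Sequence[GroundTruthLineage],
                   tol_px: float = 3.0):
    """Map measured observations to ground-truth cell ids by nearest true
    centroid at the same frame (within ``tol_px``); unmatched rows get -1.
    Returns a copy of the table with a ``true_cell`` column."""
    by_frame: dict[int, list[tuple[np.ndarray, int]]] = {}
    for lin in lineages:
        for cell in lin.cells.values():
            for i, f in enumerate(cell.frames):
                by_frame.setdefault(int(f), []).append((cell.centroids_zyx[i], cell.cell_id))
    obs = observations.copy()
    matched = np.full(len(obs), -1, dtype=int)
    pos = obs[["z", "y", "x"]].to_numpy()
    frames = obs["frame"].to_numpy()
    for i in range(len(obs)):
        cands = by_frame.get(int(frames[i]), [])
        best, best_d = -1, tol_px
        for p, cid in cands:
            d = float(np.linalg.norm(pos[i] - p))
            if d < best_d:
                best, best_d = cid, d
        matched[i] = best
    obs["true_cell"] = matched
    return obs
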