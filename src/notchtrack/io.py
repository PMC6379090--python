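"""File formats, configuration and the end-to-end pipeline.

Movies are multi-page OME-TIFF (axes TZCYX, red then green); observations,
links, edits, traces and summaries are plain CSV; trees are exported as
nested JSON and as Newick (labels = track ids, branch lengths = lifetimes in
hours).  A :class:`PipelineConfig` mirrors the per-stage parameter objects,
rejects unknown keys, and every run writes its fully-resolved configuration
(with a content hash) next to the outputs.  All randomness flows from the
single pipeline seed via derived per-stage seeds, so identical config + seed
reproduce identical output bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import lineage as lineage_mod
from . import segment as segment_mod
from . import simulate as simulate_mod
from . import stats as stats_mod
from . import track as track_mod
from .errors import ConfigurationError, FormatError
from .lineage import AnalysisParams
from .segment import SegmentationParams
from .simulate import MovieStack, NoiseParams, SimulationConfig
from .track import TrackingParams

logger = logging.getLogger(__name__)

STAGES = ["simulate", "segment", "link", "divisions", "normalize", "trees",
          "analyze", "stats"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    movie_path: str | None = None
    output_dir: str = "notchtrack_out"
    seed: int = 0
    log_level: str = "INFO"

    def derived_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)


def _build_dataclass(cls, data: dict, path: str):
    if data is None:
        return None
    if not isinstance(data, dict):
        raise ConfigurationError(f"section {path!r} must be a mapping")
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(field_map)
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in section {path!r}")
    kwargs = {}
    for key, value in data.items():
        f = field_map[key]
        if key == "noise" and isinstance(value, dict):
            value = _build_dataclass(NoiseParams, value, f"{path}.noise")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


_SECTIONS = {"simulation": SimulationConfig, "segmentation": SegmentationParams,
             "tracking": TrackingParams, "analysis": AnalysisParams}


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    unknown = set(data) - set(f.name for f in dataclasses.fields(PipelineConfig))
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build_dataclass(cls, data.pop(name), name)
    kwargs.update(data)
    return PipelineConfig(**kwargs)


def read_config(path) -> PipelineConfig:
    """Read a pipeline configuration from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_to_dict(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config_to_dict(config), sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# movies and labels
# ---------------------------------------------------------------------------

def write_movie(path, stack: MovieStack) -> None:
    """Write a two-channel movie as OME-TIFF with axes TZCYX."""
    data = np.ascontiguousarray(stack.data.transpose(0, 2, 1, 3, 4))  # T,Z,C,Y,X
    tifffile.imwrite(
        path, data, ome=True,
        metadata={
            "axes": "TZCYX",
            "PhysicalSizeZ": stack.voxel_size_um_zyx[0],
            "PhysicalSizeY": stack.voxel_size_um_zyx[1],
            "PhysicalSizeX": stack.voxel_size_um_zyx[2],
            "TimeIncrement": stack.frame_interval_min * 60.0,
            "TimeIncrementUnit": "s",
        })


def read_movie(path, axes: str | None = None, frame_interval_min: float | None = None,
               voxel_size_um_zyx: tuple[float, float, float] | None = None) -> MovieStack:
    """Read a two-channel TZCYX / TZYXC / TCZYX multi-page TIFF.

    Axes come from the TIFF metadata; if absent, an explicit ``axes`` string
    must be supplied (accepted with a warning).  Frame interval and voxel
    size overrides win over metadata.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = series.axes.upper()
        if set(file_axes) == set("TZYX") and axes is None:
            raise FormatError(
                f"expected 2 channels (red, green) but the TIFF has no channel axis "
                f"(axes {file_axes!r})")
        if set(file_axes) != set("TZCYX"):
            if axes is None:
                raise FormatError(
                    f"cannot interpret TIFF axes {file_axes!r}; expected a permutation "
                    "of TZCYX or an explicit axes override")
            logger.warning("axes metadata %r unusable; trusting override %r", file_axes, axes)
            file_axes = axes.upper()
        if sorted(file_axes) != sorted("TZCYX"):
            raise FormatError(f"axes {file_axes!r} is not a permutation of TZCYX")
        order = [file_axes.index(a) for a in "TCZYX"]
        data = np.ascontiguousarray(np.transpose(data, order))
        if data.shape[1] != 2:
            raise FormatError(f"expected 2 channels (red, green), found {data.shape[1]} "
                              f"(axes {file_axes!r})")
    return MovieStack(
        data=data.astype(np.float32),
        frame_interval_min=frame_interval_min if frame_interval_min is not None else 10.0,
        voxel_size_um_zyx=voxel_size_um_zyx or (0.5, 0.5, 0.5),
    )


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, labels.astype(np.uint16), ome=True, metadata={"axes": "TZYX"})


# ---------------------------------------------------------------------------
# ground truth and tree exports
# ---------------------------------------------------------------------------

def truth_table(lineages) -> pd.DataFrame:
    rows = [(c.cell_id,
             -1 if c.parent_id is None else c.parent_id,
             c.birth_time_h, c.end_time_h, c.role, lin.lineage_id)
            for lin in lineages for c in lin.cells.values()]
    return pd.DataFrame(rows, columns=["cell_id", "parent_id", "birth_h", "end_h",
                                       "role", "lineage_id"]).sort_values("cell_id") \
        .reset_index(drop=True)


def truth_events(lineages) -> list[dict]:
    events = []
    for lin in lineages:
        for c in lin.cells.values():
            if c.end_kind == "divides":
                kids = sorted(k.cell_id for k in lin.children_of(c.cell_id))
                events.append({"kind": "division", "time_h": c.end_time_h,
                               "mother": c.cell_id, "daughters": kids})
            if c.conversion_time_h is not None:
                events.append({"kind": "reactivation", "time_h": c.conversion_time_h,
                               "cell": c.cell_id})
    return sorted(events, key=lambda e: (e["time_h"], e.get("mother", e.get("cell"))))


def tree_to_dict(tree: lineage_mod.LineageTree, node: int | None = None) -> dict:
    node = tree.root if node is None else node
    attrs = tree.graph.nodes[node]
    return {
        "id": int(node),
        "role": tree.role(node),
        "birth_h": float(attrs["birth_time_h"]),
        "end_h": float(attrs["end_time_h"]),
        "children": [tree_to_dict(tree, k) for k in tree.children(node)],
    }


def forest_to_json(forest, path) -> None:
    with open(path, "w") as fh:
        json.dump([tree_to_dict(t) for t in forest], fh, indent=1)


def forest_from_json(path) -> list[lineage_mod.LineageTree]:
    """Read back a forest written by :func:`forest_to_json` (topology, roles
    and lifetimes; traces are not serialised in the tree export)."""
    import networkx as nx

    with open(path) as fh:
        data = json.load(fh)

    def add(graph: "nx.DiGraph", node: dict) -> None:
        graph.add_node(node["id"], role=node["role"], birth_time_h=node["birth_h"],
                       end_time_h=node["end_h"],
                       trace=pd.DataFrame(columns=["time_h", "mean_green_norm",
                                                   "equiv_diameter_px"]))
        for kid in node["children"]:
            add(graph, kid)
            graph.add_edge(node["id"], kid["id"])

    forest = []
    for root in data:
        g = nx.DiGraph()
        add(g, root)
        forest.append(lineage_mod.LineageTree(graph=g, root=root["id"]))
    return forest


def tree_to_newick(tree: lineage_mod.LineageTree) -> str:
    """Newick with integer track-id labels and lifetimes (h) as branch lengths."""

    def rec(node: int) -> str:
        attrs = tree.graph.nodes[node]
        length = max(attrs["end_time_h"] - attrs["birth_time_h"], 0.0)
        kids = tree.children(node)
        inner = "(" + ",".join(rec(k) for k in kids) + ")" if kids else ""
        return f"{inner}{node}:{length:.6g}"

    return rec(tree.root) + ";"


def forest_to_newick(forest, path) -> None:
    with open(path, "w") as fh:
        for tree in forest:
            fh.write(tree_to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, stop_after: str | None = None) -> dict:
    """Run the stages in order
    simulate? -> segment -> link -> divisions -> normalize -> trees ->
    analyze -> stats, writing every artifact into ``config.output_dir``.

    Returns a bundle with the in-memory results.  ``stop_after`` truncates
    the pipeline after the named stage.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ConfigurationError(f"stop_after must be one of {STAGES}")
    if not config.movie_path and config.simulation is None:
        raise ConfigurationError("config needs either movie_path or a simulation section")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    bundle: dict = {"config_hash": config_hash(config), "seed": config.seed}
    with open(out / "config.json", "w") as fh:
        json.dump({"hash": bundle["config_hash"], "seed": config.seed,
                   "config": config_to_dict(config)}, fh, indent=1, default=str)

    def done(stage: str) -> bool:
        return stop_after == stage

    # --- simulate / load -----------------------------------------------------
    lineages = None
    if config.movie_path:
        movie = read_movie(config.movie_path)
    elif config.simulation is not None:
        sim = dataclasses.replace(config.simulation,
                                  rng_seed=config.derived_seed("simulate"))
        lineages = simulate_mod.simulate_movie(sim)
        movie, truth_labels = simulate_mod.render_movie(lineages, sim)
        write_movie(out / "movie.ome.tif", movie)
        write_labels(out / "truth_labels.ome.tif", truth_labels)
        truth_table(lineages).to_csv(out / "truth_cells.csv", index=False)
        with open(out / "truth_events.json", "w") as fh:
            json.dump(truth_events(lineages), fh, indent=1)
        bundle["lineages"] = lineages
    else:
        raise ConfigurationError("config needs either movie_path or a simulation section")
    bundle["movie"] = movie
    if done("simulate"):
        return bundle

    # --- segment --------------------------------------------------------------
    labels, obs = segment_mod.segment_movie(movie, config.segmentation)
    write_labels(out / "labels.ome.tif", labels)
    bundle["labels"], bundle["observations"] = labels, obs
    if done("segment"):
        obs.to_csv(out / "observations.csv", index=False)
        return bundle

    # --- track ------------------------------------------------------------------
    links = track_mod.link_frames(obs, config.tracking)
    if done("link"):
        links.to_csv(out / "links.csv")
        obs.to_csv(out / "observations.csv", index=False)
        bundle["links"] = links
        return bundle
    links = track_mod.detect_divisions(links, obs, config.tracking)
    links.to_csv(out / "links.csv")
    bundle["links"] = links
    if done("divisions"):
        obs.to_csv(out / "observations.csv", index=False)
        return bundle

    obs = track_mod.normalize_green(obs)
    obs.to_csv(out / "observations.csv", index=False)
    bundle["observations"] = obs
    if done("normalize"):
        return bundle

    # --- trees + analysis -------------------------------------------------------
    forest = lineage_mod.build_trees(links, obs)
    for tree in forest:
        lineage_mod.classify_roles(tree, config.analysis)
    forest_to_json(forest, out / "trees.json")
    forest_to_newick(forest, out / "trees.nwk")
    lineage_mod.export_barchart(forest).to_csv(out / "barchart.csv", index=False)
    bundle["forest"] = forest
    if done("trees"):
        return bundle

    analysis = lineage_mod.analyze_forest(forest, config.analysis)
    with open(out / "analysis.json", "w") as fh:
        json.dump({"persistence_percent": analysis["persistence_percent"],
                   "persistence_flags": {str(k): bool(v) for k, v in
                                         analysis["persistence_flags"].items()},
                   "reactivations": analysis["reactivations"]}, fh, indent=1)
    analysis["gmc_decay_fits"].to_csv(out / "gmc_decay_fits.csv", index=False)
    bundle["analysis"] = analysis
    if done("analyze"):
        return bundle

    # --- count statistics ---------------------------------------------------------
    nb_rooted = [t for t in forest if t.role(t.root) == lineage_mod.ROLE_NB]
    counts = stats_mod.CountSample(
        "cells_per_lineage", tuple(float(len(t.nodes())) for t in nb_rooted) or (0.0,))
    summary = stats_mod.summarize_counts(counts)
    pd.DataFrame([dataclasses.asdict(summary)]).to_csv(out / "lineage_count_summary.csv",
                                                       index=False)
    bundle["count_summary"] = summary
    return bundle
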