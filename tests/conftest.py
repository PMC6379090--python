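import numpy as np
import pytest

import notchtrack as nt


@pytest.fixture(scope="session")
def small_noiseless_cfg() -> nt.SimulationConfig:
    """Two WT lineages, 6 h at 15-min frames, no image corruption."""
    return nt.SimulationConfig(
        duration_hours=6.0, frame_interval_min=15.0, condition="WT",
        n_lineages=2, volume_shape_zyx=(24, 200, 200),
        noise=nt.NoiseParams.off(), rng_seed=1)


@pytest.fixture(scope="session")
def rendered_small(small_noiseless_cfg):
    """Simulated + rendered + segmented small noiseless movie, shared across
    the segmentation / tracking / lineage tests."""
    cfg = small_noiseless_cfg
    lineages = nt.simulate_movie(cfg)
    movie, truth_labels = nt.render_movie(lineages, cfg)
    labels, obs = nt.segment_movie(movie, nt.SegmentationParams())
    params = nt.TrackingParams()
    links = nt.detect_divisions(nt.link_frames(obs, params), obs, params)
    return {"cfg": cfg, "lineages": lineages, "movie": movie,
            "truth_labels": truth_labels, "labels": labels, "obs": obs,
            "links": links, "tracking_params": params}


@pytest.fixture
def sphere_volume():
    """Factory for synthetic volumes containing solid spheres."""

    def make(shape, spheres, value=100.0, dtype=np.float32):
        vol = np.zeros(shape, dtype=dtype)
        zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
        for (cz, cy, cx, r) in spheres:
            vol[((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) <= r * r] = value
        return vol

    return make
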