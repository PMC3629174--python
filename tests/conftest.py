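import numpy as np
import pytest

from plasmakaryo import (Genome, build_bins)
from plasmakaryo.pipeline import (PipelineParams, build_panel_from_frames,
                                  sample_gr_profile)
from plasmakaryo.synthetic_data import (Implant, SyntheticSpec,
                                        generate_panel, generate_sample,
                                        synthetic_gc_track)


@pytest.fixture(scope="session")
def toy_genome():
    return Genome.from_dict({"chrA": 5_000_000, "chrB": 2_300_000})


@pytest.fixture(scope="session")
def default_spec():
    """Synthetic cohort conditions: 10% fetal fraction, one 3-Mb fetal deletion."""
    return SyntheticSpec(
        implants=(Implant("chr2", 5_000_000, 8_000_000, -1, "fetal"),),
        fetal_fraction=0.10,
        seed=11,
    )


@pytest.fixture(scope="session")
def params():
    return PipelineParams()


@pytest.fixture(scope="session")
def cohort(default_spec, params):
    """One fully processed synthetic cohort, shared across tests.

    Returns dict with the fine grid, GC track, built reference panel, the
    affected test sample's fragment frame, truth record and GR profile.
    """
    spec = default_spec
    grid = spec.grid()
    gc = synthetic_gc_track(spec)
    panel_frames = generate_panel(spec)
    panel = build_panel_from_frames(panel_frames, grid, gc, params)
    test_rng = np.random.default_rng(997)
    frame, truth = generate_sample(spec, rng=test_rng)
    profile = sample_gr_profile(frame, grid, gc, params)
    return {
        "spec": spec, "grid": grid, "gc": gc,
        "panel_frames": panel_frames, "panel": panel,
        "test_frame": frame, "truth": truth, "profile": profile,
    }
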