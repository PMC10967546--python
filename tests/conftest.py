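"""Shared fixtures: generated sequences and cached tracking runs.

Tracking runs are session-scoped because they are the expensive part of the
suite; every test reads from the cached results rather than re-tracking.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cftrack.config import TrackerConfig
from cftrack.io_formats import read_annotation
from cftrack.pipeline import track_sequence
from cftrack.synthetic import ScenarioSpec, fixture_suite, generate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def _spec(name: str) -> ScenarioSpec:
    return next(s for s in fixture_suite(0) if s.name == name)


@pytest.fixture(scope="session")
def easy_sequence(tmp_path_factory):
    out = tmp_path_factory.mktemp("seq_easy")
    return generate(_spec("easy_translation"), out)


@pytest.fixture(scope="session")
def occlusion_sequence(tmp_path_factory):
    out = tmp_path_factory.mktemp("seq_occ")
    return generate(_spec("full_occlusion"), out)


@pytest.fixture(scope="session")
def tiny_sequence(tmp_path_factory):
    """A fast, small sequence for smoke/determinism/CLI tests."""
    out = tmp_path_factory.mktemp("seq_tiny")
    spec = ScenarioSpec(
        name="tiny", canvas=(120, 160), n_frames=15, init_box=(40, 50, 24, 20),
        velocity=(2.0, 1.0), noise_sigma=0.01, seed=5,
    )
    seq, ann, ev = generate(spec, out)
    return out, seq, ann, ev


@pytest.fixture(scope="session")
def easy_run(easy_sequence):
    seq, ann, ev = easy_sequence
    result = track_sequence(seq, ann.boxes[0], TrackerConfig())
    return seq, ann, ev, result


@pytest.fixture(scope="session")
def occlusion_run(occlusion_sequence):
    seq, ann, ev = occlusion_sequence
    result = track_sequence(seq, ann.boxes[0], TrackerConfig())
    return seq, ann, ev, result


@pytest.fixture(scope="session")
def hard_runs(tmp_path_factory):
    """Full method and both ablations on the hard fixture subset."""
    from cftrack.synthetic import HARD_FIXTURES

    runs = {}
    for name in HARD_FIXTURES:
        out = tmp_path_factory.mktemp(f"seq_{name}")
        seq, ann, ev = generate(_spec(name), out)
        variants = {
            "full": TrackerConfig(),
            "no_update": TrackerConfig(disable_update=True),
            "no_fusion": TrackerConfig(disable_fusion_selection=True),
        }
        runs[name] = (ann, ev, {k: track_sequence(seq, ann.boxes[0], c) for k, c in variants.items()})
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
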