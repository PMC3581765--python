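"""Shared fixtures: synthetic sessions and their evaluation grids.

The expensive end-to-end artifacts are session-scoped so the integration
and acceptance tests share them. Run durations are scaled to 16 s per run
(vs the protocol's 65 s) to keep the suite fast; fold structure, window
counts per block, and all orderings under test are unaffected.
"""

from __future__ import annotations

import pytest

from emgkin import pipeline, synthdata

SESSION_SEED = 11
DURATION_S = 16.0
MINI_DURATION_S = 4.0


def _session_results(tmp_path_factory, name, sigma_gain, sigma_base):
    d = tmp_path_factory.mktemp(name)
    cfg = synthdata.EmgSynthConfig(
        sigma_gain=sigma_gain, sigma_base=sigma_base, seed=SESSION_SEED)
    synthdata.generate_session(
        d, duration_s=DURATION_S, emg_config=cfg, master_seed=SESSION_SEED)
    pc = pipeline.PipelineConfig(master_seed=SESSION_SEED)
    res = pipeline.run_pipeline(pc, d / "manifest.tsv", out_dir=d / "results")
    res["session_dir"] = d
    res["config"] = pc
    return res


@pytest.fixture(scope="session")
def effect_results(tmp_path_factory):
    """Full pipeline results with a moderate arm-position effect (sigma_g=0.3)."""
    return _session_results(tmp_path_factory, "effect_session", 0.3, 0.02)


@pytest.fixture(scope="session")
def null_results(tmp_path_factory):
    """Full pipeline results with the arm-position effect switched off."""
    return _session_results(tmp_path_factory, "null_session", 0.0, 0.0)


@pytest.fixture(scope="session")
def mini_session(tmp_path_factory):
    """A small complete session for I/O, CLI, and plumbing tests."""
    d = tmp_path_factory.mktemp("mini_session")
    cfg = synthdata.EmgSynthConfig(sigma_gain=0.2, sigma_base=0.01, seed=5)
    manifest = synthdata.generate_session(
        d, duration_s=MINI_DURATION_S, emg_config=cfg,
        marker_noise_mm=0.2, master_seed=5)
    return d, manifest
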