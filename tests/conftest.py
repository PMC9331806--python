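"""Shared fixtures: the default synthetic cohort run, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from palmraman.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full default pipeline run (47-fruit three-class cohort, seed 0).

    Returns ``(report, out_dir)``; several test modules share it because the
    end-to-end artifacts (features.csv, anova.csv, peaks.csv) feed many checks.
    """
    out = tmp_path_factory.mktemp("default_run")
    report = run_pipeline(PipelineConfig(seed=0, out_dir=str(out)))
    return report, out


@pytest.fixture(scope="session")
def default_features(default_run):
    """Feature table and labels of the default cohort run."""
    import pandas as pd

    _, out = default_run
    table = pd.read_csv(out / "features.csv")
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
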