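"""Shared fixtures: panels, layouts and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seroarray.layout import AntigenPanel, build_default_panel, build_slide_layout
from seroarray.normalize import AntigenMatrix, normalize_cohort
from seroarray.simulate import SampleMeta, SimConfig, simulate_cohort
from seroarray.spots import process_array

NO_ARTIFACTS = {"high_background": 0.0, "speckle": 0.0, "doughnut": 0.0, "saturated": 0.0}


@pytest.fixture(scope="session")
def panel() -> AntigenPanel:
    return build_default_panel()


@pytest.fixture(scope="session")
def layout(panel):
    return build_slide_layout(panel, seed=0)


def clean_config(**overrides) -> SimConfig:
    """Artifact-free, unit-gain simulation config for targeted tests."""
    defaults = dict(artifact_rates=dict(NO_ARTIFACTS), gain_log_sd=0.0, seed=1)
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort(layout):
    """6/6/6 artifact-free cohort plus its QC products."""
    cfg = clean_config(n_per_group={"PCa": 6, "BPH": 6, "DC": 6}, seed=11)
    meta, scans = simulate_cohort(layout, cfg)
    collapsed, summaries = {}, []
    for scan in scans:
        sigs, summ = process_array(scan, layout)
        collapsed[scan.sample_id] = sigs
        summaries.append(summ)
    return meta, scans, collapsed, summaries


@pytest.fixture(scope="session")
def small_matrix(small_cohort) -> AntigenMatrix:
    meta, _, collapsed, summaries = small_cohort
    return normalize_cohort(collapsed, summaries, meta)


def make_matrix(
    values: np.ndarray,
    groups: list[str],
    antigen_ids: list[str] | None = None,
    ethnicities: list[str] | None = None,
) -> AntigenMatrix:
    """Build an AntigenMatrix directly from a values array and group labels."""
    n, m = values.shape
    antigen_ids = antigen_ids or [f"AG{j:03d}" for j in range(m)]
    sample_ids = [f"S{i:03d}" for i in range(n)]
    meta = [
        SampleMeta(
            sample_ids[i], groups[i], 60,
            ethnicity=ethnicities[i] if ethnicities else None,
        )
        for i in range(n)
    ]
    vdf = pd.DataFrame(values, index=sample_ids, columns=antigen_ids)
    fdf = pd.DataFrame(
        [[frozenset()] * m for _ in range(n)], index=sample_ids, columns=antigen_ids
    )
    return AntigenMatrix(vdf, fdf, meta)
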