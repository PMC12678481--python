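"""Shared fixtures: one calibrated-control run and small fast configs."""

import pandas as pd
import pytest

from histodyn import calibrated_control, scenario_config, simulate_embryo


@pytest.fixture(scope="session")
def control_run():
    """Full calibrated-control simulation (both channels), seed 0."""
    return simulate_embryo(calibrated_control(seed=0))


@pytest.fixture(scope="session")
def control_run_clean():
    """Noise-free control simulation for exact-property checks."""
    return simulate_embryo(calibrated_control(seed=0, noise_cv=0.0,
                                              background=0.0))


@pytest.fixture(scope="session")
def shkl_run():
    return simulate_embryo(scenario_config("shkl", seed=0))


@pytest.fixture(scope="session")
def hira_run():
    return simulate_embryo(scenario_config("hira_ssm", seed=0))


def small_config(seed=0, n_cycles=2, n_start=6, **overrides):
    """A fast two-cycle embryo for structural tests."""
    cfg = calibrated_control(seed=seed, start_nucleus_count=n_start,
                             embryo_length=90.0, embryo_width=55.0)
    sched = {nc: cfg.cycle_schedule[nc]
             for nc in list(sorted(cfg.cycle_schedule))[:n_cycles]}
    cfg = cfg.replace(cycle_schedule=sched)
    return cfg.replace(**overrides) if overrides else cfg


@pytest.fixture()
def tiny_track_table():
    """Hand-built two-cycle TrackTable with known values."""
    rows = []
    # NC10: two nuclei, NC13: one nucleus (ids 0,1 -> 2)
    for nid, total in ((0, 90.0), (1, 110.0)):
        for f in range(3):
            rows.append(dict(nucleus_id=nid, parent_id=-1, cycle=10, frame=f,
                             t=45.0 * f, x=10.0 * (nid + 1), y=10.0, z=5.0,
                             volume=100.0 + 10 * f, phase="interphase",
                             total_ch=total, mean_ch=total / (100.0 + 10 * f)))
        for f in (3, 4):
            rows.append(dict(nucleus_id=nid, parent_id=-1, cycle=10, frame=f,
                             t=45.0 * f, x=10.0 * (nid + 1), y=10.0, z=5.0,
                             volume=40.0, phase="mitosis",
                             total_ch=total, mean_ch=total / 40.0))
    for f in range(5, 8):
        rows.append(dict(nucleus_id=2, parent_id=0, cycle=13, frame=f,
                         t=45.0 * f, x=10.0, y=10.0, z=5.0,
                         volume=80.0 + 10 * (f - 5), phase="interphase",
                         total_ch=40.0, mean_ch=40.0 / (80.0 + 10 * (f - 5))))
    rows.append(dict(nucleus_id=2, parent_id=0, cycle=13, frame=8, t=360.0,
                     x=10.0, y=10.0, z=5.0, volume=40.0, phase="mitosis",
                     total_ch=40.0, mean_ch=1.0))
    return pd.DataFrame(rows)
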