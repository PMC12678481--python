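"""Simulation and analysis configuration.

The simulator models the cortical nuclear sheet of a syncytial *Drosophila*
embryo during the pre-ZGA nuclear cycles (NC10 onward).  Nuclei double each
cycle, grow to a per-cycle maximum volume, and compete for shared, depleting
cytoplasmic pools of H3-family histones.  Two incorporation pathways are
modelled: replication-dependent deposition during S-phase (canonical H3 and
the H3-like ASVM chimera) and replication-independent deposition gated by
cell-cycle state and local nuclear density (H3.3).

All intensity-like quantities are in arbitrary units (a.u.), lengths in
micrometres, times in seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "SpeciesParams",
    "CyclePhase",
    "SimConfig",
    "AnalysisParams",
    "calibrated_control",
    "scenario_config",
    "SCENARIOS",
]

RD = "rd"  # replication-dependent (S-phase coupled) incorporation
RI = "ri"  # replication-independent (gated) incorporation

SCENARIOS = ("control", "shkl", "hira_ssm", "slbp", "zelda", "chk1")


@dataclass(frozen=True)
class SpeciesParams:
    """Kinetic parameters for one tagged histone species (one channel).

    Parameters
    ----------
    name
        Channel name used for TrackTable columns (e.g. ``"H3"``).
    pool
        Initial cytoplasmic pool, a.u.
    synthesis_rate
        Zeroth-order cytoplasmic synthesis, a.u./s (maternal translation).
    k_import
        Import coefficient; nuclear influx is
        ``k_import * (pool/V_embryo) * V_nuc**(2/3) / (1 + beta * n_neighbors)``
        in a.u./s, i.e. surface-area-scaled uptake from the local cytoplasm.
    k_inc
        First-order chromatin incorporation rate, 1/s, acting on the free
        nuclear amount.
    pathway
        ``"rd"``: deposition proportional to the unreplicated genome fraction,
        S-phase only.  ``"ri"``: deposition gated by cell-cycle state.
    gate_gamma
        Per-NC cell-cycle-state gate for RI incorporation (scalar or
        ``{nc: value}`` mapping).  Rises over the pre-ZGA cycles as the N/C
        ratio climbs; scenario perturbations scale or abolish it.
    gate_density_exp
        Within a cycle the gate is further modulated by local crowding:
        ``(n / n_mean_of_cycle) ** q``, so nuclei in denser neighborhoods
        incorporate relatively more RI histone than sparse ones.
    """

    name: str
    pool: float
    synthesis_rate: float = 0.0
    k_import: float = 0.5
    k_inc: float = 3e-3
    pathway: str = RD
    gate_gamma: float | Mapping[int, float] = 1.0
    gate_density_exp: float = 1.5
    init_bound: float = 0.0  # chromatin carried into the first simulated cycle
    beta: float | None = None  # crowding sensitivity; None -> SimConfig default

    def gamma(self, cycle: int) -> float:
        if isinstance(self.gate_gamma, Mapping):
            return float(self.gate_gamma.get(cycle, 1.0))
        return float(self.gate_gamma)

    def __post_init__(self) -> None:
        if self.pathway not in (RD, RI):
            raise ValueError(f"pathway must be 'rd' or 'ri', got {self.pathway!r}")
        if (self.pool < 0 or self.synthesis_rate < 0 or self.k_import < 0
                or self.k_inc < 0 or self.init_bound < 0):
            raise ValueError(f"species {self.name!r}: pools and rates must be >= 0")


@dataclass(frozen=True)
class CyclePhase:
    """Durations (s) for one nuclear cycle: interphase, mitosis, S-phase."""

    interphase: float
    mitosis: float
    s_phase: float | None = None  # defaults to the full interphase

    def __post_init__(self) -> None:
        if self.interphase <= 0 or self.mitosis <= 0:
            raise ValueError("non-positive cycle phase duration")
        if self.s_phase is not None and self.s_phase <= 0:
            raise ValueError("non-positive S-phase duration")

    @property
    def s_dur(self) -> float:
        return self.interphase if self.s_phase is None else min(self.s_phase, self.interphase)

    @property
    def total(self) -> float:
        return self.interphase + self.mitosis


def _default_schedule() -> dict[int, CyclePhase]:
    # Interphase lengthens with each cycle; mitosis is roughly constant; the
    # S-phase fraction of interphase shrinks as a G2-like gap appears late.
    return {
        10: CyclePhase(420.0, 180.0, 360.0),
        11: CyclePhase(495.0, 180.0, 340.0),
        12: CyclePhase(630.0, 180.0, 540.0),
        13: CyclePhase(1080.0, 180.0, 900.0),
    }


def _haploid_schedule() -> dict[int, CyclePhase]:
    # Haploid embryos slow their cycles one division later and run an extra
    # syncytial cycle (NC14) before ZGA.
    return {
        10: CyclePhase(420.0, 180.0, 340.0),
        11: CyclePhase(450.0, 180.0, 380.0),
        12: CyclePhase(495.0, 180.0, 430.0),
        13: CyclePhase(630.0, 180.0, 500.0),
        14: CyclePhase(1080.0, 180.0, 900.0),
    }


def _default_vmax() -> dict[int, float]:
    # Maximum nuclear volume attained in each cycle falls as nuclei double.
    return {10: 525.0, 11: 400.0, 12: 290.0, 13: 190.0, 14: 150.0}


@dataclass
class SimConfig:
    """Full parameterization of one simulated embryo.

    Geometry is a 2-D cortical sheet (``embryo_length`` x ``embryo_width``)
    at height ``sheet_z`` with small z jitter; a fraction of boundary nuclei
    sit >= ``edge_z_offset`` below the sheet, emulating the incomplete edge
    nuclei that the Z-coordinate filter removes in real data.
    """

    # geometry
    embryo_length: float = 500.0
    embryo_width: float = 180.0
    embryo_depth: float = 40.0  # cytoplasmic depth used for the pool concentration
    sheet_z: float = 5.0
    z_jitter: float = 0.3
    edge_fraction: float = 0.10
    edge_z_offset: float = 3.0

    # cycle program
    start_cycle: int = 10
    start_nucleus_count: int = 64
    cycle_schedule: dict[int, CyclePhase] = field(default_factory=_default_schedule)
    v_max: dict[int, float] = field(default_factory=_default_vmax)
    v_min: float = 65.0
    v_max_cv: float = 0.04  # per-nucleus spread of the attained maximum volume
    volume_ramp: float = 6.0  # e-folding steepness of interphase volume growth
    mitotic_volume: float = 40.0  # apparent chromatin-mass volume during mitosis
    ploidy: float = 1.0  # genome dose; 0.5 for haploids (halved deposition capacity)

    # kinetics
    species: tuple[SpeciesParams, ...] = ()
    beta_competition: float = 0.8

    # scenario
    scenario: str = "control"
    scenario_params: dict = field(default_factory=dict)

    # imaging / noise
    noise_cv: float = 0.05
    volume_cv: float = 0.03
    background: float = 20.0
    bleach_per_frame: float = 1.0
    frame_interval: float = 45.0
    dt: float = 5.0
    conversion_efficiency: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("SimConfig needs at least one species channel")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.dt <= 0 or self.frame_interval <= 0:
            raise ValueError("dt and frame_interval must be positive")
        ratio = self.frame_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("frame_interval must be an integer multiple of dt")
        if not 0.0 < self.bleach_per_frame <= 1.0:
            raise ValueError("bleach_per_frame must lie in (0, 1]")
        p = self.scenario_params.get("arrest_probability")
        if p is not None and not 0.0 <= p <= 1.0:
            raise ValueError("arrest_probability must lie in [0, 1]")
        if self.noise_cv < 0 or self.background < 0:
            raise ValueError("noise_cv and background must be >= 0")
        for nc in range(self.start_cycle, max(self.cycle_schedule) + 1):
            if nc not in self.cycle_schedule:
                raise ValueError(f"cycle_schedule is missing NC{nc}")

    # -- helpers -----------------------------------------------------------

    @property
    def embryo_volume(self) -> float:
        return self.embryo_length * self.embryo_width * self.embryo_depth

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_by_name(self, name: str) -> SpeciesParams:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def vmax_for(self, cycle: int) -> float:
        if cycle in self.v_max:
            return self.v_max[cycle]
        return min(self.v_max.values())

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = [dataclasses.asdict(s) for s in self.species]
        d["cycle_schedule"] = {
            int(k): [v.interphase, v.mitosis, v.s_phase] for k, v in self.cycle_schedule.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["species"] = tuple(SpeciesParams(**s) for s in d.get("species", []))
        d["cycle_schedule"] = {
            int(k): CyclePhase(*v) for k, v in d.get("cycle_schedule", {}).items()
        }
        if "v_max" in d:
            d["v_max"] = {int(k): float(v) for k, v in d["v_max"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of the quantification pipeline.

    ``neb_lookback`` (s) sets the "45 s before NEB" concentration timepoint;
    ``slope_window`` the number of leading timepoints of an aligned import
    curve entering the initial-rate regression; ``neighbor_radius`` (um) the
    fixed-radius local-density count; ``region_box_px`` the side of the
    middle/pole analysis boxes in pixels (converted via ``pixel_size_um``);
    ``nc11_reference_duration`` the duration (s) the control NC11 mean is
    normalized to.
    """

    neb_lookback: float = 45.0
    slope_window: int = 5
    neighbor_radius: float = 20.0
    region_box_px: int = 250
    pixel_size_um: float = 0.149
    reference_cycle: int = 10
    nc11_reference_duration: float = 600.0
    z_edge_threshold: float = 2.0
    t0_search_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.slope_window < 2:
            raise ValueError("slope_window must be >= 2")
        for name in ("neb_lookback", "neighbor_radius", "region_box_px",
                     "pixel_size_um", "nc11_reference_duration", "z_edge_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def region_box_um(self) -> float:
        return self.region_box_px * self.pixel_size_um


# ---------------------------------------------------------------------------
# Calibrated default configurations
# ---------------------------------------------------------------------------

def _h3(**kw) -> SpeciesParams:
    base = dict(name="H3", pool=3.0e5, synthesis_rate=30.0, k_import=3.4,
                k_inc=3.7e-3, pathway=RD, init_bound=60.0, beta=0.35)
    base.update(kw)
    return SpeciesParams(**base)


def _h33(**kw) -> SpeciesParams:
    base = dict(name="H33", pool=1.6e5, synthesis_rate=0.0, k_import=0.50,
                k_inc=2.6e-3, pathway=RI,
                gate_gamma={10: 0.08, 11: 0.25, 12: 0.48, 13: 0.33, 14: 0.33},
                gate_density_exp=1.5, beta=0.7, init_bound=10.0)
    base.update(kw)
    return SpeciesParams(**base)


def _asvm(**kw) -> SpeciesParams:
    # H3.3(ASVM) chimera: protein-identical to H3, expressed from the H3.3A
    # locus -> replication-coupled deposition from a modest but slowly
    # depleting pool (low per-genome demand relative to supply).
    base = dict(name="ASVM", pool=2.0e5, synthesis_rate=0.0, k_import=0.30,
                k_inc=2.0e-3, pathway=RD, init_bound=15.0, beta=0.4)
    base.update(kw)
    return SpeciesParams(**base)


def calibrated_control(seed: int = 0, **overrides) -> SimConfig:
    """The shipped calibrated-control configuration (H3 + H3.3 channels)."""
    cfg = SimConfig(species=(_h3(), _h33()), scenario="control", seed=seed)
    return cfg.replace(**overrides) if overrides else cfg


def scenario_config(scenario: str, seed: int = 0, **overrides) -> SimConfig:
    """Calibrated configuration for a perturbation scenario.

    Scenarios
    ---------
    control
        Wild-type embryo, NC10-NC13.
    shkl
        Anterior/posterior nuclear-density gradient, asynchronous mitotic
        wave, partial extra NC14 division in the sparse posterior.
    hira_ssm
        Haploid; H3.3 incorporation gate abolished; one extra cycle (NC14);
        carries an additional ASVM chimera channel.
    slbp
        H3 pool scaled down; elongated NC12; 60% of embryos arrest in NC13
        (no NC13 mitosis).
    zelda
        Transcription knockdown: long NC13, incorporation untouched.
    chk1
        Checkpoint mutant: cycles shortened from NC12 and the H3.3 gate
        scaled down from NC12.
    """
    if scenario == "control":
        return calibrated_control(seed=seed, **overrides)
    if scenario == "shkl":
        sched = _default_schedule()
        sched[14] = CyclePhase(660.0, 180.0, 540.0)  # partial posterior division
        cfg = SimConfig(
            species=(_h3(), _h33()),
            scenario="shkl",
            cycle_schedule=sched,
            scenario_params={
                "density_gradient_slope": 1.6,
                "async_span": 90.0,       # mitotic-wave spread across the embryo, s
                "nc14_count_quantile": 0.25,  # sparsest quartile divides again
            },
            seed=seed,
        )
    elif scenario == "hira_ssm":
        cfg = SimConfig(
            species=(_h3(), _h33(gate_gamma=0.0), _asvm()),
            scenario="hira_ssm",
            cycle_schedule=_haploid_schedule(),
            ploidy=0.5,
            scenario_params={"gate_scale": 0.0},
            seed=seed,
        )
    elif scenario == "slbp":
        sched = _default_schedule()
        sched[12] = CyclePhase(sched[12].interphase * 1.4, 180.0, sched[12].s_dur * 1.4)
        cfg = SimConfig(
            species=(_h3(pool=3.0e5 * 0.25), _h33()),
            scenario="slbp",
            cycle_schedule=sched,
            scenario_params={"pool_scale": 0.25, "arrest_probability": 0.60,
                             "arrest_cycle": 13},
            seed=seed,
        )
    elif scenario == "zelda":
        sched = _default_schedule()
        sched[13] = CyclePhase(sched[13].interphase * 1.4, 180.0, sched[13].s_dur)
        cfg = SimConfig(species=(_h3(), _h33()), scenario="zelda",
                        cycle_schedule=sched, seed=seed)
    elif scenario == "chk1":
        shorten = 60.0  # NC12 only ~1 min faster than wildtype
        sched = _default_schedule()
        for nc in (12, 13):
            ph = sched[nc]
            sched[nc] = CyclePhase(max(ph.interphase - shorten, 120.0), ph.mitosis,
                                   min(ph.s_dur, max(ph.interphase - shorten, 120.0)))
        base_gate = dict(_h33().gate_gamma)
        gate = {nc: g * (0.5 if nc >= 12 else 1.0) for nc, g in base_gate.items()}
        cfg = SimConfig(
            species=(_h3(), _h33(gate_gamma=gate)),
            scenario="chk1",
            cycle_schedule=sched,
            scenario_params={"cycle_shortening": shorten, "gate_scale": 0.5},
            seed=seed,
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return cfg.replace(**overrides) if overrides else cfg
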