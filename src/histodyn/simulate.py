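"""Agent-based simulator of histone dynamics on the syncytial cortex.

Each nucleus carries free and chromatin-bound amounts of every configured
histone species.  During interphase it imports histone from a shared,
depleting cytoplasmic pool at a rate scaled by its surface area and reduced
by local crowding; chromatin incorporation transfers free histone onto
chromatin through either a replication-coupled (S-phase) or a gated,
replication-independent pathway.  At nuclear envelope breakdown (NEB) the
free nuclear pool returns to the cytoplasm; at division the chromatin-bound
amount splits equally between the two daughters.  Mass is conserved exactly
per species: cytoplasm + sum(free) + sum(bound) = initial pool + synthesis.

Green-to-red photoconversion events convert the entire nuclear content of a
target nucleus; thereafter the red sub-pool obeys the same incorporation
kinetics with no import (the cytoplasm holds no red) and no export, so total
nuclear red is non-decreasing until NEB.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import RD, RI, SimConfig

__all__ = ["ConversionEvent", "GroundTruth", "simulate_embryo",
           "apply_photoconversion", "photoconvert_mid_cycle"]

logger = logging.getLogger(__name__)

INTERPHASE = "interphase"
MITOSIS = "mitosis"


@dataclass(frozen=True)
class ConversionEvent:
    """Instantaneous green-to-red photoconversion of one nucleus."""

    nucleus_id: int
    t_conv: float


@dataclass
class GroundTruth:
    """Noise-free simulator state, the oracle for every pipeline stage.

    Attributes
    ----------
    pools
        Per frame and species: cytoplasmic, summed nuclear free, summed
        chromatin amounts, cumulative synthesis and the initial pool.
    import_rates
        True instantaneous import flux (a.u./s) per nucleus, frame, species.
    free_fractions
        Per nucleus/cycle/species the free fraction free/(free+bound) at NEB;
        for photoconverted nuclei also the red-based fraction.
    nuclei
        Registry of every nucleus: lineage, cycle timing, position, neighbor
        count at its cycle start, sub-cortical (edge) flag and fate.
    cycle_times
        Per cycle: mean interphase start, mean metaphase time, durations.
    """

    pools: pd.DataFrame
    import_rates: pd.DataFrame
    free_fractions: pd.DataFrame
    nuclei: pd.DataFrame
    cycle_times: pd.DataFrame
    arrested: bool
    conversions: tuple[ConversionEvent, ...] = ()

    def mass_balance_residual(self) -> pd.Series:
        """Max relative mass-balance residual per species over all frames."""
        g = self.pools.copy()
        g["total"] = g["cytoplasm"] + g["nuclear_free"] + g["chromatin"]
        g["expected"] = g["initial"] + g["synthesized"]
        g["resid"] = (g["total"] - g["expected"]).abs() / g["expected"].where(
            g["expected"] > 0, 1.0)
        return g.groupby("species")["resid"].max()


def _lognorm_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv)) if cv > 0 else 0.0


class _State:
    """Flat per-nucleus arrays for all currently alive nuclei."""

    def __init__(self, n: int, n_species: int):
        self.ids = np.zeros(n, dtype=np.int64)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.cycle = np.zeros(n, dtype=np.int64)
        self.t0 = np.zeros(n)
        self.ti = np.zeros(n)
        self.tm = np.zeros(n)
        self.ts = np.zeros(n)
        self.pos = np.zeros((n, 3))
        self.vmax = np.zeros(n)
        self.nnb = np.zeros(n, dtype=np.int64)
        self.edge = np.zeros(n, dtype=bool)
        self.neb = np.zeros(n, dtype=bool)
        self.arrested = np.zeros(n, dtype=bool)
        self.fg = np.zeros((n, n_species))
        self.bg = np.zeros((n, n_species))
        self.fr = np.zeros((n, n_species))
        self.br = np.zeros((n, n_species))

    def __len__(self) -> int:
        return len(self.ids)

    def take(self, idx: np.ndarray) -> "_State":
        out = _State(0, self.fg.shape[1])
        for name, val in vars(self).items():
            setattr(out, name, val[idx])
        return out

    @staticmethod
    def concat(a: "_State", b: "_State") -> "_State":
        out = _State(0, a.fg.shape[1])
        for name in vars(a):
            setattr(out, name, np.concatenate([getattr(a, name), getattr(b, name)]))
        return out


def _relax(pos: np.ndarray, bounds: tuple[float, float], d_min: float,
           n_iter: int, step: float = 0.5) -> np.ndarray:
    """Soft-repulsion relaxation of in-sheet positions (xy only).

    Pairs closer than ``d_min`` push apart by ``step`` times their overlap
    each iteration; positions are clipped to the sheet bounds.
    """
    lx, ly = bounds
    pos = pos.copy()
    for _ in range(n_iter):
        tree = cKDTree(pos[:, :2])
        pairs = tree.query_pairs(d_min, output_type="ndarray")
        if len(pairs) == 0:
            break
        delta = pos[pairs[:, 0], :2] - pos[pairs[:, 1], :2]
        dist = np.linalg.norm(delta, axis=1)
        dist = np.where(dist < 1e-9, 1e-9, dist)
        push = (d_min - dist) / dist * step
        shift = delta * push[:, None]
        np.add.at(pos[:, :2], pairs[:, 0], shift)
        np.add.at(pos[:, :2], pairs[:, 1], -shift)
        pos[:, 0] = np.clip(pos[:, 0], 0.0, lx)
        pos[:, 1] = np.clip(pos[:, 1], 0.0, ly)
    return pos


class _Simulator:
    def __init__(self, config: SimConfig,
                 conversions: tuple[ConversionEvent, ...] = ()):
        self.cfg = config
        self.conversions = tuple(sorted(conversions, key=lambda c: c.t_conv))
        ss = np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x5D])
        init_ss, bio_ss, noise_ss = ss.spawn(3)
        self.rng_init = np.random.default_rng(init_ss)
        self.rng_bio = np.random.default_rng(bio_ss)
        self.rng_noise = np.random.default_rng(noise_ss)
        self.n_species = len(config.species)
        self._next_id = 0
        self._pool = np.array([s.pool for s in config.species], dtype=float)
        self._initial = self._pool.copy()
        self._red_cyto = np.zeros(self.n_species)
        # chromatin of nuclei whose tracking ended (kept for mass balance)
        self._retired_chromatin = np.zeros(self.n_species)
        self._synth = np.zeros(self.n_species)
        self._synth_rate = np.array([s.synthesis_rate for s in config.species])
        self._rows: list[dict] = []
        self._pool_rows: list[dict] = []
        self._rate_rows: list[dict] = []
        self._ff_rows: list[dict] = []
        self._registry: list[dict] = []
        self._cycle_starts: dict[int, list[float]] = {}
        self._cycle_meta: dict[int, list[float]] = {}
        self._nc13_counts: list[int] = []
        self._nnb_sum: dict[int, float] = {}
        self._nnb_cnt: dict[int, int] = {}
        self._nc14_ids: set[int] | None = None
        self._pool_warned = False
        self._done_conv: set[int] = set()
        self._converted_any = len(self.conversions) > 0
        # per-embryo arrest decision for the slbp scenario
        p_arr = config.scenario_params.get("arrest_probability", 0.0)
        self.embryo_arrests = bool(config.scenario == "slbp"
                                   and self.rng_bio.random() < p_arr)
        self.arrest_cycle = int(config.scenario_params.get("arrest_cycle", 13))

    # -- setup -------------------------------------------------------------

    def _initial_positions(self, n: int) -> np.ndarray:
        cfg = self.cfg
        lx, ly = cfg.embryo_length, cfg.embryo_width
        x = self.rng_init.uniform(0, lx, size=4 * n)
        if cfg.scenario == "shkl":
            slope = cfg.scenario_params.get("density_gradient_slope", 1.6)
            w = 1.0 + slope * (1.0 - np.abs(2.0 * x / lx - 1.0))
            keep = self.rng_init.uniform(0, 1 + slope, size=len(x)) < w
            x = x[keep]
        x = x[:n]
        while len(x) < n:  # pragma: no cover - rejection shortfall
            x = np.concatenate([x, self.rng_init.uniform(0, lx, size=n)])[:n]
        y = self.rng_init.uniform(0, ly, size=n)
        pos = np.column_stack([x, y, np.zeros(n)])
        d_typ = math.sqrt(lx * ly / n)
        n_iter = 8 if cfg.scenario == "shkl" else 30
        pos = _relax(pos, (lx, ly), 0.9 * d_typ, n_iter)
        return pos

    def _assign_z_and_edges(self, st: _State, idx: np.ndarray) -> None:
        cfg = self.cfg
        margin = 12.0
        x, y = st.pos[idx, 0], st.pos[idx, 1]
        d_edge = np.minimum.reduce([x, cfg.embryo_length - x, y,
                                    cfg.embryo_width - y])
        on_boundary = d_edge < margin
        draw = self.rng_bio.random(len(idx))
        edge = on_boundary & (draw < cfg.edge_fraction)
        z = cfg.sheet_z + self.rng_bio.normal(0.0, cfg.z_jitter, size=len(idx))
        z = np.where(edge, z - cfg.edge_z_offset, z)
        st.pos[idx, 2] = z
        st.edge[idx] = edge

    def _new_cohort(self, st: _State, idx: np.ndarray, cycle: int, t: float,
                    all_pos: np.ndarray) -> None:
        """Finalize per-cycle attributes for nuclei created at time t."""
        cfg = self.cfg
        phase = cfg.cycle_schedule[cycle]
        st.cycle[idx] = cycle
        st.t0[idx] = t
        st.ti[idx] = phase.interphase
        st.tm[idx] = phase.mitosis
        st.ts[idx] = phase.s_dur
        vbase = cfg.vmax_for(cycle)
        st.vmax[idx] = vbase * np.clip(
            1.0 + self.rng_bio.normal(0.0, cfg.v_max_cv, size=len(idx)), 0.5, 1.5)
        self._assign_z_and_edges(st, idx)
        tree = cKDTree(all_pos)
        counts = tree.query_ball_point(st.pos[idx], r=20.0, return_length=True)
        # the query set is part of all_pos, so subtract self-matches
        st.nnb[idx] = np.maximum(counts - 1, 0)
        if cfg.scenario == "slbp" and self.embryo_arrests and cycle >= self.arrest_cycle:
            st.arrested[idx] = True
        self._nnb_sum[cycle] = self._nnb_sum.get(cycle, 0.0) + float(st.nnb[idx].sum())
        self._nnb_cnt[cycle] = self._nnb_cnt.get(cycle, 0) + len(idx)
        if cycle == 13:
            self._nc13_counts.extend(int(c) for c in st.nnb[idx])
        self._cycle_starts.setdefault(cycle, []).extend([t] * len(idx))
        for i in idx:
            self._registry.append({
                "nucleus_id": int(st.ids[i]), "parent_id": int(st.parent[i]),
                "cycle": cycle, "t0": t, "interphase": st.ti[i],
                "mitosis": st.tm[i], "x": st.pos[i, 0], "y": st.pos[i, 1],
                "z": st.pos[i, 2], "v_max": st.vmax[i],
                "n_neighbors": int(st.nnb[i]), "is_edge": bool(st.edge[i]),
                "fate": "arrests" if st.arrested[i] else "divides",
            })

    def _init_state(self) -> _State:
        cfg = self.cfg
        n = cfg.start_nucleus_count
        st = _State(n, self.n_species)
        st.ids = np.arange(n, dtype=np.int64)
        self._next_id = n
        st.pos = self._initial_positions(n)
        self._new_cohort(st, np.arange(n), cfg.start_cycle, 0.0, st.pos)
        b0 = np.array([s.init_bound for s in cfg.species])
        st.bg[:] = b0[None, :]
        self._initial += n * b0  # inherited chromatin is part of the budget
        return st

    # -- kinetics ----------------------------------------------------------

    def _volume(self, st: _State, t: float) -> np.ndarray:
        tau = np.maximum(t - st.t0, 0.0)
        ramp = 1.0 - np.exp(-self.cfg.volume_ramp * tau / st.ti)
        return self.cfg.v_min + (st.vmax - self.cfg.v_min) * ramp

    def _import_rate(self, st: _State, vol: np.ndarray) -> np.ndarray:
        """True import flux (a.u./s), shape (N, S)."""
        cfg = self.cfg
        conc = self._pool / cfg.embryo_volume  # (S,)
        k_imp = np.array([s.k_import for s in cfg.species])
        # competition per neighbor scales with per-genome demand (ploidy)
        beta = cfg.ploidy * np.array(
            [cfg.beta_competition if s.beta is None else s.beta
             for s in cfg.species])
        crowd = 1.0 / (1.0 + beta[None, :] * st.nnb[:, None])  # (N, S)
        geom = vol ** (2.0 / 3.0)  # (N,)
        return geom[:, None] * crowd * (k_imp * conc)[None, :]

    def _inc_coeff(self, st: _State, t: float, mask: np.ndarray) -> np.ndarray:
        """Incorporation rate coefficient (1/s) per nucleus/species."""
        cfg = self.cfg
        n = len(st)
        coeff = np.zeros((n, self.n_species))
        tau = t - st.t0
        for j, sp in enumerate(cfg.species):
            if sp.pathway == RD:
                u = np.clip(1.0 - tau / st.ts, 0.0, 1.0)
                coeff[:, j] = sp.k_inc * u * cfg.ploidy
            else:
                gamma = np.array([sp.gamma(int(c)) for c in st.cycle])
                nbar = np.array([self._mean_nnb(int(c)) for c in st.cycle])
                with np.errstate(divide="ignore", invalid="ignore"):
                    mod = np.where(nbar > 0,
                                   (st.nnb / np.where(nbar > 0, nbar, 1.0))
                                   ** sp.gate_density_exp, 1.0)
                coeff[:, j] = sp.k_inc * gamma * mod * cfg.ploidy
        coeff[~mask] = 0.0
        return coeff

    def _integrate(self, st: _State, t: float) -> None:
        cfg = self.cfg
        dt = cfg.dt
        tau = t - st.t0
        inter = (tau >= -1e-9) & ((tau < st.ti - 1e-9) | st.arrested)
        if inter.any():
            vol = self._volume(st, t)
            rate = self._import_rate(st, vol)
            rate[~inter] = 0.0
            demand = rate.sum(axis=0) * dt  # (S,)
            scale = np.ones(self.n_species)
            over = demand > self._pool
            if over.any():
                scale[over] = np.where(demand[over] > 0,
                                       self._pool[over] / demand[over], 0.0)
                if not self._pool_warned:
                    logger.warning(
                        "cytoplasmic pool exhausted; import clamped at zero "
                        "(consider a smaller dt)")
                    self._pool_warned = True
            dF = rate * (scale * dt)[None, :]
            st.fg += dF
            self._pool = np.maximum(self._pool - dF.sum(axis=0), 0.0)
            coeff = self._inc_coeff(st, t, inter)
            frac = -np.expm1(-coeff * dt)
            for free, bound in ((st.fg, st.bg), (st.fr, st.br)):
                dB = free * frac
                free -= dB
                bound += dB
        self._pool += self._synth_rate * dt
        self._synth += self._synth_rate * dt

    # -- events ------------------------------------------------------------

    def _apply_conversions(self, st: _State, t: float) -> None:
        for k, ev in enumerate(self.conversions):
            if k in self._done_conv or ev.t_conv > t + 1e-9:
                continue
            where = np.nonzero(st.ids == ev.nucleus_id)[0]
            if len(where) == 0:
                raise ValueError(
                    f"photoconversion target nucleus {ev.nucleus_id} does not "
                    f"exist at t={ev.t_conv:g} s")
            i = where[0]
            tau = t - st.t0[i]
            if st.neb[i] or not (0.0 <= tau < st.ti[i]):
                raise ValueError(
                    f"nucleus {ev.nucleus_id} is not in interphase at "
                    f"t={ev.t_conv:g} s")
            eff = self.cfg.conversion_efficiency
            st.fr[i] += eff * st.fg[i]
            st.br[i] += eff * st.bg[i]
            st.fg[i] *= 1.0 - eff
            st.bg[i] *= 1.0 - eff
            self._done_conv.add(k)

    def _apply_neb(self, st: _State, t: float) -> None:
        due = (~st.neb) & (~st.arrested) & (t - st.t0 >= st.ti - 1e-9)
        if not due.any():
            return
        idx = np.nonzero(due)[0]
        for i in idx:
            tot = st.fg[i] + st.fr[i] + st.bg[i] + st.br[i]
            ff = np.where(tot > 0, (st.fg[i] + st.fr[i]) / np.where(tot > 0, tot, 1.0),
                          np.nan)
            red_tot = st.fr[i] + st.br[i]
            red_ff = np.where(red_tot > 0, st.fr[i] / np.where(red_tot > 0, red_tot, 1.0),
                              np.nan)
            for j, sp in enumerate(self.cfg.species):
                self._ff_rows.append({
                    "nucleus_id": int(st.ids[i]), "cycle": int(st.cycle[i]),
                    "species": sp.name, "free_fraction": float(ff[j]),
                    "red_free_fraction": float(red_ff[j]),
                })
        self._pool += st.fg[idx].sum(axis=0)
        self._red_cyto += st.fr[idx].sum(axis=0)
        st.fg[idx] = 0.0
        st.fr[idx] = 0.0
        st.neb[idx] = True
        for i in idx:
            self._cycle_meta.setdefault(int(st.cycle[i]), []).append(
                float(st.t0[i] + st.ti[i] + st.tm[i] / 2.0))

    def _divide(self, st: _State, t: float) -> _State:
        due = st.neb & (t - st.t0 >= st.ti + st.tm - 1e-9)
        if not due.any():
            return st
        cfg = self.cfg
        keep = st.take(np.nonzero(~due)[0])
        parents = st.take(np.nonzero(due)[0])
        d_states = []
        for i in range(len(parents)):
            cyc_next = int(parents.cycle[i]) + 1
            divides = cyc_next in cfg.cycle_schedule
            if divides and cfg.scenario == "shkl" and cyc_next == 14:
                divides = self._nc14_allowed(parents, i)
            reg_i = self._find_registry(int(parents.ids[i]))
            if not divides:
                reg_i["fate"] = "terminal"
                self._retired_chromatin += parents.bg[i] + parents.br[i]
                continue
            if cyc_next == 14:
                reg_i["fate"] = "extra_division"
            d = _State(2, self.n_species)
            d.ids = np.array([self._next_id, self._next_id + 1], dtype=np.int64)
            self._next_id += 2
            d.parent = np.full(2, parents.ids[i], dtype=np.int64)
            radius = (3.0 * parents.vmax[i] / (4.0 * math.pi)) ** (1.0 / 3.0)
            ang = self.rng_bio.uniform(0.0, 2.0 * math.pi)
            off = radius * np.array([math.cos(ang), math.sin(ang), 0.0])
            d.pos = np.vstack([parents.pos[i] + off, parents.pos[i] - off])
            d.pos[:, 0] = np.clip(d.pos[:, 0], 0.0, cfg.embryo_length)
            d.pos[:, 1] = np.clip(d.pos[:, 1], 0.0, cfg.embryo_width)
            d.bg = np.vstack([parents.bg[i] / 2.0] * 2)
            d.br = np.vstack([parents.br[i] / 2.0] * 2)
            d_states.append((cyc_next, d))
        if not d_states:
            return keep
        merged = keep
        new_idx_start = len(keep)
        cycles = []
        for cyc_next, d in d_states:
            merged = _State.concat(merged, d)
            cycles.extend([cyc_next] * 2)
        new_idx = np.arange(new_idx_start, len(merged))
        # spread freshly placed daughters to non-touching spacing
        cyc_next = max(cyc for cyc, _ in d_states)
        r_next = (3.0 * cfg.vmax_for(cyc_next) / (4.0 * math.pi)) ** (1.0 / 3.0)
        merged.pos = _relax(merged.pos, (cfg.embryo_length, cfg.embryo_width),
                            1.6 * r_next, 3)
        for cyc in sorted(set(cycles)):
            sel = new_idx[np.array(cycles) == cyc]
            self._new_cohort(merged, sel, cyc, t, merged.pos)
        return merged

    def _mean_nnb(self, cycle: int) -> float:
        cnt = self._nnb_cnt.get(cycle, 0)
        return self._nnb_sum.get(cycle, 0.0) / cnt if cnt else 0.0

    def _nc14_allowed(self, parents: _State, i: int) -> bool:
        if self._nc14_ids is None:
            q = self.cfg.scenario_params.get("nc14_count_quantile", 0.25)
            rows = [r for r in self._registry if r["cycle"] == 13]
            # sparsest nuclei divide again; posterior wins ties
            rows.sort(key=lambda r: (r["n_neighbors"], -r["x"]))
            k = int(round(q * len(rows)))
            self._nc14_ids = {r["nucleus_id"] for r in rows[:k]}
        return int(parents.ids[i]) in self._nc14_ids

    def _find_registry(self, nucleus_id: int) -> dict:
        # registry rows are append-only and id-ordered within cycles
        for row in reversed(self._registry):
            if row["nucleus_id"] == nucleus_id:
                return row
        raise KeyError(nucleus_id)  # pragma: no cover

    # -- recording ---------------------------------------------------------

    def _record_frame(self, st: _State, t: float, frame: int) -> None:
        cfg = self.cfg
        n = len(st)
        if n == 0:
            return
        tau = t - st.t0
        inter = (tau < st.ti - 1e-9) | st.arrested
        vol_true = np.where(inter, self._volume(st, t), cfg.mitotic_volume)
        sig_v = _lognorm_sigma(cfg.volume_cv if cfg.noise_cv > 0 else 0.0)
        if sig_v > 0:
            vol_meas = vol_true * self.rng_noise.lognormal(
                -sig_v ** 2 / 2.0, sig_v, size=n)
        else:
            vol_meas = vol_true.copy()
        sig = _lognorm_sigma(cfg.noise_cv)
        bleach = cfg.bleach_per_frame ** frame
        row: dict[str, np.ndarray] = {
            "nucleus_id": st.ids.copy(), "parent_id": st.parent.copy(),
            "cycle": st.cycle.copy(), "frame": np.full(n, frame, dtype=np.int64),
            "t": np.full(n, t), "x": st.pos[:, 0].copy(),
            "y": st.pos[:, 1].copy(), "z": st.pos[:, 2].copy(),
            "volume": vol_meas,
            "phase": np.where(inter, INTERPHASE, MITOSIS),
        }
        for j, sp in enumerate(cfg.species):
            green = st.fg[:, j] + st.bg[:, j]
            if sig > 0:
                noise = self.rng_noise.lognormal(-sig ** 2 / 2.0, sig, size=n)
            else:
                noise = 1.0
            total = green * noise * bleach + cfg.background
            row[f"total_{sp.name}"] = total
            row[f"mean_{sp.name}"] = total / vol_meas
            if self._converted_any:
                red = st.fr[:, j] + st.br[:, j]
                if sig > 0:
                    noise_r = self.rng_noise.lognormal(-sig ** 2 / 2.0, sig, size=n)
                else:
                    noise_r = 1.0
                row[f"red_{sp.name}"] = red * noise_r * bleach + cfg.background
        self._rows.append(row)
        # ground-truth bookkeeping
        free_sum = (st.fg + st.fr).sum(axis=0)
        bound_sum = (st.bg + st.br).sum(axis=0) + self._retired_chromatin
        for j, sp in enumerate(cfg.species):
            self._pool_rows.append({
                "frame": frame, "t": t, "species": sp.name,
                "cytoplasm": self._pool[j] + self._red_cyto[j],
                "nuclear_free": free_sum[j], "chromatin": bound_sum[j],
                "synthesized": self._synth[j], "initial": self._initial[j],
            })
        if inter.any():
            vol = self._volume(st, t)
            rate = self._import_rate(st, vol)
            idx = np.nonzero(inter)[0]
            for j, sp in enumerate(cfg.species):
                for i in idx:
                    self._rate_rows.append({
                        "frame": frame, "t": t, "nucleus_id": int(st.ids[i]),
                        "species": sp.name, "rate": rate[i, j],
                    })

    # -- main loop ---------------------------------------------------------

    def run(self) -> tuple[pd.DataFrame, GroundTruth]:
        cfg = self.cfg
        st = self._init_state()
        async_span = cfg.scenario_params.get("async_span", 0.0)
        if async_span > 0:
            off = st.pos[:, 0] / cfg.embryo_length * async_span
            st.t0 += np.round(off / cfg.dt) * cfg.dt
        t_end = sum(cfg.cycle_schedule[nc].total
                    for nc in sorted(cfg.cycle_schedule)
                    if nc >= cfg.start_cycle) + async_span
        n_steps = int(round(t_end / cfg.dt))
        steps_per_frame = int(round(cfg.frame_interval / cfg.dt))
        frame = 0
        for step in range(n_steps + 1):
            t = step * cfg.dt
            self._apply_neb(st, t)
            st = self._divide(st, t)
            self._apply_conversions(st, t)
            if step % steps_per_frame == 0:
                self._record_frame(st, t, frame)
                frame += 1
            if step < n_steps:
                self._integrate(st, t)
        if len(self._done_conv) < len(self.conversions):
            missed = [self.conversions[k] for k in range(len(self.conversions))
                      if k not in self._done_conv]
            raise ValueError(f"conversion events never applied: {missed}")
        return self._build_table(), self._build_truth()

    def _build_table(self) -> pd.DataFrame:
        cols = self._rows[0].keys()
        data = {c: np.concatenate([r[c] for r in self._rows]) for c in cols}
        df = pd.DataFrame(data)
        return df.sort_values(["frame", "nucleus_id"], kind="stable").reset_index(drop=True)

    def _build_truth(self) -> GroundTruth:
        cyc_rows = []
        for cyc in sorted(self._cycle_starts):
            starts = self._cycle_starts[cyc]
            metas = self._cycle_meta.get(cyc, [])
            ph = self.cfg.cycle_schedule[cyc]
            cyc_rows.append({
                "cycle": cyc, "t_start_mean": float(np.mean(starts)),
                "t_metaphase_mean": float(np.mean(metas)) if metas else np.nan,
                "interphase": ph.interphase, "mitosis": ph.mitosis,
                "n_nuclei": len(starts),
            })
        return GroundTruth(
            pools=pd.DataFrame(self._pool_rows),
            import_rates=pd.DataFrame(self._rate_rows),
            free_fractions=pd.DataFrame(
                self._ff_rows, columns=["nucleus_id", "cycle", "species",
                                        "free_fraction", "red_free_fraction"]),
            nuclei=pd.DataFrame(self._registry),
            cycle_times=pd.DataFrame(cyc_rows),
            arrested=self.embryo_arrests,
            conversions=self.conversions,
        )


def simulate_embryo(config: SimConfig,
                    conversions: tuple[ConversionEvent, ...] | list = (),
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one embryo; returns the measured TrackTable and ground truth.

    The TrackTable holds one row per nucleus per frame at the configured
    acquisition cadence, with per-channel measured total and mean intensities
    (multiplicative lognormal noise, per-frame bleaching, additive
    background).  ``conversions`` schedules photoconversion events; red
    channel columns appear only when at least one event is given.
    """
    return _Simulator(config, tuple(conversions)).run()


def apply_photoconversion(config: SimConfig, nucleus_id: int, t_conv: float,
                          ) -> tuple[pd.DataFrame, GroundTruth]:
    """Re-simulate ``config`` with a green-to-red conversion of one nucleus.

    Raises ``ValueError`` if the nucleus does not exist or is not in
    interphase at ``t_conv``.
    """
    return simulate_embryo(config, (ConversionEvent(nucleus_id, t_conv),))


def photoconvert_mid_cycle(config: SimConfig, cycle: int,
                           ) -> tuple[pd.DataFrame, GroundTruth, int]:
    """Convert a representative nucleus of ``cycle`` at mid-interphase.

    Runs the simulation once to locate the target — an interior (non-edge)
    nucleus whose local neighbor count is most typical of the cohort
    (closest to the median; ties broken toward the embryo centre) — then
    re-runs with the conversion event.  Returns (track table, ground truth,
    nucleus id).
    """
    _, truth = simulate_embryo(config)
    reg = truth.nuclei
    cand = reg[(reg["cycle"] == cycle) & (~reg["is_edge"])]
    if cand.empty:
        raise ValueError(f"no nuclei in cycle NC{cycle}")
    med = cand["n_neighbors"].median()
    cand = cand[np.abs(cand["n_neighbors"] - med)
                == np.abs(cand["n_neighbors"] - med).min()]
    cx = config.embryo_length / 2.0
    cy = config.embryo_width / 2.0
    d2 = (cand["x"] - cx) ** 2 + (cand["y"] - cy) ** 2
    target = cand.loc[d2.idxmin()]
    t_conv = float(target["t0"] + target["interphase"] / 2.0)
    t_conv = round(t_conv / config.dt) * config.dt
    table, truth2 = apply_photoconversion(config, int(target["nucleus_id"]), t_conv)
    return table, truth2, int(target["nucleus_id"])
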