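"""Per-cycle quantification operations against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest

from histodyn import (AnalysisParams, ImportCurve, calibrated_control,
                      cycle_durations, define_regions, import_curves,
                      initial_import_rate, interphase_concentration,
                      mitotic_chromatin_totals, normalize_durations,
                      simulate_embryo)


class TestMitoticChromatinTotals:
    def test_identical_totals_normalize_to_one(self, tiny_track_table):
        t = tiny_track_table.copy()
        t["total_ch"] = 100.0
        cs = mitotic_chromatin_totals(t, "ch")
        assert np.allclose(cs.per_cycle["normalized_mean"], 1.0)

    def test_reference_arithmetic(self, tiny_track_table):
        # NC10 metaphase totals {90, 110} -> mean 100; NC13 {40} -> 0.40
        cs = mitotic_chromatin_totals(tiny_track_table, "ch")
        assert cs.normalized_mean(10) == pytest.approx(1.0)
        assert cs.normalized_mean(13) == pytest.approx(0.40)
        assert cs.reference_value == pytest.approx(100.0)

    def test_missing_reference_cycle_errors(self, tiny_track_table):
        sub = tiny_track_table[tiny_track_table.cycle != 10]
        with pytest.raises(ValueError, match="reference"):
            mitotic_chromatin_totals(sub, "ch")

    def test_arrested_cycle_omitted(self, tiny_track_table, caplog):
        t = tiny_track_table[~((tiny_track_table.cycle == 13)
                               & (tiny_track_table.phase == "mitosis"))]
        with caplog.at_level("INFO", logger="histodyn.quantify"):
            cs = mitotic_chromatin_totals(t, "ch")
        assert 13 not in set(cs.per_cycle["cycle"])

    def test_control_trends_h3_down_h33_up(self, control_run):
        table, _ = control_run
        h3 = mitotic_chromatin_totals(table, "H3")
        h33 = mitotic_chromatin_totals(table, "H33")
        assert h3.normalized_mean(13) < 1.0
        assert h33.normalized_mean(13) > 1.0

    def test_normalization_idempotent(self, tiny_track_table):
        cs = mitotic_chromatin_totals(tiny_track_table, "ch")
        again = cs.renormalized()
        assert np.allclose(again.per_nucleus["normalized"],
                           cs.per_nucleus["normalized"])
        assert np.allclose(again.per_cycle["normalized_mean"],
                           cs.per_cycle["normalized_mean"])

    def test_scale_equivariance(self, tiny_track_table):
        t = tiny_track_table.copy()
        t["total_ch"] *= 7.3
        a = mitotic_chromatin_totals(tiny_track_table, "ch")
        b = mitotic_chromatin_totals(t, "ch")
        assert np.allclose(a.per_cycle["normalized_mean"],
                           b.per_cycle["normalized_mean"])


class TestInterphaseConcentration:
    def test_constant_concentration_normalizes_to_one(self, tiny_track_table):
        t = tiny_track_table.copy()
        t["mean_ch"] = 5.0
        cs = interphase_concentration(t, "ch")
        assert np.allclose(cs.per_cycle["normalized_mean"], 1.0)

    def test_reference_arithmetic(self, tiny_track_table):
        # NEB-45 s frame = last interphase frame; NC10 means {200, 200},
        # NC13 nucleus at 120 -> 0.6
        t = tiny_track_table.copy()
        t.loc[t.phase == "interphase", "mean_ch"] = 200.0
        t.loc[(t.cycle == 13) & (t.phase == "interphase"), "mean_ch"] = 120.0
        cs = interphase_concentration(t, "ch")
        assert cs.normalized_mean(13) == pytest.approx(0.6)

    def test_short_tracks_excluded_with_warning(self, tiny_track_table, caplog):
        t = tiny_track_table[~((tiny_track_table.nucleus_id == 1)
                               & (tiny_track_table.frame > 0)
                               & (tiny_track_table.phase == "interphase"))]
        with caplog.at_level("WARNING", logger="histodyn.quantify"):
            cs = interphase_concentration(t, "ch")
        assert 1 not in set(cs.per_nucleus["nucleus_id"])
        assert any("excluded" in r.message for r in caplog.records)

    def test_h3_falls_faster_than_h33(self, control_run):
        table, _ = control_run
        h3 = interphase_concentration(table, "H3").normalized_mean(13)
        h33 = interphase_concentration(table, "H33").normalized_mean(13)
        assert h3 < h33 < 1.0


class TestImportCurves:
    def test_alignment_shifts_min_volume_to_t0(self, tiny_track_table):
        curves = import_curves(tiny_track_table, 13, "ch",
                               mode="mean_max_size_per_cycle")
        (c,) = curves
        assert c.times[0] == 0.0
        assert len(c.values) == 3  # interphase frames from T0 to NEB

    def test_identical_nuclei_give_identical_unit_max_curves(self):
        rows = []
        for nid in (0, 1):
            for f in range(6):
                rows.append(dict(nucleus_id=nid, parent_id=-1, cycle=11,
                                 frame=f, t=45.0 * f, x=1.0 * nid, y=0.0,
                                 z=5.0, volume=60.0 + 10 * f,
                                 phase="interphase", total_ch=10.0 * (f + 1),
                                 mean_ch=1.0))
        t = pd.DataFrame(rows)
        curves = import_curves(t, 11, "ch", mode="mean_max_size_per_cycle")
        assert np.allclose(curves[0].values, curves[1].values)
        maxima = [c.values[np.argmax([60.0 + 10 * i for i in
                                      range(len(c.values))])] for c in curves]
        assert np.mean(maxima) == pytest.approx(1.0)

    def test_h3_plateaus_h33_slows_in_nc13(self, control_run):
        table, _ = control_run
        ratios = {}
        for ch in ("H3", "H33"):
            init, late = [], []
            for c in import_curves(table, 13, ch):
                if len(c.values) < 10:
                    continue
                init.append(initial_import_rate(c))
                late.append(np.polyfit(c.times[-5:], c.values[-5:], 1)[0])
            ratios[ch] = np.mean(late) / np.mean(init)
        assert ratios["H3"] < 0.10
        assert ratios["H33"] > 0.25


class TestInitialImportRate:
    def test_exact_line(self):
        c = ImportCurve(nucleus_id=0, cycle=11,
                        times=np.array([0.0, 45, 90, 135, 180]),
                        values=np.array([0.0, 45, 90, 135, 180]), mode="m")
        assert initial_import_rate(c) == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_zero_slope(self):
        c = ImportCurve(nucleus_id=0, cycle=11,
                        times=np.arange(5) * 45.0,
                        values=np.full(5, 3.3), mode="m")
        assert initial_import_rate(c) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_ols(self):
        # slope = sum((t-tbar)(y-ybar)) / sum((t-tbar)^2) = 3150/20250
        t = np.array([0.0, 45, 90, 135, 180])
        y = np.array([0.0, 10, 18, 24, 28])
        c = ImportCurve(nucleus_id=0, cycle=11, times=t, values=y, mode="m")
        tbar, ybar = t.mean(), y.mean()
        oracle = ((t - tbar) * (y - ybar)).sum() / ((t - tbar) ** 2).sum()
        assert oracle == pytest.approx(3150.0 / 20250.0)
        assert initial_import_rate(c) == pytest.approx(oracle, abs=1e-10)

    def test_too_few_points_names_nucleus(self):
        c = ImportCurve(nucleus_id=42, cycle=11, times=np.arange(3) * 45.0,
                        values=np.zeros(3), mode="m")
        with pytest.raises(ValueError, match="42"):
            initial_import_rate(c)

    def test_recovers_true_import_rate(self):
        # noise-free curves: initial slope matches the simulator's flux
        cfg = calibrated_control(seed=0, noise_cv=0.0, background=0.0)
        table, truth = simulate_embryo(cfg)
        curves = import_curves(table, 12, "H3", mode="mean_max_size_per_cycle")
        rates = truth.import_rates
        raw_norm = []
        sub = table[table.cycle == 12]
        for nid, grp in sub.groupby("nucleus_id"):
            inter = grp[grp.phase == "interphase"].sort_values("frame")
            imax = int(np.argmax(inter["volume"].to_numpy()))
            raw_norm.append(float(inter["total_H3"].to_numpy()[imax]))
        norm = np.mean(raw_norm)
        checked = 0
        for c in curves[:30]:
            est = initial_import_rate(c) * norm
            nuc = rates[(rates.nucleus_id == c.nucleus_id)
                        & (rates.species == "H3")].sort_values("frame")
            true_early = nuc["rate"].iloc[:5].mean()
            assert est == pytest.approx(true_early, rel=0.10)
            checked += 1
        assert checked > 10


class TestRegions:
    def test_control_boxes(self, control_run):
        table, _ = control_run
        params = AnalysisParams()
        reg = define_regions(table, "control", params)
        merged = reg.merge(
            table.groupby("nucleus_id").agg(x=("x", "mean")).reset_index())
        mid = merged[merged.region == "middle"]
        pole = merged[merged.region == "pole"]
        xmin, xmax = merged.x.min(), merged.x.max()
        xmid = (xmin + xmax) / 2
        assert (np.abs(mid.x - xmid) <= params.region_box_um / 2 + 1e-9).all()
        assert (pole.x <= xmin + params.region_box_um + 1e-9).all()
        assert len(mid) and len(pole)

    def test_shkl_low_density_is_nc14_lineage(self, shkl_run):
        table, _ = shkl_run
        reg = define_regions(table, "shkl")
        low = set(reg[reg.region == "low_density"].nucleus_id)
        nc14 = set(table[table.cycle == 14].nucleus_id)
        assert nc14 <= low
        # every low-density nucleus is an NC14 nucleus or one of its ancestors
        parent = dict(table.groupby("nucleus_id")["parent_id"].first())
        ancestors = set()
        for nid in nc14:
            cur = nid
            while cur >= 0:
                ancestors.add(cur)
                cur = parent.get(cur, -1)
        assert low == ancestors

    def test_shkl_without_nc14_errors(self, control_run):
        table, _ = control_run
        with pytest.raises(ValueError, match="NC14"):
            define_regions(table, "shkl")

    def test_shkl_high_density_region_is_denser(self, shkl_run):
        table, _ = shkl_run
        from histodyn import neighbor_profiles
        reg = define_regions(table, "shkl")
        prof = neighbor_profiles(table, 13).merge(reg, on="nucleus_id")
        hi = prof[prof.region == "high_density"]["neighbor_count"].mean()
        lo = prof[prof.region == "low_density"]["neighbor_count"].mean()
        assert hi > lo


class TestCycleDurations:
    def test_unit_factor_leaves_durations(self):
        d = pd.DataFrame({"cycle": [11, 11, 11], "duration": [600.0] * 3})
        out = normalize_durations(d, control_nc11_mean=600.0)
        assert np.allclose(out["duration_scaled"], 600.0)

    def test_scaling_arithmetic(self):
        d = pd.DataFrame({"cycle": [12], "duration": [864.0]})
        out = normalize_durations(d, control_nc11_mean=720.0)
        assert out["duration_scaled"].iloc[0] == pytest.approx(720.0)

    def test_control_nc11_mean_is_exactly_reference(self, control_run):
        table, _ = control_run
        durations = cycle_durations(table)
        nc11 = float(durations.loc[durations.cycle == 11, "duration"].iloc[0])
        out = normalize_durations(durations, control_nc11_mean=nc11)
        scaled_nc11 = float(
            out.loc[out.cycle == 11, "duration_scaled"].iloc[0])
        assert scaled_nc11 == pytest.approx(600.0, abs=1e-9)

    def test_metaphase_to_metaphase_measurement(self, control_run):
        table, truth = control_run
        durations = cycle_durations(table).set_index("cycle")["duration"]
        tm = truth.cycle_times.set_index("cycle")["t_metaphase_mean"]
        for cyc in (10, 11, 12):
            assert durations[cyc] == pytest.approx(tm[cyc + 1] - tm[cyc],
                                                   abs=45.0)
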