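# histodyn

Histone availability and chromatin incorporation dynamics in syncytial
embryos: a calibrated simulator plus the live-imaging quantification
pipeline it stands in for.

## The problem

Before zygotic genome activation (ZGA), a *Drosophila* embryo runs rapid
syncytial nuclear cycles (NC10–13) in which the number of nuclei doubles
every division while the maternally supplied pool of histones does not
keep up. Canonical H3 is deposited during S-phase and its nuclear
availability collapses as the nucleo-cytoplasmic (N/C) ratio rises; the
replication-independent variant H3.3 progressively replaces it on
chromatin, gated by cell-cycle state and local nuclear density. Live
imaging quantifies this with per-nucleus tracking tables: total and mean
fluorescence intensity, volume and position per nucleus per 45-s frame.

`histodyn` is for people who analyse such tracking data (or build methods
for it). It provides:

- **`embryo_sim`-style simulation** (`simulate_embryo`,
  `apply_photoconversion`, `render_image_stack`): an agent-based model of
  the cortical nuclear sheet with shared depleting pools, surface-area
  scaled import under local-density competition
  (`dF/dt = k_import·(P/V_embryo)·V^{2/3}/(1+β·n)`), S-phase-coupled (H3)
  vs state-gated (H3.3) incorporation, scenario variants (haploid
  chaperone mutant `hira_ssm`, density-gradient `shkl`, pool-depleted
  `slbp`, transcription-null `zelda`, checkpoint `chk1`), photoconversion,
  noise/bleaching, and exact ground truth for every quantity.
- **Quantification** (`quantify`, `neighbors`, `photoconv`): mitotic
  chromatin totals, pre-NEB nuclear concentrations, aligned import curves
  and initial slopes, fixed-radius (20 µm) neighbor counts with
  Z-coordinate edge filtering and weighted binning, photoconversion
  export/free-fraction assays, cycle durations with the 10-min NC11
  normalization.
- **Imaging** (`render`, `imaging`): synthetic 3D+t TIFF rendering, a
  threshold/connected-component segmenter, division-aware nearest-neighbor
  tracking, and a reader for ilastik-style tracking CSV exports.
- **Statistics and reporting** (`stats`, `report`): genotype × cycle
  two-way ANOVA (Type-II sums of squares) and deterministic CSV report
  bundles.

## Worked example

```python
from histodyn import (calibrated_control, simulate_embryo,
                      interphase_concentration, mitotic_chromatin_totals)

table, truth = simulate_embryo(calibrated_control(seed=0))
for ch in ("H3", "H33"):
    conc = interphase_concentration(table, ch)
    chrom = mitotic_chromatin_totals(table, ch)
    print(ch, conc.normalized_mean(13), chrom.normalized_mean(13))
```

Running `python examples/02_concentration_and_chromatin.py` prints:

```
H3: normalized concentration (NEB-45 s) and chromatin totals per cycle
 cycle  concentration  chromatin
    10          1.000      1.000
    11          0.832      0.927
    12          0.651      0.888
    13          0.581      0.725

H3.3: normalized concentration (NEB-45 s) and chromatin totals per cycle
 cycle  concentration  chromatin
    10          1.000      1.000
    11          0.791      1.490
    12          0.678      1.838
    13          0.786      1.736
```

Read: by NC13 the H3 nuclear concentration measured 45 s before nuclear
envelope breakdown has fallen ~42% relative to NC10 (multi-embryo mean
~40%) and its chromatin totals decline, while H3.3 concentration falls
only ~20% and its chromatin totals *rise* — the variant replaces the
canonical histone on chromatin as the N/C ratio climbs. The
photoconversion example (`examples/03_photoconversion.py`) converts one
nucleus green→red mid-interphase and reports the free (unincorporated)
fraction after NEB, which falls from ~70% to ~30% (H3.3) and ~55% to
~20% (H3) between NC11 and NC13 on multi-embryo means.

`docs/methods.md` describes the kinetic model, its calibration, every
tunable parameter, and the limits of what the synthetic data shows.

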