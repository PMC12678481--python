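"""Per-cycle nuclear concentration and mitotic chromatin quantification.

Reproduces the two headline per-cycle measurements on one simulated control
embryo: the interphase nuclear concentration 45 s before nuclear envelope
breakdown (NC10-normalized) and the total intensity on mitotic chromatin at
metaphase (NC10-normalized).
"""

from histodyn import (calibrated_control, interphase_concentration,
                      mitotic_chromatin_totals, simulate_embryo)

table, _ = simulate_embryo(calibrated_control(seed=0))

for ch, label in (("H3", "H3"), ("H33", "H3.3")):
    conc = interphase_concentration(table, ch)
    chrom = mitotic_chromatin_totals(table, ch)
    print(f"\n{label}: normalized concentration (NEB-45 s) and chromatin "
          "totals per cycle")
    merged = conc.per_cycle[["cycle", "normalized_mean"]].rename(
        columns={"normalized_mean": "concentration"}).merge(
        chrom.per_cycle[["cycle", "normalized_mean"]].rename(
            columns={"normalized_mean": "chromatin"}), on="cycle")
    print(merged.round(3).to_string(index=False))

# H3 concentration falls ~40% by NC13 and its chromatin totals decline;
# H3.3 concentration falls only ~20% while its chromatin totals rise --
# the variant replaces the canonical histone on chromatin before ZGA.
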