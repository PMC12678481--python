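"""Group-comparison statistics: two-way ANOVA over genotype x cycle.

Type-II sums of squares are used because embryo counts per genotype are
typically unbalanced; on balanced designs Type I/II/III coincide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["AnovaResult", "two_way_anova", "significance_stars"]

logger = logging.getLogger(__name__)


def significance_stars(p: float) -> str:
    """Figure-legend star convention: ns > 0.05 > * > 0.01 > ** > 0.001 > ***."""
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    return "***"


@dataclass(frozen=True)
class AnovaResult:
    """Per-effect sum of squares, df, F and p, plus star annotations.

    ``table`` has rows for factor A, factor B, the interaction (when
    estimable) and the residual.  ``replicate_unit`` records whether
    per-embryo means or individual nuclei were the replicates.
    """

    table: pd.DataFrame
    replicate_unit: str
    ss_type: int = 2

    def p_value(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def stars(self, effect: str) -> str:
        return significance_stars(self.p_value(effect))


def two_way_anova(data: pd.DataFrame, value: str = "value",
                  factor_a: str = "genotype", factor_b: str = "cycle",
                  replicate_unit: str = "embryo_mean") -> AnovaResult:
    """Two-way ANOVA of ``value`` over two categorical factors.

    Uses Type-II sums of squares (unbalanced-safe).  With empty factor
    cells the interaction is dropped with a warning; zero residual
    variance raises (F undefined).
    """
    df = data[[value, factor_a, factor_b]].dropna().copy()
    df.columns = ["y", "A", "B"]
    df["A"] = df["A"].astype("category")
    df["B"] = df["B"].astype("category")
    for fac in ("A", "B"):
        if df[fac].nunique() < 2:
            raise ValueError(f"factor {fac} needs >= 2 levels")
    if len(df) < df["A"].nunique() * df["B"].nunique() + 1:
        raise ValueError("not enough replicates for the tested effects")
    cells = df.groupby(["A", "B"], observed=False).size()
    interaction = bool((cells > 0).all())
    if not interaction:
        logger.warning("empty factor cells; interaction term dropped")
    formula = "y ~ C(A) * C(B)" if interaction else "y ~ C(A) + C(B)"
    fit = smf.ols(formula, data=df).fit()
    if fit.ssr <= 1e-12 * max(fit.centered_tss, 1.0) or fit.df_resid < 1:
        raise ValueError("zero residual variance; F statistic undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = sm.stats.anova_lm(fit, typ=2)
    rename = {"C(A)": factor_a, "C(B)": factor_b,
              "C(A):C(B)": f"{factor_a}:{factor_b}", "Residual": "residual"}
    tab = tab.rename(index=rename)
    tab = tab.rename(columns={"sum_sq": "ss", "PR(>F)": "p"})
    tab["stars"] = [significance_stars(p) if np.isfinite(p) else ""
                    for p in tab["p"].fillna(np.inf)]
    return AnovaResult(table=tab, replicate_unit=replicate_unit)
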