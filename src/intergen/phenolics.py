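"""Total-phenolics ANCOVA.

Each plant's two technical replicate measurements (tannic-acid
equivalents per g dry sample) are averaged, then modelled as
value ~ seed_weight + parental * offspring with Type-II sums of squares:
the seed-weight covariate absorbs initial-size differences before the
2x2 treatment terms are assessed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .design import Design


def average_reps(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of rep1/rep2 per plant; a missing replicate falls back to the
    other one and is flagged in ``single_rep``."""
    rep1 = table["rep1"]
    rep2 = table["rep2"]
    both_missing = rep1.isna() & rep2.isna()
    if both_missing.any():
        raise ValueError(f"plants with no replicate measurement: {list(table.index[both_missing])}")
    value = pd.concat([rep1, rep2], axis=1).mean(axis=1)
    out = table.copy()
    out["value"] = value
    out["single_rep"] = rep1.isna() | rep2.isna()
    return out


def phenolics_ancova(
    values: pd.Series,
    seed_weight: pd.Series,
    design: Design,
    ss_type: int = 2,
) -> pd.DataFrame:
    """ANCOVA effect table for the 2x2 design with a seed-weight covariate.

    Returns one row per term (seed_weight, parental, offspring,
    parental:offspring, residual) with sum_sq, df, F and p. ``ss_type``
    selects the sum-of-squares decomposition (2 default; 1 and 3
    available).
    """
    t = design.table
    for g in ("CC", "CJ", "JC", "JJ"):
        if (t["group"] == g).sum() == 0:
            raise ValueError(f"group {g} is empty")
    df = pd.DataFrame(
        {
            "value": values.loc[t.index].astype(float),
            "seed_weight": seed_weight.loc[t.index].astype(float),
            "parental": t["parental"],
            "offspring": t["offspring"],
        }
    )
    fit = smf.ols("value ~ seed_weight + C(parental) * C(offspring)", data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=ss_type)
    anova = anova.rename(
        index={
            "C(parental)": "parental",
            "C(offspring)": "offspring",
            "C(parental):C(offspring)": "parental:offspring",
            "Residual": "residual",
        }
    )
    cols = ["sum_sq", "df", "F", "PR(>F)"]
    anova = anova[[c for c in cols if c in anova.columns]].rename(columns={"PR(>F)": "p"})
    anova.attrs["params"] = fit.params
    return anova


def analyze_phenolics(table: pd.DataFrame, design: Design, ss_type: int = 2) -> pd.DataFrame:
    """Average technical replicates, then run the ANCOVA."""
    avg = average_reps(table)
    return phenolics_ancova(avg["value"], avg["seed_weight"], design, ss_type=ss_type)
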