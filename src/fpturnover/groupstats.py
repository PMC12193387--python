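"""Group-comparison statistics for turnover experiments.

Four comparisons recur in this kind of study:

* ANCOVA on decay slopes — is the ln(fluorescence)-vs-time slope the same in
  two or more groups? Implemented as the F-test of the time x group
  interaction in a pooled OLS model, which for two groups is the classic
  equality-of-slopes test.
* Unpaired two-tailed t-test on collections of half-life values (Welch by
  default; a pooled-variance option reproduces the textbook statistic).
* Two-factor ANOVA of half-life on age and sex with interaction, sequential
  (Type-I) sums of squares as produced by ``anova(lm(...))`` in base R.
* t-test on per-vial peak fluorescence (synthesis-level comparison).

No multiple-testing correction is applied; reports annotate the number of
comparisons so the reader can apply one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DataError, DegenerateStatisticsWarning

__all__ = [
    "SlopeComparison",
    "compare_slopes_ancova",
    "compare_halflives_ttest",
    "halflife_anova",
    "compare_peaks",
]

_REL_TOL = 1e-12


@dataclass(frozen=True)
class SlopeComparison:
    groups: tuple[str, ...]
    slopes: dict
    interaction_F: float
    p_value: float
    df: tuple[int, int]
    degenerate: bool = False

    def summary(self) -> str:
        rows = "\n".join(f"  {g}: slope {s: .6g}" for g, s in self.slopes.items())
        flag = "  [degenerate: zero residual variance]" if self.degenerate else ""
        return (
            f"ANCOVA equality-of-slopes test ({len(self.groups)} groups)\n{rows}\n"
            f"  F({self.df[0]}, {self.df[1]}) = {self.interaction_F:.4g}, "
            f"p = {self.p_value:.6g}{flag}"
        )


def compare_slopes_ancova(
    datasets: Mapping[str, tuple[Sequence[float], Sequence[float]]]
) -> SlopeComparison:
    """Test equality of decay slopes across groups by pooled OLS.

    ``datasets`` maps group label -> (time, ln-fluorescence) points, already
    windowed and log-transformed (see ``kinetics.windowed_ln_points``). The
    full model ln F ~ time + group + time:group is compared with the reduced
    model without the interaction; the extra-sum-of-squares F statistic tests
    whether all group slopes are equal.

    Degenerate inputs are handled explicitly: an interaction sum of squares
    of (numerically) zero gives F = 0, p = 1; a zero residual with a nonzero
    interaction (noiseless lines with different slopes) is reported as p = 0
    with the ``degenerate`` flag set.
    """
    if len(datasets) < 2:
        raise DataError("ANCOVA requires at least 2 groups")
    slopes = {}
    rows = []
    for name, (t, lnf) in datasets.items():
        t = np.asarray(t, dtype=float)
        lnf = np.asarray(lnf, dtype=float)
        if len(t) < 3:
            raise DataError(f"group {name!r} has {len(t)} points; >= 3 required")
        slopes[name] = float(sps.linregress(t, lnf).slope)
        rows.append(pd.DataFrame({"time": t, "lnF": lnf, "group": str(name)}))
    data = pd.concat(rows, ignore_index=True)

    k = len(datasets)
    n = len(data)
    df_num = k - 1
    df_den = n - 2 * k
    if df_den < 1:
        raise DataError("not enough points for the interaction F-test")

    full = smf.ols("lnF ~ time * C(group)", data=data).fit()
    reduced = smf.ols("lnF ~ time + C(group)", data=data).fit()
    ss_interaction = float(reduced.ssr - full.ssr)
    ss_resid = float(full.ssr)

    scale = float(np.var(data["lnF"])) * n + 1e-300
    degenerate = False
    if ss_interaction <= _REL_TOL * scale:
        F, p = 0.0, 1.0
        if ss_resid <= _REL_TOL * scale:
            degenerate = True
            warnings.warn(
                "ANCOVA: zero interaction and zero residual variance",
                DegenerateStatisticsWarning,
            )
    elif ss_resid <= _REL_TOL * scale:
        F, p = float("inf"), 0.0
        degenerate = True
        warnings.warn(
            "ANCOVA: zero residual variance with nonzero slope difference; "
            "reporting p = 0",
            DegenerateStatisticsWarning,
        )
    else:
        F = (ss_interaction / df_num) / (ss_resid / df_den)
        p = float(sps.f.sf(F, df_num, df_den))

    return SlopeComparison(
        groups=tuple(str(g) for g in datasets),
        slopes=slopes,
        interaction_F=float(F),
        p_value=float(p),
        df=(df_num, df_den),
        degenerate=degenerate,
    )


def compare_halflives_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Unpaired two-tailed t-test on two collections of half-life values.

    Welch's unequal-variance form by default (experiments differ in spread);
    ``equal_var=True`` gives the pooled-variance textbook statistic. Returns
    (t, df, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError(
            f"t-test requires >= 2 values per group, got {len(a)} and {len(b)}"
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    if np.isnan(t):
        # both groups constant and equal: no evidence of difference
        warnings.warn(
            "t-test: zero variance in both groups", DegenerateStatisticsWarning
        )
        t, p = 0.0, 1.0
    return t, df, p


def halflife_anova(table: pd.DataFrame) -> pd.DataFrame:
    """Two-factor ANOVA of half-life on age group and sex with interaction.

    Expects columns ``half_life``, ``age_group`` and ``sex``. Fits the linear
    model half_life ~ age_group * sex and returns the sequential (Type-I)
    ANOVA table — the behaviour of base R's ``anova(lm(...))`` — with one row
    per term (age_group, sex, age_group:sex, Residual) and columns df,
    sum_sq, F, p.

    If all responses are equal the F statistics are 0/0; by documented
    convention they are reported as F = 0, p = 1 with a warning.
    """
    required = {"half_life", "age_group", "sex"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"half-life table is missing columns: {sorted(missing)}")
    for factor in ("age_group", "sex"):
        if table[factor].nunique() < 2:
            raise DataError(f"factor {factor!r} needs >= 2 levels")
    cells = table.groupby(["age_group", "sex"], observed=True).size()
    n_cells = table["age_group"].nunique() * table["sex"].nunique()
    if len(cells) < n_cells:
        raise DataError("empty age x sex cells make the interaction unidentifiable")

    if float(np.var(table["half_life"])) == 0.0:
        warnings.warn(
            "ANOVA: response has zero variance; reporting F = 0, p = 1",
            DegenerateStatisticsWarning,
        )
        df_fac = {
            "age_group": table["age_group"].nunique() - 1,
            "sex": table["sex"].nunique() - 1,
        }
        df_fac["age_group:sex"] = df_fac["age_group"] * df_fac["sex"]
        resid_df = len(table) - 1 - sum(df_fac.values())
        out = pd.DataFrame(
            {
                "df": list(df_fac.values()) + [resid_df],
                "sum_sq": 0.0,
                "F": [0.0, 0.0, 0.0, np.nan],
                "p": [1.0, 1.0, 1.0, np.nan],
            },
            index=list(df_fac) + ["Residual"],
        )
        return out

    model = smf.ols("half_life ~ C(age_group) * C(sex)", data=table).fit()
    aov = sm.stats.anova_lm(model, typ=1)
    aov = aov.rename(
        index={
            "C(age_group)": "age_group",
            "C(sex)": "sex",
            "C(age_group):C(sex)": "age_group:sex",
        },
        columns={"PR(>F)": "p"},
    )
    return aov[["df", "sum_sq", "F", "p"]]


def compare_peaks(
    group_a_peaks: Sequence[float], group_b_peaks: Sequence[float]
) -> tuple[float, float]:
    """t-test on per-vial peak-day fluorescence between two groups.

    Peak level reflects synthesis and accumulation, complementing the
    half-life (degradation) comparison. Returns (t, p).
    """
    a = np.asarray(group_a_peaks, dtype=float)
    b = np.asarray(group_b_peaks, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError(
            f"peak comparison requires >= 2 vials per group, got {len(a)} and {len(b)}"
        )
    t, _, p = compare_halflives_ttest(a, b)
    return t, p
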