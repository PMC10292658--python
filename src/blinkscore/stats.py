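"""Statistical contracts for group comparisons.

The reporting conventions follow the study design: unpaired two-sample
t-tests for pairwise comparisons; two-way ANOVA (strain x lobule/layer)
for section measurements; two-way repeated-measures (mixed) ANOVA
(strain between animals, session/radius within) for learning curves and
Sholl profiles; Bonferroni-corrected planned comparisons after significant
effects; alpha = 0.05. Main strain effects are reported regardless of
significance.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class AnovaEffect:
    name: str  # "strain" | "factor2" | "interaction"
    F: float
    df_num: float
    df_den: float
    p: float


@dataclass
class AnovaResult:
    effects: dict[str, AnovaEffect]
    post_hoc: Optional[pd.DataFrame] = None
    alpha: float = ALPHA
    repeated: bool = False

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]


def two_sample_test(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> TTestResult:
    """Unpaired two-sample t-test, two-sided.

    Equal-variance by default; set ``equal_var=False`` for Welch. Two
    zero-variance groups with equal means return t = 0, p = 1 by
    convention rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return TTestResult(t=0.0, df=float(len(x) + len(y) - 2), p=1.0)
        return TTestResult(t=np.inf, df=float(len(x) + len(y) - 2), p=0.0)
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def _check_columns(table: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns {missing}")


def two_way_anova(
    table: pd.DataFrame,
    dv: str = "value",
    between: str = "strain",
    factor2: str = "level",
    subject: str = "animal_id",
    repeated: bool = False,
) -> AnovaResult:
    """Two-way ANOVA of ``dv`` on ``between`` (strain) x ``factor2``.

    With ``repeated=True`` the second factor is within-animal and a mixed
    (split-plot) ANOVA partitions within-animal variance over it; the
    design must then be complete (every animal at every level). With a
    single factor2 level either version collapses to a one-way
    between-group ANOVA, whose F equals the squared two-sample t.
    """
    _check_columns(table, [dv, between, factor2, subject])
    levels = table[factor2].unique()
    if len(levels) <= 1:
        groups = [g[dv].to_numpy() for _, g in table.groupby(between, observed=True)]
        if len(groups) != 2:
            raise ValueError("between factor must have exactly 2 levels")
        f, p = sps.f_oneway(*groups)
        eff = AnovaEffect(
            "strain",
            F=float(f),
            df_num=1.0,
            df_den=float(len(table) - 2),
            p=float(p),
        )
        return AnovaResult(effects={"strain": eff}, repeated=repeated)

    if repeated:
        counts = table.pivot_table(
            index=subject, columns=factor2, values=dv, aggfunc="size", observed=True
        )
        incomplete = counts.isna() | (counts != 1)
        if incomplete.any().any():
            bad = [
                (str(counts.index[i]), str(counts.columns[j]))
                for i, j in zip(*np.where(incomplete))
            ]
            raise ValueError(
                "repeated-measures design incomplete; offending "
                f"(subject, level) cells: {bad[:10]}"
            )
        aov = pg.mixed_anova(
            data=table,
            dv=dv,
            within=factor2,
            subject=subject,
            between=between,
            correction=False,
        )
        name_map = {between: "strain", factor2: "factor2", "Interaction": "interaction"}
        effects = {}
        for _, row in aov.iterrows():
            key = name_map.get(row["Source"])
            if key is None:
                continue
            effects[key] = AnovaEffect(
                key,
                F=float(row["F"]),
                df_num=float(row["DF1"]),
                df_den=float(row["DF2"]),
                p=float(row["p_unc"]),
            )
        return AnovaResult(effects=effects, repeated=True)

    data = table.rename(columns={dv: "_dv", between: "_b", factor2: "_f"})
    model = smf.ols("_dv ~ C(_b) * C(_f)", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    key_map = {
        "C(_b)": "strain",
        "C(_f)": "factor2",
        "C(_b):C(_f)": "interaction",
    }
    df_resid = float(aov.loc["Residual", "df"])
    effects = {}
    for row_name, key in key_map.items():
        effects[key] = AnovaEffect(
            key,
            F=float(aov.loc[row_name, "F"]),
            df_num=float(aov.loc[row_name, "df"]),
            df_den=df_resid,
            p=float(aov.loc[row_name, "PR(>F)"]),
        )
    return AnovaResult(effects=effects, repeated=False)


def bonferroni_adjust(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Bonferroni correction: p_adjusted = min(1, p x m).

    ``m`` defaults to the family size len(p_values); adjusted p-values are
    never below the raw ones.
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    return np.minimum(1.0, p * m)


def planned_comparisons(
    table: pd.DataFrame,
    dv: str = "value",
    between: str = "strain",
    factor2: str = "level",
    comparisons: Optional[Sequence] = None,
    family_size: Optional[int] = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Bonferroni-corrected per-level strain comparisons after an ANOVA.

    One unpaired t-test per ``factor2`` level (the comparisons plotted per
    panel); the correction family defaults to the number of comparisons.
    Returns an empty table for an empty comparison list.
    """
    _check_columns(table, [dv, between, factor2])
    if comparisons is None:
        comparisons = list(pd.unique(table[factor2]))
    if len(comparisons) == 0:
        return pd.DataFrame(
            columns=["level", "mean_diff", "t", "df", "p", "p_adjusted"]
        )
    strains = sorted(table[between].unique())
    if len(strains) != 2:
        raise ValueError("planned comparisons need exactly 2 strain levels")
    rows = []
    for level in comparisons:
        sub = table[table[factor2] == level]
        a = sub.loc[sub[between] == strains[0], dv].to_numpy()
        b = sub.loc[sub[between] == strains[1], dv].to_numpy()
        res = two_sample_test(a, b, equal_var=equal_var)
        rows.append(
            {
                "level": level,
                "mean_diff": float(np.mean(b) - np.mean(a)),
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bonferroni_adjust(
        out["p"].to_numpy(), family_size if family_size is not None else len(out)
    )
    return out


def anova_report(result: AnovaResult) -> dict:
    """JSON-serializable view of an AnovaResult."""
    rep: dict = {
        "alpha": result.alpha,
        "repeated": result.repeated,
        "effects": {
            k: {"F": e.F, "df_num": e.df_num, "df_den": e.df_den, "p": e.p}
            for k, e in result.effects.items()
        },
    }
    if result.post_hoc is not None:
        rep["post_hoc"] = result.post_hoc.to_dict(orient="records")
    return rep
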