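"""Linear mixed-model comparison of baseline vs induced lameness.

One model per variable and gait: stride-level values with horse as random
intercept and condition as fixed effect, fitted by restricted maximum
likelihood.  Model estimates are reported as least-square means (the
model-based condition means at balanced weighting); p-values are adjusted
across the modelled variables with the Bonferroni correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class ModelResult:
    variable: str
    gait: str
    ls_mean_baseline: float
    ls_mean_lame: float
    difference: float
    percent_change: float
    p_raw: float
    p_bonferroni: float
    n_strides: int
    n_horses: int
    fallback: bool = False  # pooled two-sample estimate after singular fit


def bonferroni(p_values: Iterable[float], m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p), elementwise."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def fit_condition_model(
    values: Sequence[float],
    horse_ids: Sequence[str],
    conditions: Sequence[str],
    variable: str = "",
    gait: str = "",
) -> ModelResult:
    """Fit value ~ condition + (1 | horse) by REML for one variable.

    Horses present in only one condition are excluded with a warning.  A
    singular or non-converging fit falls back to a pooled two-sample
    comparison, flagged in the result.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float),
         "horse_id": list(horse_ids),
         "condition": list(conditions)}
    ).dropna(subset=["value"])
    keep = df.groupby("horse_id")["condition"].nunique()
    dropped = keep[keep < 2].index.tolist()
    if dropped:
        logger.warning("%s: excluding horses with one condition only: %s", variable, dropped)
        df = df[~df["horse_id"].isin(dropped)]
    if df["horse_id"].nunique() < 2 or df["condition"].nunique() < 2:
        raise ValueError(f"{variable}: need >= 2 horses with both conditions")
    df["is_lame"] = (df["condition"] != "baseline").astype(float)

    beta0 = beta1 = p_raw = np.nan
    fallback = False
    overall_sd = float(df["value"].std())
    resid_var = float(df.groupby(["horse_id", "is_lame"])["value"].var().mean())
    try:
        if not np.isfinite(resid_var) or resid_var <= 1e-12 * max(overall_sd**2, 1e-300):
            raise np.linalg.LinAlgError("no within-condition variance")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("value ~ is_lame", df, groups=df["horse_id"])
            fit = model.fit(reml=True)
        if not np.isfinite(fit.bse.get("is_lame", np.nan)) or fit.bse["is_lame"] <= 0:
            raise np.linalg.LinAlgError("degenerate standard error")
        beta0 = float(fit.params["Intercept"])
        beta1 = float(fit.params["is_lame"])
        p_raw = float(fit.pvalues["is_lame"])
        base_mean = float(df.loc[df["is_lame"] == 0, "value"].mean())
        if abs(beta0 - base_mean) > 0.2 * (abs(base_mean) + overall_sd) + 1e-12:
            raise np.linalg.LinAlgError("implausible intercept (singular fit)")
    except Exception as exc:  # singular fit, convergence failure
        logger.info("%s: mixed model failed (%s); paired horse-mean fallback",
                    variable, exc)
        fallback = True
        means = df.groupby(["horse_id", "is_lame"])["value"].mean().unstack()
        beta0 = float(means[0.0].mean())
        beta1 = float((means[1.0] - means[0.0]).mean())
        d = (means[1.0] - means[0.0]).to_numpy()
        if np.std(d) > 0:
            from scipy.stats import ttest_1samp

            p_raw = float(ttest_1samp(d, 0.0).pvalue)
        else:
            p_raw = 0.0 if abs(beta1) > 0 else 1.0

    pct = 100.0 * beta1 / beta0 if beta0 != 0 else np.inf * np.sign(beta1)
    return ModelResult(
        variable=variable,
        gait=gait,
        ls_mean_baseline=beta0,
        ls_mean_lame=beta0 + beta1,
        difference=beta1,
        percent_change=float(pct),
        p_raw=p_raw,
        p_bonferroni=np.nan,  # filled by model_table once m is known
        n_strides=int(len(df)),
        n_horses=int(df["horse_id"].nunique()),
        fallback=fallback,
    )


def model_table(
    strides: pd.DataFrame,
    variables: Optional[Sequence[str]] = None,
    gait: Optional[str] = None,
    m: Optional[int] = None,
) -> pd.DataFrame:
    """Fit the condition model for every variable of one gait.

    ``m`` for the Bonferroni correction defaults to the number of variables
    actually modelled.  Walk and trot are analysed in separate models; pass
    ``gait`` to subset a mixed table.
    """
    df = strides if gait is None else strides[strides["gait"] == gait]
    if variables is None:
        variables = sorted(df["variable"].unique())
    results: List[ModelResult] = []
    for var in variables:
        sub = df[df["variable"] == var]
        if sub.empty:
            continue
        try:
            res = fit_condition_model(
                sub["value"], sub["horse_id"], sub["condition"],
                variable=var, gait=gait or (sub["gait"].iloc[0] if "gait" in sub else ""),
            )
        except ValueError as exc:
            logger.warning("skipping %s: %s", var, exc)
            continue
        results.append(res)
    if not results:
        return pd.DataFrame()
    m_eff = m if m is not None else len(results)
    table = pd.DataFrame([r.__dict__ for r in results])
    table["p_bonferroni"] = bonferroni(table["p_raw"], m_eff)
    return table.sort_values("variable").reset_index(drop=True)
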