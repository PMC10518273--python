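"""Mixed-model comparison of biomechanical properties across groups.

Because several samples come from each cadaver donor, group comparisons
of moduli use a linear mixed-effects model

    response = grand mean + group fixed effect + donor random intercept
               + residual,

fitted by REML, with pairwise group contrasts tested by Fisher's LSD
(model-based standard errors, no multiplicity adjustment).  Degrees of
freedom for the contrast t-tests use the between-within approximation
``df = N - n_groups - (n_donors - 1)``, recorded in every result.

Three grouping systems mirror the classifier designs: pooled OARSI
groups (normal vs OA, normal vs early OA), SVM prediction groups, and
the three-group normal / early OA / advanced OA comparison.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .records import pool_grade

RESPONSES = ("E_eq_MPa", "E_inst_MPa", "E_dyn_MPa", "phase_deg", "thickness_mm")

GROUPINGS = ("oarsi_classifier1", "oarsi_classifier2",
             "prediction_classifier1", "prediction_classifier2", "three_group")


@dataclass
class MixedModelResult:
    """REML fit summary for one response/grouping."""

    response: str
    group_levels: tuple[str, ...]
    group_means: dict
    fixed_effects: pd.DataFrame = field(repr=False)
    random_intercept_var: float = float("nan")
    residual_var: float = float("nan")
    n_obs: int = 0
    n_donors: int = 0
    df_contrast: float = float("nan")
    singular: bool = False
    _fit: object = field(default=None, repr=False)
    _param_names: tuple[str, ...] = ()


def fit_mixed_model(data: pd.DataFrame, response: str, *,
                    group_col: str = "group",
                    donor_col: str = "donor_id") -> MixedModelResult:
    """Fit ``response ~ group`` with a donor random intercept (REML)."""
    df = data[[response, group_col, donor_col]].dropna()
    levels = tuple(sorted(df[group_col].astype(str).unique()))
    donors = df[donor_col].unique()
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if len(donors) < 2:
        raise ValueError("need at least 2 donors")
    endog = df[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(endog)):
        raise ValueError("response contains non-finite values")

    exog = np.column_stack(
        [np.ones(len(df))]
        + [(df[group_col].astype(str) == g).to_numpy(float) for g in levels[1:]])
    names = ("Intercept",) + tuple(f"{group_col}[{g}]" for g in levels[1:])

    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(endog, exog, groups=df[donor_col].to_numpy())
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except np.linalg.LinAlgError:
            fit = model.fit(reml=True, method="powell")
    re_var = float(np.atleast_2d(fit.cov_re)[0, 0])
    if re_var < 1e-10:
        singular = True

    params = np.asarray(fit.fe_params)
    means = {levels[0]: params[0]}
    for i, g in enumerate(levels[1:]):
        means[g] = params[0] + params[1 + i]

    n, p = len(df), len(levels)
    df_contrast = max(n - p - (len(donors) - 1), 1)
    fe = pd.DataFrame({"param": names, "estimate": params,
                       "se": np.sqrt(np.diag(fit.cov_params())[:p])})
    return MixedModelResult(
        response=response, group_levels=levels, group_means=means,
        fixed_effects=fe, random_intercept_var=re_var,
        residual_var=float(fit.scale), n_obs=n, n_donors=len(donors),
        df_contrast=float(df_contrast), singular=singular,
        _fit=fit, _param_names=names)


def lsd_posthoc(result: MixedModelResult, contrasts=None,
                *, alpha: float = 0.05, holm: bool = False) -> pd.DataFrame:
    """Pairwise group contrasts at unadjusted alpha (Fisher's LSD).

    Each row gives the difference ``a - b`` of estimated group means, its
    model-based SE, t statistic, p-value and confidence interval.  With
    ``holm`` a Holm step-down adjustment is added for users who want
    multiplicity control.
    """
    levels = result.group_levels
    if contrasts is None:
        contrasts = list(itertools.combinations(levels, 2))
    fit = result._fit
    cov = np.asarray(fit.cov_params())[:len(levels), :len(levels)]
    params = np.asarray(fit.fe_params)

    def coef_vec(g):
        v = np.zeros(len(levels))
        v[0] = 1.0
        if g != levels[0]:
            v[levels.index(g)] = 1.0
        return v

    rows = []
    tcrit = stats.t.ppf(1 - alpha / 2, result.df_contrast)
    for a, b in contrasts:
        for g in (a, b):
            if g not in levels:
                raise ValueError(f"contrast references absent group {g!r}")
        c = coef_vec(a) - coef_vec(b)
        est = float(c @ params)
        # singular fits can leave a slightly negative quadratic form
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        tval = est / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(tval), result.df_contrast) if se > 0 else np.nan
        rows.append({"contrast": f"{a} - {b}", "estimate": est, "se": se,
                     "t": tval, "df": result.df_contrast, "p": p,
                     "ci_low": est - tcrit * se, "ci_high": est + tcrit * se,
                     "significant": p < alpha})
    out = pd.DataFrame(rows)
    if holm:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_holm"] = adj
        out["significant_holm"] = out["p_holm"] < alpha
    return out


def _grouping_labels(manifest: pd.DataFrame, grouping: str,
                     predictions: dict | None) -> pd.Series:
    """Per-sample group labels under one grouping design (NaN = excluded)."""
    grades = manifest["oarsi_grade"]
    if grouping == "oarsi_classifier1":
        return pd.Series(np.where(grades <= 1, "normal", "oa"),
                         index=manifest.index)
    if grouping == "oarsi_classifier2":
        lab = np.where(grades <= 1, "normal",
                       np.where(grades <= 3, "early_oa", None))
        return pd.Series(lab, index=manifest.index)
    if grouping == "three_group":
        return grades.map(pool_grade)
    if grouping in ("prediction_classifier1", "prediction_classifier2"):
        task = "classifier1" if grouping.endswith("1") else "classifier2"
        if not predictions or task not in predictions:
            raise ValueError(f"no predictions supplied for {grouping}")
        pred = predictions[task].set_index("sample_id")["predicted_group"]
        pos = "oa" if task == "classifier1" else "early_oa"
        mapped = manifest["sample_id"].map(pred)
        lab = mapped.map({0: "normal", 1: pos})
        return pd.Series(lab, index=manifest.index)
    raise ValueError(f"unknown grouping {grouping!r}")


def build_comparison_tables(moduli: pd.DataFrame, manifest: pd.DataFrame,
                            predictions: dict | None = None, *,
                            groupings=("oarsi_classifier1",
                                       "prediction_classifier1"),
                            responses: tuple[str, ...] = RESPONSES[:4],
                            per_site: bool = True,
                            pooled: bool = True) -> pd.DataFrame:
    """Long-format contrast table across sites, responses and groupings.

    One row per (site, response, grouping, contrast) with estimate,
    confidence interval and LSD p-value; rows that cannot be fitted
    (missing group or single donor) are emitted with a ``skipped``
    reason so the table structure stays complete.
    """
    need = {"sample_id", "donor_id", "site", "oarsi_grade"}
    if not need <= set(manifest.columns):
        raise ValueError(f"manifest missing columns {need - set(manifest.columns)}")
    data = manifest.merge(moduli, on="sample_id", how="inner")
    if data.empty:
        raise ValueError("no samples shared between manifest and moduli")

    scopes = []
    if per_site:
        scopes += [(s, data[data["site"] == s]) for s in sorted(data["site"].unique())]
    if pooled:
        scopes.append(("pooled", data))

    rows = []
    for grouping in groupings:
        for site, sub in scopes:
            labels = _grouping_labels(sub, grouping, predictions)
            sub = sub.assign(_group=labels.values).dropna(subset=["_group"])
            for response in responses:
                base = {"site": site, "grouping": grouping, "response": response}
                try:
                    res = fit_mixed_model(sub, response, group_col="_group")
                    post = lsd_posthoc(res)
                except ValueError as err:
                    rows.append({**base, "contrast": None, "estimate": np.nan,
                                 "ci_low": np.nan, "ci_high": np.nan,
                                 "p": np.nan, "significant": False,
                                 "n": len(sub), "skipped": str(err)})
                    continue
                for _, c in post.iterrows():
                    rows.append({**base, "contrast": c["contrast"],
                                 "estimate": c["estimate"],
                                 "ci_low": c["ci_low"], "ci_high": c["ci_high"],
                                 "p": c["p"], "significant": bool(c["significant"]),
                                 "n": res.n_obs, "skipped": ""})
    return pd.DataFrame(rows)
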