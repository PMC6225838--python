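"""Trend and relationship models for suitability and functional dispersion.

Three model families summarise the pipeline outputs:

* a community linear mixed model of the transformed suitability
  response with fixed effects for sampling year (categorical, earliest
  year as baseline) and exposure class, and crossed random intercepts
  for site, predator species and trait;
* per-species mixed models of the same form (random site and trait
  intercepts), with the response re-standardised within each species;
* a mixed model of functional dispersion on year with random site
  intercepts, and an ordinary least-squares regression of mean
  assemblage suitability S on FDis (closed-form, not delegated).

The response is Gaussian on the log scale, so the mixed models are
linear mixed models fitted by REML (default) or ML through
statsmodels' variance-components machinery; one all-encompassing
group with indicator variance components yields the crossed random
intercepts.  Reported p-values for fixed effects use the large-sample
normal approximation to the Wald statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .community import FDisTable
from .suitability import SuitabilityTable
from .types import EXPOSED, ValidationError

__all__ = [
    "ModelResult",
    "fit_community_model",
    "fit_species_models",
    "fit_fdis_trend",
    "fit_fdis_rs_lm",
    "significance_matrix",
]


@dataclass(frozen=True)
class ModelResult:
    """Fixed-effect table, variance components and fit diagnostics."""

    formula: str
    fixed_effects: pd.DataFrame = field(repr=False)  # estimate, se, tvalue, pvalue
    random_variances: dict[str, float]
    fit_info: dict

    # populated for the simple regression only
    slope: float | None = None
    intercept: float | None = None
    adj_r2: float | None = None

    def __post_init__(self) -> None:
        p = self.fixed_effects["pvalue"].to_numpy()
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("p-values must lie in [0, 1]")

    def summary_frame(self) -> pd.DataFrame:
        return self.fixed_effects.copy()


def _exposure_numeric(values: pd.Series) -> np.ndarray:
    # sheltered = 0, exposed = 1 (|estimate| is coding-invariant)
    return (values == EXPOSED).astype(float).to_numpy()


def _year_terms(years: pd.Series) -> tuple[pd.DataFrame, list[str], int]:
    levels = sorted(years.unique())
    base = levels[0]
    cols = {str(y): (years == y).astype(float).to_numpy() for y in levels[1:]}
    return pd.DataFrame(cols), [str(y) for y in levels[1:]], base


def _clean_term(term: str) -> str:
    return term.replace("year_", "")


def _fit_lmm(
    data: pd.DataFrame,
    response: str,
    vc_factors: list[str],
    method: str,
    formula_label: str,
) -> ModelResult:
    """Gaussian LMM with crossed random intercepts via variance components.

    Random factors with fewer than two levels carry no variance and are
    dropped; with no usable random factor the model degenerates to OLS
    on the same fixed design.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    year_df, year_names, base = _year_terms(data["year"])
    frame = pd.DataFrame({"_y": data[response].to_numpy()})
    fixed_terms: list[str] = []
    for name in year_names:
        frame[f"year_{name}"] = year_df[name].to_numpy()
        fixed_terms.append(f"year_{name}")
    if data["exposure"].nunique() > 1:
        frame["exposure"] = _exposure_numeric(data["exposure"])
        fixed_terms.append("exposure")
    rhs = " + ".join(fixed_terms) if fixed_terms else "1"

    usable = [f for f in vc_factors if data[f].nunique() > 1]
    dropped = [f for f in vc_factors if f not in usable]
    if not usable:
        ols = sm.OLS.from_formula(f"_y ~ {rhs}", data=frame).fit()
        fe = pd.DataFrame(
            {
                "estimate": ols.params,
                "se": ols.bse,
                "tvalue": ols.tvalues,
                "pvalue": ols.pvalues,
            }
        )
        fe.index = [_clean_term(t) for t in fe.index]
        return ModelResult(
            formula=formula_label,
            fixed_effects=fe,
            random_variances={},
            fit_info={
                "method": "OLS (no random factor with >1 level)",
                "converged": True,
                "n_obs": int(len(data)),
                "baseline_year": base,
                "dropped_random_factors": dropped,
            },
        )

    for f in usable:
        frame[f] = data[f].astype(str).to_numpy()
    frame["_group"] = 0  # one all-encompassing group -> crossed intercepts
    model = sm.MixedLM.from_formula(
        f"_y ~ {rhs}",
        groups="_group",
        vc_formula={f: f"0 + C({f})" for f in usable},
        re_formula="0",
        data=frame,
    )
    refit = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=(method == "reml"), method="lbfgs", maxiter=500)
        if not fit.converged:
            # boundary-flat variance surfaces: polish with a derivative-free step
            fit = model.fit(
                reml=(method == "reml"),
                method="powell",
                maxiter=2000,
                start_params=fit.params_object,
            )
            refit = True
    k = len(fixed_terms) + 1
    est = np.asarray(fit.params)[:k]
    se = np.asarray(fit.bse)[:k]
    tval = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    pval = 2 * stats.norm.sf(np.abs(tval))
    fe = pd.DataFrame(
        {"estimate": est, "se": se, "tvalue": tval, "pvalue": pval},
        index=[_clean_term(t) for t in fit.model.exog_names[:k]],
    )
    return ModelResult(
        formula=formula_label,
        fixed_effects=fe,
        random_variances={f: float(v) for f, v in zip(usable, fit.vcomp)},
        fit_info={
            "method": method.upper(),
            "converged": bool(fit.converged),
            "refit": refit,
            "n_obs": int(len(data)),
            "baseline_year": base,
            "dropped_random_factors": dropped,
            "resid_var": float(fit.scale),
        },
    )


def fit_community_model(table: SuitabilityTable, method: str = "reml") -> ModelResult:
    """Community-wide trend in transformed suitability.

    Fixed year (baseline = earliest) and exposure; crossed random
    intercepts for site, predator species and trait.
    """
    if not table.has_transform:
        raise ValidationError("transformed values missing; call transform_rs first")
    data = table.records.rename(columns={"predator": "species"})
    return _fit_lmm(
        data,
        response="rs_transformed",
        vc_factors=["site", "species", "trait"],
        method=method,
        formula_label="rs_transformed ~ year + exposure + (1|site) + (1|species) + (1|trait)",
    )


def fit_species_models(
    table: SuitabilityTable,
    method: str = "reml",
    rescale_within_species: bool = True,
) -> dict[str, ModelResult]:
    """One suitability trend model per predator species.

    Each species' records keep the global log transform but are by
    default re-z-scored within the species, so estimates are in units
    of that species' own response spread.  Random intercepts: site and
    trait.
    """
    if not table.has_transform:
        raise ValidationError("transformed values missing; call transform_rs first")
    out: dict[str, ModelResult] = {}
    for species, sub in table.records.groupby("predator", sort=True):
        data = sub.copy()
        if rescale_within_species:
            t = data["rs_transformed"].to_numpy()
            sd = t.std(ddof=1)
            if sd == 0:
                raise ValidationError(f"constant response for species {species!r}")
            data["rs_transformed"] = (t - t.mean()) / sd
        out[str(species)] = _fit_lmm(
            data,
            response="rs_transformed",
            vc_factors=["site", "trait"],
            method=method,
            formula_label="rs_transformed ~ year + exposure + (1|site) + (1|trait)",
        )
    return out


def fit_fdis_trend(fdis: FDisTable, method: str = "reml") -> ModelResult:
    """Temporal trend in functional dispersion with random site intercepts."""
    data = fdis.to_frame()
    if data["year"].nunique() < 2:
        raise ValidationError("FDis trend model needs at least 2 sampling years")
    return _fit_lmm(
        data,
        response="fdis",
        vc_factors=["site"],
        method=method,
        formula_label="fdis ~ year + (1|site)",
    )


def fit_fdis_rs_lm(fdis: FDisTable, s: pd.DataFrame) -> ModelResult:
    """OLS of mean assemblage suitability S on functional dispersion.

    The slope, intercept, t-test and adjusted R² come from the textbook
    closed forms rather than a library fit.  ``s`` must carry columns
    site/year/S as produced by ``assemblage_mean_suitability``.
    """
    left = fdis.to_frame()[["site", "year", "fdis"]]
    merged = left.merge(s[["site", "year", "S"]], on=["site", "year"], how="inner")
    n = len(merged)
    if n < 3:
        raise ValidationError("regression needs at least 3 matched assemblages")
    x = merged["fdis"].to_numpy(float)
    y = merged["S"].to_numpy(float)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx == 0:
        raise ValidationError("FDis has no variance; slope undefined")
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    sse = (resid**2).sum()
    sst = ((y - ym) ** 2).sum()
    sigma2 = sse / (n - 2)
    se_slope = np.sqrt(sigma2 / sxx)
    se_inter = np.sqrt(sigma2 * (1.0 / n + xm**2 / sxx))
    t_slope = slope / se_slope if se_slope > 0 else 0.0
    t_inter = intercept / se_inter if se_inter > 0 else 0.0
    p_slope = 2 * stats.t.sf(abs(t_slope), df=n - 2)
    p_inter = 2 * stats.t.sf(abs(t_inter), df=n - 2)
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    fe = pd.DataFrame(
        {
            "estimate": [intercept, slope],
            "se": [se_inter, se_slope],
            "tvalue": [t_inter, t_slope],
            "pvalue": [p_inter, p_slope],
        },
        index=["Intercept", "fdis"],
    )
    return ModelResult(
        formula="S ~ fdis",
        fixed_effects=fe,
        random_variances={},
        fit_info={"method": "OLS closed form", "converged": True, "n_obs": n},
        slope=float(slope),
        intercept=float(intercept),
        adj_r2=float(adj_r2),
    )


def significance_matrix(
    results: dict[str, ModelResult], alpha_codes: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1)
) -> pd.DataFrame:
    """Sign/significance overview of the per-species models.

    One row per species, one column per fixed term (years beyond the
    baseline plus exposure); entries combine the estimate's sign with a
    significance code (``***``, ``**``, ``*``, ``.`` or blank).
    """
    rows = {}
    for species, res in results.items():
        row = {}
        for term, rec in res.fixed_effects.iterrows():
            if term == "Intercept":
                continue
            stars = ""
            for code, sym in zip(alpha_codes, ("***", "**", "*", ".")):
                if rec["pvalue"] < code:
                    stars = sym
                    break
            row[term] = f"{'+' if rec['estimate'] >= 0 else '-'}{stars}"
        rows[species] = row
    return pd.DataFrame.from_dict(rows, orient="index")
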