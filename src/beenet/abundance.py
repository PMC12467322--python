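"""Abundance comparisons between plot types and relative-change regressions.

Two model families quantify the honeybee effect:

* per native species, a negative-binomial GLM (log link) of sweep-net counts
  on plot type (nearby vs distant), the replication unit being one plot x one
  survey round;
* across species, Gaussian linear models of the relative change in abundance
  on PAC_D, PAC_C, baseline (distant) abundance, or baseline abundance x
  PAC_D with interaction.

Relative change is (distant - nearby) / distant: positive values mean decline
near apiaries, and a species undetected nearby scores exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

SWEEP_COLUMNS = ("plot_id", "plot_type", "survey_round", "bee_species", "count")

#: Predictor sets accepted by :func:`fit_change_model`.
CHANGE_MODELS = {
    "pac_d": "relative_change ~ pac_d",
    "pac_c": "relative_change ~ pac_c",
    "abundance_distant": "relative_change ~ abundance_distant",
    "interaction": "relative_change ~ abundance_distant * pac_d",
}


class UndefinedChangeError(ValueError):
    """Relative change is undefined when the reference abundance is zero."""


class NonIdentifiableError(ValueError):
    """The model has no information to estimate its parameters."""


@dataclass
class ModelFit:
    """A fitted model reduced to the quantities the analysis reports."""

    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    df_resid: int
    nobs: int
    adj_rsquared: float | None = None
    dispersion: float | None = None  # NB alpha (var = mu + alpha*mu^2)
    boundary_warning: bool = False
    result: object = field(default=None, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "p": self.pvalues}
        )


def relative_change(distant: float, nearby: float) -> float:
    """(distant − nearby) / distant; positive = decline near apiaries."""
    if distant <= 0:
        raise UndefinedChangeError(
            "relative change undefined: zero abundance in distant (reference) plots"
        )
    return (distant - nearby) / distant


def abundance_change_table(
    sweeps: pd.DataFrame, unit: str = "plot_survey"
) -> pd.DataFrame:
    """Per-species mean abundances by plot type and their relative change.

    ``mean_abundance_*`` is the mean count per plot per survey round (species
    missing from a plot type count as zero there).  Species with zero
    abundance in the distant plots are dropped with a warning: the relative
    change has no reference for them.
    """
    _check_sweep_schema(sweeps)
    wide = (
        sweeps.groupby(["bee_species", "plot_type"])["count"].sum().unstack(fill_value=0)
    )
    for t in ("nearby", "distant"):
        if t not in wide.columns:
            wide[t] = 0
    effort = sweeps.groupby("plot_type")[["plot_id", "survey_round"]].nunique()
    n_units = {
        t: effort.loc[t, "plot_id"] * effort.loc[t, "survey_round"]
        if t in effort.index
        else 1
        for t in ("nearby", "distant")
    }
    out = pd.DataFrame(
        {
            "mean_abundance_distant": wide["distant"] / n_units["distant"],
            "mean_abundance_nearby": wide["nearby"] / n_units["nearby"],
        }
    )
    undefined = out["mean_abundance_distant"] <= 0
    if undefined.any():
        warnings.warn(
            "dropping species with zero distant-plot abundance: "
            f"{sorted(out.index[undefined])}",
            stacklevel=2,
        )
        out = out[~undefined]
    out["relative_change"] = [
        relative_change(d, n)
        for d, n in zip(out["mean_abundance_distant"], out["mean_abundance_nearby"])
    ]
    out.index.name = "bee_species"
    return out.sort_index()


def fit_species_abundance_glm(
    sweeps: pd.DataFrame, species: str | None = None, unit: str = "plot_survey"
) -> ModelFit:
    """Negative-binomial GLM of one species' counts on plot type.

    The response is the count per replication unit — per plot per survey
    round by default (``unit="plot_total"`` sums the rounds within each
    plot).  Plot type enters as a treatment-coded indicator with *distant*
    as the reference level, so the reported coefficient is the log ratio of
    nearby to distant mean counts.  The dispersion parameter alpha
    (var = mu + alpha*mu^2) is estimated by maximum likelihood; p-values are
    Wald.

    A species observed in only one plot type still fits, but the result is
    flagged with ``boundary_warning`` because the group-mean log-ratio sits
    at the boundary of the parameter space.
    """
    _check_sweep_schema(sweeps)
    subset = sweeps
    if species is not None:
        subset = sweeps[sweeps["bee_species"] == species]
        if subset.empty:
            raise NonIdentifiableError(f"no sweep counts for species {species!r}")
    # The survey grid (which plot x round units exist) comes from the full
    # table, so units where the species went unrecorded contribute zeros.
    data = _replication_units(subset, unit, grid_source=sweeps)
    means = data.groupby("plot_type")["count"].mean()
    if means.get("nearby", 0) == 0 and means.get("distant", 0) == 0:
        raise NonIdentifiableError("all counts zero in both plot types")
    boundary = (means.get("nearby", 0) == 0) or (means.get("distant", 0) == 0)

    X = sm.add_constant(
        (data["plot_type"] == "nearby").astype(float).rename("plot_type_nearby")
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(data["count"].to_numpy(), X)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            res = model.fit(disp=0, method="nm", maxiter=2000)
    params = pd.Series(res.params, index=list(X.columns) + ["alpha"])
    bse = pd.Series(res.bse, index=params.index)
    pvals = pd.Series(res.pvalues, index=params.index)
    if bse.drop("alpha").isna().any():
        # Near the Poisson boundary (alpha -> 0) the full-likelihood Hessian
        # can be singular; Wald SEs then come from the GLM at fixed alpha.
        alpha_hat = max(float(params["alpha"]), 1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(
                data["count"].to_numpy(),
                X,
                family=sm.families.NegativeBinomial(alpha=alpha_hat),
            ).fit()
        for i, name in enumerate(X.columns):
            params[name] = np.asarray(glm.params)[i]
            bse[name] = np.asarray(glm.bse)[i]
            pvals[name] = np.asarray(glm.pvalues)[i]
    return ModelFit(
        formula=f"count ~ plot_type (NB, log link, unit={unit})",
        params=params.drop("alpha"),
        bse=bse.drop("alpha"),
        pvalues=pvals.drop("alpha"),
        df_resid=int(len(data) - 2),
        nobs=len(data),
        dispersion=float(params["alpha"]),
        boundary_warning=bool(boundary),
        result=res,
    )


def species_glm_table(sweeps: pd.DataFrame, unit: str = "plot_survey") -> pd.DataFrame:
    """One NB GLM per native species; one summary row per species."""
    rows = []
    for sp in sorted(sweeps["bee_species"].unique()):
        try:
            fit = fit_species_abundance_glm(sweeps, species=sp, unit=unit)
        except NonIdentifiableError:
            continue
        rows.append(
            {
                "bee_species": sp,
                "estimate_nearby": fit.params["plot_type_nearby"],
                "se": fit.bse["plot_type_nearby"],
                "p": fit.pvalues["plot_type_nearby"],
                "dispersion": fit.dispersion,
                "boundary": fit.boundary_warning,
            }
        )
    return pd.DataFrame(rows).set_index("bee_species").sort_index()


def fit_change_model(table: pd.DataFrame, predictors: str = "pac_d") -> ModelFit:
    """Gaussian linear model of relative change across species.

    ``table`` joins the abundance-change table with the PAC table; it must
    carry ``relative_change`` plus the columns the chosen predictor set uses
    (``pac_d``, ``pac_c``, ``abundance_distant``).  Species with a missing
    predictor value are dropped (the PAC_C model loses the species that
    disappeared from nearby plots).  Reports OLS estimates, Wald p-values,
    residual degrees of freedom and adjusted R².
    """
    if predictors not in CHANGE_MODELS:
        raise ValueError(
            f"unknown predictor set {predictors!r}; choose from {sorted(CHANGE_MODELS)}"
        )
    formula = CHANGE_MODELS[predictors]
    used = [c for c in ("pac_d", "pac_c", "abundance_distant") if c in formula]
    data = table.dropna(subset=["relative_change", *used])
    n_params = {"pac_d": 2, "pac_c": 2, "abundance_distant": 2, "interaction": 4}[
        predictors
    ]
    if len(data) < n_params + 1:
        raise NonIdentifiableError(
            f"{len(data)} complete cases cannot identify {n_params} parameters"
        )
    for c in used:
        if np.ptp(data[c].to_numpy()) == 0:
            raise NonIdentifiableError(f"predictor {c!r} is constant")
    res = smf.ols(formula, data=data).fit()
    return ModelFit(
        formula=formula,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        df_resid=int(res.df_resid),
        nobs=int(res.nobs),
        adj_rsquared=float(res.rsquared_adj),
        result=res,
    )


def _replication_units(
    sweeps: pd.DataFrame, unit: str, grid_source: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Expand sweep records into one count per replication unit.

    Units where the species was not recorded get an explicit zero, so every
    plot x survey round (or plot) contributes an observation.  The unit grid
    is taken from ``grid_source`` (default: the records themselves).
    """
    if unit not in ("plot_survey", "plot_total"):
        raise ValueError(f"unknown replication unit {unit!r}")
    keys = ["plot_id", "plot_type"] + (
        ["survey_round"] if unit == "plot_survey" else []
    )
    grid = (grid_source if grid_source is not None else sweeps)[keys].drop_duplicates()
    agg = sweeps.groupby(keys, as_index=False)["count"].sum()
    data = grid.merge(agg, on=keys, how="left").fillna({"count": 0})
    data["count"] = data["count"].astype(int)
    return data


def _check_sweep_schema(sweeps: pd.DataFrame) -> None:
    missing = [c for c in SWEEP_COLUMNS if c not in sweeps.columns]
    if missing:
        raise ValueError(f"sweep-count table missing column(s): {missing}")
    if (sweeps["count"] < 0).any():
        raise ValueError("negative sweep count")
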