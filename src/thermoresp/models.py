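"""Model fits: treatment mixed models, biome linear models, acclimation models.

Three model families, mirroring the analysis levels of the study design:

* per gene set, a Gaussian linear mixed model of the library-level
  bootstrapped median expression with treatment as a categorical fixed
  effect (control reference) and a random intercept per species, fit by
  REML.  Variance partitioning is summarised by the interclass correlation
  ICC = sigma2_species / (sigma2_species + sigma2_residual) and the marginal
  R2 of the treatment fixed effect;
* per gene set x contrast, a one-way fixed-effect linear model of the
  species-level fold change on biome of origin;
* per thermal trait x gene set, a simple linear regression of the species'
  thermal-tolerance acclimation delta on its fold-change response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .errors import ValidationError, ZeroVarianceError

_TREATMENT_ORDER = ("control", "cold", "hot")


@dataclass
class MixedModelResult:
    set_id: str
    contrasts: dict[str, dict[str, float]]  # 'cold'/'hot' -> estimate, t, df, p
    sigma2_species: float
    sigma2_residual: float
    icc: float
    marginal_r2: float
    n_obs: int
    n_species: int
    converged: bool
    singular: bool

    def to_rows(self) -> list[dict]:
        rows = []
        for contrast, c in self.contrasts.items():
            rows.append(
                {
                    "set_id": self.set_id,
                    "contrast": contrast,
                    "estimate": c["estimate"],
                    "t": c["t"],
                    "df": c["df"],
                    "p": c["p"],
                    "sigma2_species": self.sigma2_species,
                    "sigma2_residual": self.sigma2_residual,
                    "icc": self.icc,
                    "marginal_r2": self.marginal_r2,
                    "n_obs": self.n_obs,
                    "n_species": self.n_species,
                    "converged": self.converged,
                    "singular": self.singular,
                }
            )
        return rows


@dataclass
class BiomeModelResult:
    set_id: str
    contrast: str
    r_squared: float
    p_value: float
    n_species: int
    group_stats: pd.DataFrame = field(repr=False)  # biome, mean, se, n
    flagged_biomes: list[str] = field(default_factory=list)


@dataclass
class AcclimationModelResult:
    trait: str
    set_id: str
    slope: float
    t: float
    p_value: float
    adj_r_squared: float
    n_species: int
    min_n: int | None
    fc_median: float
    fc_min: float
    fc_max: float


def lmm_degrees_of_freedom(n_obs: int, n_species: int, n_levels: int) -> int:
    """Residual df convention: n_obs - n_species - (n_treatment_levels - 1)."""
    return n_obs - n_species - (n_levels - 1)


def fit_treatment_lmm(
    data: pd.DataFrame,
    set_id: str = "",
    df_mode: str = "residual",
) -> MixedModelResult:
    """Random-intercept mixed model of ``estimate ~ treatment + (1|species)``.

    ``data`` needs columns estimate, treatment, species_id (one row per
    library).  Control is the reference level; t statistics use the residual
    df convention by default (``df_mode='normal'`` uses the z approximation).
    A species variance collapsing to zero is flagged singular and reported
    with ICC 0 rather than dropped.
    """
    species = data["species_id"].to_numpy()
    if len(np.unique(species)) < 2:
        raise ValidationError(
            f"{set_id or 'lmm'}: needs >= 2 species (ICC undefined otherwise)"
        )
    levels = [t for t in _TREATMENT_ORDER if (data["treatment"] == t).any()]
    if len(levels) < 2 or "control" not in levels:
        raise ValidationError(f"{set_id or 'lmm'}: needs control plus >= 1 treatment")
    y = data["estimate"].to_numpy(float)
    n = y.size
    cols = [np.ones(n)]
    names = ["intercept"]
    for t in levels:
        if t == "control":
            continue
        cols.append((data["treatment"] == t).to_numpy(float))
        names.append(t)
    X = np.column_stack(cols)

    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=species)
        # optimizers occasionally stall; take the first that truly converges
        for method in ("cg", "bfgs", "powell", "nm"):
            try:
                cand = model.fit(reml=True, method=method)
            except Exception:
                continue
            if res is None:
                res = cand
            if getattr(cand, "converged", False):
                res = cand
                break
    if res is None:
        raise ValidationError(f"{set_id or 'lmm'}: mixed model fit failed")
    converged = bool(getattr(res, "converged", True))
    sigma2_sp = float(np.asarray(res.cov_re)[0, 0])
    sigma2_res = float(res.scale)
    singular = sigma2_sp < 1e-8 * max(sigma2_res, 1e-300)
    icc = 0.0 if singular else sigma2_sp / (sigma2_sp + sigma2_res)

    fe = np.asarray(res.fe_params, dtype=float)
    bse = np.asarray(res.bse_fe, dtype=float)
    n_species = len(np.unique(species))
    if df_mode == "residual":
        df = lmm_degrees_of_freedom(n, n_species, len(levels))
    elif df_mode == "normal":
        df = np.inf
    else:
        raise ValidationError(f"unknown df_mode '{df_mode}'")
    if df <= 0:
        raise ValidationError(f"{set_id or 'lmm'}: non-positive residual df")

    contrasts: dict[str, dict[str, float]] = {}
    for i, name in enumerate(names):
        if name == "intercept":
            continue
        tval = fe[i] / bse[i] if bse[i] > 0 else np.nan
        if np.isinf(df):
            p = 2 * st.norm.sf(abs(tval))
        else:
            p = 2 * st.t.sf(abs(tval), df)
        contrasts[name] = {
            "estimate": float(fe[i]),
            "t": float(tval),
            "df": float(df),
            "p": float(p),
        }

    fitted_fixed = X @ fe
    var_fixed = float(np.var(fitted_fixed, ddof=1))
    marginal_r2 = var_fixed / (var_fixed + sigma2_sp + sigma2_res)

    return MixedModelResult(
        set_id=set_id,
        contrasts=contrasts,
        sigma2_species=sigma2_sp,
        sigma2_residual=sigma2_res,
        icc=float(icc),
        marginal_r2=float(marginal_r2),
        n_obs=n,
        n_species=n_species,
        converged=converged,
        singular=bool(singular),
    )


def fit_biome_lm(
    species_fc: pd.Series,
    biomes: pd.Series,
    set_id: str = "",
    contrast: str = "",
) -> BiomeModelResult:
    """One-way linear model of species-level fold change on biome.

    Reports the multiple R2 and the overall F-test p value.  Degenerate
    cases: constant response gives R2 = 0, p = 1; an exact between-biome fit
    with zero within-biome variance gives R2 = 1, p -> 0.
    """
    df = pd.DataFrame({"fc": species_fc, "biome": biomes}).dropna()
    groups = df.groupby("biome")["fc"]
    if groups.ngroups < 2:
        raise ValidationError(f"{set_id}: biome model needs >= 2 biomes")
    flagged = [b for b, g in groups if len(g) < 2]

    y = df["fc"].to_numpy(float)
    dummies = pd.get_dummies(df["biome"], drop_first=True, dtype=float)
    X = sm.add_constant(dummies.to_numpy())
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 1e-300:
        r2, p = 0.0, 1.0
    else:
        res = sm.OLS(y, X).fit()
        r2 = float(res.rsquared)
        p = float(res.f_pvalue)
        if not np.isfinite(p):
            # zero residual variance: exact group separation
            p = 0.0 if res.ssr / tss < 1e-12 else 1.0
    stats = groups.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    stats["se"] = stats["sd"] / np.sqrt(stats["n"])
    stats.loc[stats["n"] < 2, "se"] = np.nan
    stats = stats.drop(columns="sd")
    return BiomeModelResult(
        set_id=set_id,
        contrast=contrast,
        r_squared=r2,
        p_value=p,
        n_species=len(df),
        group_stats=stats,
        flagged_biomes=flagged,
    )


def fit_acclimation_lm(
    acclimation: pd.Series,
    species_fc: pd.Series,
    trait: str,
    set_id: str = "",
    min_n: int | None = None,
) -> AcclimationModelResult:
    """Simple regression of a thermal acclimation delta on gene-set FC.

    ``acclimation`` and ``species_fc`` are species-indexed; only species with
    both values enter.  Reports the slope t and p, adjusted R2, and the FC
    median/min/max across species.
    """
    df = pd.DataFrame({"acc": acclimation, "fc": species_fc}).dropna()
    if len(df) < 4:
        raise ValidationError(
            f"{set_id}/{trait}: needs >= 4 species with trait and FC values"
        )
    fc = df["fc"].to_numpy(float)
    if np.ptp(fc) == 0:
        raise ZeroVarianceError(f"{set_id}/{trait}: zero FC variance across species")
    X = sm.add_constant(fc)
    res = sm.OLS(df["acc"].to_numpy(float), X).fit()
    slope = float(res.params[1])
    tval = float(res.tvalues[1])
    p = float(res.pvalues[1])
    if not np.isfinite(p):  # perfect fit
        p = 0.0
    adj = float(res.rsquared_adj)
    return AcclimationModelResult(
        trait=trait,
        set_id=set_id,
        slope=slope,
        t=tval,
        p_value=p,
        adj_r_squared=adj,
        n_species=len(df),
        min_n=min_n,
        fc_median=float(np.median(fc)),
        fc_min=float(fc.min()),
        fc_max=float(fc.max()),
    )


def rank_results(
    results: pd.DataFrame,
    by: str = "adj_r2",
    top_k: int | None = None,
    add_bh_fdr: bool = False,
) -> pd.DataFrame:
    """Order fitted results for reporting.

    Descending for R2-like columns and |t|, ascending for p; ties broken by
    set_id lexicographically (stable, deterministic).  An optional
    Benjamini-Hochberg column can be added but is off by default: with 20
    species the emphasis is on effect sizes rather than corrected p values.
    """
    df = results.copy()
    if by in ("adj_r2", "r_squared", "adj_r_squared"):
        col = by if by in df.columns else "adj_r_squared"
        key, ascending = df[col], False
    elif by == "t":
        key, ascending = df["t"].abs(), False
    elif by == "p":
        col = "p" if "p" in df.columns else "p_value"
        key, ascending = df[col], True
    else:
        raise ValidationError(f"unknown ranking key '{by}'")
    df = df.assign(_key=key).sort_values(
        ["_key", "set_id"], ascending=[ascending, True], kind="mergesort"
    )
    df = df.drop(columns="_key")
    if add_bh_fdr:
        from statsmodels.stats.multitest import multipletests

        pcol = "p" if "p" in df.columns else "p_value"
        df["p_bh"] = multipletests(df[pcol].to_numpy(), method="fdr_bh")[1]
    if top_k is not None:
        df = df.head(top_k)
    return df.reset_index(drop=True)
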