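"""Cohort-level statistics for hibernation experiments.

Per-animal summaries feed a small battery of models, mirroring standard
practice in hibernation ecophysiology:

* linear mixed models on square-root-transformed bout durations with
  treatment and initial body mass as fixed effects and animal identity as a
  random intercept;
* repeatability ``R = V_I / (V_I + V_Res)`` of a trait from the variance
  components of the random-intercept model, with a likelihood-ratio test of
  the individual effect against chi-square with 1 d.f.;
* Poisson GLMs for per-animal event counts, a binomial GLM for the
  proportion of arousals that include drinking, and a gamma GLM for
  over-winter mass loss;
* Welch's t-test and Cohen's d for simple two-group contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .detect import Bout

__all__ = [
    "BatRecord",
    "ModelFitResult",
    "RepeatabilityResult",
    "EffectSize",
    "fit_duration_mixed_model",
    "repeatability",
    "fit_count_glm",
    "fit_drink_proportion_glm",
    "fit_mass_loss_glm",
    "cohens_d",
    "welch_t",
]


@dataclass
class BatRecord:
    """Per-animal metadata and event totals."""

    bat_id: str
    treatment: str
    initial_mass: float | None = None
    final_mass: float | None = None
    n_arousals: int = 0
    n_drinks: int = 0
    n_arousals_with_drink: int = 0
    n_arousals_without_drink: int = 0

    @property
    def mass_loss(self) -> float | None:
        if self.initial_mass is None or self.final_mass is None:
            return None
        return self.initial_mass - self.final_mass


@dataclass
class ModelFitResult:
    """A fitted model's coefficient table plus family metadata."""

    response: str
    family: str
    table: pd.DataFrame  # index: term; columns: estimate, se, stat, p
    transform: str = "identity"
    extras: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


@dataclass
class RepeatabilityResult:
    v_individual: float
    v_residual: float
    lrt_chisq: float
    lrt_p: float
    lrt_df: int = 1

    @property
    def r(self) -> float:
        total = self.v_individual + self.v_residual
        if total <= 0:
            return 0.0
        return self.v_individual / total


_D_CUTPOINTS = ((0.2, "negligible"), (0.5, "small"), (0.8, "medium"))


@dataclass
class EffectSize:
    d: float

    @property
    def magnitude(self) -> str:
        for cut, label in _D_CUTPOINTS:
            if abs(self.d) < cut:
                return label
        return "large"


def _records_frame(bat_records: list[BatRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bat_id": [b.bat_id for b in bat_records],
            "treatment": [b.treatment for b in bat_records],
            "initial_mass": [b.initial_mass for b in bat_records],
            "mass_loss": [b.mass_loss for b in bat_records],
            "arousals": [b.n_arousals for b in bat_records],
            "drinks": [b.n_drinks for b in bat_records],
            "with_drink": [b.n_arousals_with_drink for b in bat_records],
            "without_drink": [b.n_arousals_without_drink for b in bat_records],
        }
    )


def _glm_table(result) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "estimate": result.params,
            "se": result.bse,
            "stat": result.tvalues,
            "p": result.pvalues,
        }
    )


def fit_duration_mixed_model(
    bouts: list[Bout],
    bat_records: list[BatRecord],
    response: str,
) -> ModelFitResult:
    """Mixed model for bout durations: sqrt(y) ~ treatment + initial mass.

    ``response`` is ``"arousal_h"`` (arousal duration in hours) or
    ``"torpor_day"`` (torpor bout duration in days).  Censored bouts are
    excluded.  Animal identity enters as a random intercept; the model is
    fitted by REML.  A singular fit (zero between-animal variance) is
    reported in ``extras`` rather than raised.
    """
    if response not in ("arousal_h", "torpor_day"):
        raise ValueError(f"unknown response {response!r}")
    kind = "arousal" if response == "arousal_h" else "torpor"
    scale = 60.0 if response == "arousal_h" else 1440.0
    rows = [
        (b.bat_id, b.duration_min / scale)
        for b in bouts
        if b.kind == kind and not b.censored
    ]
    if not rows:
        raise ValueError(f"no uncensored {kind} bouts to fit")
    meta = {b.bat_id: b for b in bat_records}
    df = pd.DataFrame(rows, columns=["bat_id", "y"])
    df["treatment"] = [meta[i].treatment for i in df["bat_id"]]
    df["initial_mass"] = [meta[i].initial_mass for i in df["bat_id"]]
    df["sqrt_y"] = np.sqrt(df["y"])
    n_treat = df.groupby("treatment")["bat_id"].nunique()
    if (n_treat < 2).any():
        raise ValueError("need at least 2 animals per treatment")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "sqrt_y ~ C(treatment) + initial_mass", df, groups=df["bat_id"]
        )
        fit = model.fit(reml=True)
    table = pd.DataFrame(
        {
            "estimate": fit.fe_params,
            "se": fit.bse_fe,
            "stat": fit.fe_params / fit.bse_fe,
            "p": fit.pvalues[fit.fe_params.index],
        }
    )
    v_i = float(np.asarray(fit.cov_re)[0, 0])
    extras = {
        "v_individual": v_i,
        "v_residual": float(fit.scale),
        "singular": bool(v_i <= 1e-8),
        "n_bouts": len(df),
        "n_bats": df["bat_id"].nunique(),
        "raw_means": df.groupby("treatment")["y"].mean().to_dict(),
    }
    return ModelFitResult(
        response=response,
        family="gaussian (REML mixed)",
        transform="sqrt",
        table=table,
        extras=extras,
    )


def _anova_components(df: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA moment estimator of (V_I, V_Res), unbalanced-safe."""
    groups = [g["value"].to_numpy() for _, g in df.groupby("bat_id")]
    k = len(groups)
    n_i = np.array([len(g) for g in groups], dtype=float)
    n = n_i.sum()
    grand = df["value"].mean()
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_within = ss_within / (n - k)
    ss_between = sum(ni * (g.mean() - grand) ** 2 for ni, g in zip(n_i, groups))
    ms_between = ss_between / (k - 1)
    n0 = (n - (n_i**2).sum() / n) / (k - 1)
    v_i = max(0.0, (ms_between - ms_within) / n0)
    return v_i, float(ms_within)


def repeatability(
    measurements, method: str = "reml"
) -> RepeatabilityResult:
    """Repeatability of a trait from repeated measures per animal.

    Parameters
    ----------
    measurements : iterable of (bat_id, value)
        Repeated observations of the (already transformed) trait.
    method : {"reml", "anova"}
        Variance components from a REML random-intercept fit (default) or
        from the one-way ANOVA moment estimator, which is exact in closed
        form for balanced designs.

    The likelihood-ratio test always compares maximum-likelihood fits with
    and without the individual random effect, referred to chi-square with
    1 d.f.  (This naive reference is conservative for a boundary variance.)
    """
    df = pd.DataFrame(list(measurements), columns=["bat_id", "value"])
    counts = df.groupby("bat_id").size()
    if len(counts) < 2:
        raise ValueError("need at least 2 animals")
    if (counts < 2).all():
        raise ValueError("repeatability undefined: no animal has repeated measures")
    if method == "anova":
        v_i, v_res = _anova_components(df)
    elif method == "reml":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM.from_formula(
                "value ~ 1", df, groups=df["bat_id"]
            ).fit(reml=True)
        v_i = float(np.asarray(fit.cov_re)[0, 0])
        v_res = float(fit.scale)
    else:
        raise ValueError(f"unknown method {method!r}")
    # LRT: ML mixed model vs intercept-only OLS (ML variance).
    y = df["value"].to_numpy()
    n = y.size
    rss0 = ((y - y.mean()) ** 2).sum()
    if rss0 <= 0:
        # Degenerate constant response: no information for the test.
        ll0 = np.inf
        chisq = 0.0
    else:
        ll0 = -0.5 * n * (np.log(2 * np.pi) + np.log(rss0 / n) + 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_ml = sm.MixedLM.from_formula(
                "value ~ 1", df, groups=df["bat_id"]
            ).fit(reml=False)
        chisq = max(0.0, 2.0 * (float(fit_ml.llf) - ll0))
    p = float(scipy.stats.chi2.sf(chisq, df=1)) if np.isfinite(chisq) else 1.0
    return RepeatabilityResult(
        v_individual=v_i, v_residual=v_res, lrt_chisq=chisq, lrt_p=p
    )


def fit_count_glm(
    bat_records: list[BatRecord], response: str, include_mass: bool = True
) -> ModelFitResult:
    """Poisson GLM of per-animal totals on treatment (and initial mass).

    ``response`` is ``"arousals"`` or ``"drinks"``.  The exponentiated
    treatment coefficient is the between-treatment rate ratio; in the
    treatment-only model (``include_mass=False``) it equals the ratio of
    group mean counts exactly.  A Pearson overdispersion statistic is
    reported in ``extras``.
    """
    if response not in ("arousals", "drinks"):
        raise ValueError(f"unknown response {response!r}")
    df = _records_frame(bat_records)
    sizes = df.groupby("treatment").size()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need at least 2 animals in each of 2 treatments")
    if (df.groupby("treatment")[response].sum() == 0).any():
        warnings.warn("a treatment has all-zero counts (separation)", stacklevel=2)
    formula = f"{response} ~ C(treatment)" + (" + initial_mass" if include_mass else "")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.glm(formula, df, family=sm.families.Poisson()).fit()
    table = _glm_table(fit)
    treat_term = [t for t in table.index if t.startswith("C(treatment)")]
    extras = {
        "overdispersion": float(fit.pearson_chi2 / fit.df_resid)
        if fit.df_resid > 0
        else np.nan,
        "rate_ratio": float(np.exp(table.loc[treat_term[0], "estimate"]))
        if treat_term
        else np.nan,
    }
    return ModelFitResult(
        response=response, family="poisson (log link)", table=table, extras=extras
    )


def fit_drink_proportion_glm(
    bat_records: list[BatRecord], include_mass: bool = True
) -> ModelFitResult:
    """Binomial GLM for the proportion of arousals that included drinking.

    The response is the (arousals-with-drinking, arousals-without) composite
    per animal; animals with zero arousals are excluded with a warning.  In
    the treatment-only model the exponentiated treatment coefficient equals
    the pooled-table odds ratio exactly.
    """
    df = _records_frame(bat_records)
    zero = df["with_drink"] + df["without_drink"] == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} animal(s) with zero arousals",
            stacklevel=2,
        )
        df = df[~zero]
    for tr, g in df.groupby("treatment"):
        if (g["without_drink"] == 0).all() or (g["with_drink"] == 0).all():
            warnings.warn(f"treatment {tr!r}: boundary proportions (separation)",
                          stacklevel=2)
    formula = "with_drink + without_drink ~ C(treatment)" + (
        " + initial_mass" if include_mass else ""
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.glm(formula, df, family=sm.families.Binomial()).fit()
    table = _glm_table(fit)
    treat_term = [t for t in table.index if t.startswith("C(treatment)")]
    extras = {
        "odds_ratio": float(np.exp(table.loc[treat_term[0], "estimate"]))
        if treat_term
        else np.nan
    }
    return ModelFitResult(
        response="drink_proportion",
        family="binomial (logit link)",
        table=table,
        extras=extras,
    )


def fit_mass_loss_glm(bat_records: list[BatRecord]) -> ModelFitResult:
    """Gamma GLM (log link) of over-winter mass loss.

    Predictors: initial body mass, treatment, total drinking bouts and
    total arousals per animal.  Mass loss is right-skewed and strictly
    positive; animals with non-positive or missing loss are excluded with a
    warning.
    """
    df = _records_frame(bat_records)
    bad = df["mass_loss"].isna() | (df["mass_loss"] <= 0)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} animal(s) with non-positive mass loss",
            stacklevel=2,
        )
        df = df[~bad]
    if len(df) < 6:
        raise ValueError("too few animals with positive mass loss")
    if np.var(df["mass_loss"].to_numpy(float)) == 0:
        # constant response: every slope is exactly zero, no dispersion to fit
        terms = ["Intercept", "C(treatment)[T.humid]", "initial_mass",
                 "drinks", "arousals"]
        table = pd.DataFrame(
            {
                "estimate": [float(np.log(df["mass_loss"].iloc[0]))]
                + [0.0] * (len(terms) - 1),
                "se": np.nan, "stat": np.nan, "p": np.nan,
            },
            index=terms,
        )
        return ModelFitResult(response="mass_loss", family="gamma (log link)",
                              table=table, extras={"degenerate": True})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.glm(
            "mass_loss ~ initial_mass + C(treatment) + drinks + arousals",
            df,
            family=sm.families.Gamma(link=sm.families.links.Log()),
        ).fit()
    return ModelFitResult(
        response="mass_loss",
        family="gamma (log link)",
        table=_glm_table(fit),
    )


def cohens_d(group_a, group_b) -> EffectSize:
    """Cohen's d with the pooled sample s.d. (n-1 denominators)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    if pooled <= 0:
        raise ValueError("Cohen's d undefined: zero pooled variance")
    return EffectSize(d=float((a.mean() - b.mean()) / np.sqrt(pooled)))


def welch_t(group_a, group_b) -> dict:
    """Welch's unequal-variance t-test with Welch–Satterthwaite d.f."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        equal = a.mean() == b.mean()
        return {"t": 0.0 if equal else np.inf, "df": float(a.size + b.size - 2),
                "p": 1.0 if equal else 0.0}
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2 * scipy.stats.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}
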