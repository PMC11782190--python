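"""Frailty indicator dichotomization and cluster-vs-reference association tests.

The Fried phenotype is operationalized as the count of five indicators —
unintentional weight loss (>=4.5 kg/year), low physical activity (lowest
sex-stratified MET quintile or highest sitting quintile), slowness (timed
up-and-go > 13.5 s), weakness (lowest sex-stratified grip-strength quintile)
and exhaustion — with >=2 indicators marking the pre-frail/frail phenotype.
Supplementary indicators: compromised independence (Katz ADL <= 5), impaired
cognition (MoCA < 26), slow gait (<= 0.6 m/s), impaired balance (functional
reach < 15 cm) and a self-reported fall in the previous year.

Associations of each indicator with cluster membership versus the normal-
orthostatic-response reference group are estimated as odds ratios with Wald
95% confidence intervals, either from the closed-form 2x2 table or from
logistic models (unadjusted / age-sex adjusted / fully adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnalysisConfig",
    "AssociationResult",
    "met_expenditure",
    "sex_stratified_quantile_cut",
    "dichotomize",
    "dichotomize_cohort",
    "odds_ratio_2x2",
    "fit_logistic",
    "association_table",
    "compare_groups",
    "INDICATOR_COLUMNS",
]

Z_CRIT = 1.959964  # two-sided 95% Wald critical value

INDICATOR_COLUMNS = [
    "weight_loss", "low_activity", "sedentary", "slow_tug", "weak_grip",
    "exhaustion", "fried_count", "fried_positive", "adl_compromised",
    "cognition_impaired", "slow_gait", "balance_impaired", "recent_fall",
]


@dataclass
class AnalysisConfig:
    """Dichotomization thresholds and test settings.

    Quantile-based cuts (grip strength, MET, sitting time) use the lowest or
    highest sex-stratified fifth, the Fried convention.
    """

    tug_slow_s: float = 13.5          # slow if strictly greater
    moca_impaired: float = 26.0       # impaired if strictly less
    gait_slow_ms: float = 0.6         # slow if <=
    fr_impaired_cm: float = 15.0      # impaired if strictly less
    adl_compromised: float = 5.0      # compromised if <=
    weight_loss_kg: float = 4.5
    crp_high_mgl: float = 3.0
    supine_htn_mmhg: float = 140.0
    polypharmacy_n: int = 5
    quantile_fraction: float = 0.2
    bonferroni_alpha: float = 0.017
    met_coefficients: tuple[float, float, float] = (3.3, 4.0, 8.0)


@dataclass
class AssociationResult:
    indicator: str | None
    cluster: str | None
    model: str            # unadjusted | age_sex | full
    or_hat: float
    ci_low: float
    ci_high: float
    wald_p: float
    n: int | None = None


def met_expenditure(walk_min: float, walk_days: float,
                    mod_min: float, mod_days: float,
                    vig_min: float, vig_days: float,
                    coefficients: tuple[float, float, float] = (3.3, 4.0, 8.0)) -> float:
    """Weekly MET expenditure: 3.3·walk + 4.0·moderate + 8.0·vigorous
    (each as min/day x days/week)."""
    args = (walk_min, walk_days, mod_min, mod_days, vig_min, vig_days)
    if any(a < 0 for a in args):
        raise ValueError("activity inputs must be non-negative")
    if walk_days > 7 or mod_days > 7 or vig_days > 7:
        raise ValueError("days per week cannot exceed 7")
    cw, cm, cv = coefficients
    return cw * walk_min * walk_days + cm * mod_min * mod_days + cv * vig_min * vig_days


def sex_stratified_quantile_cut(values, sexes, side: str,
                                fraction: float = 0.2,
                                ) -> tuple[dict, np.ndarray]:
    """Per-sex empirical quantile cutoffs and the membership flags.

    ``side='lowest'`` flags values <= the per-sex ``fraction`` quantile;
    ``side='highest'`` flags values >= the (1 − fraction) quantile. With all
    values equal within a stratum everyone is flagged (degenerate case).
    Missing values yield missing flags.
    """
    if side not in ("lowest", "highest"):
        raise ValueError("side must be 'lowest' or 'highest'")
    values = pd.Series(np.asarray(values, dtype=float))
    sexes = pd.Series(np.asarray(sexes, dtype=object))
    cutoffs: dict = {}
    flags = np.full(len(values), np.nan, dtype=object)
    for sex in sexes.unique():
        in_stratum = (sexes == sex).to_numpy()
        vals = values[in_stratum].dropna()
        if len(vals) < 5:
            raise ValueError(f"stratum {sex!r} too small for a quantile cut")
        q = fraction if side == "lowest" else 1.0 - fraction
        cut = float(np.quantile(vals, q))
        cutoffs[sex] = cut
        for i in np.nonzero(in_stratum)[0]:
            v = values.iloc[i]
            if np.isnan(v):
                continue
            flags[i] = bool(v <= cut) if side == "lowest" else bool(v >= cut)
    return cutoffs, flags


def dichotomize_cohort(df: pd.DataFrame, cfg: AnalysisConfig | None = None,
                       ) -> pd.DataFrame:
    """Dichotomize raw assessment values for a whole cohort.

    Expected columns: sex, weight_loss (bool), walk_min, walk_days, mod_min,
    mod_days, vig_min, vig_days, sit_hours, tug_s, hgs_kg, exhaustion (bool),
    adl, moca, gait_speed, fr_cm, fall (bool). Missing raw values propagate to
    missing indicators (complete-case per indicator downstream).
    """
    cfg = cfg or AnalysisConfig()
    out = pd.DataFrame(index=df.index)

    met = df.apply(
        lambda r: met_expenditure(r["walk_min"], r["walk_days"], r["mod_min"],
                                  r["mod_days"], r["vig_min"], r["vig_days"],
                                  cfg.met_coefficients)
        if not r[["walk_min", "walk_days", "mod_min",
                  "mod_days", "vig_min", "vig_days"]].isna().any() else np.nan,
        axis=1,
    )
    _, low_act = sex_stratified_quantile_cut(met, df["sex"], "lowest",
                                             cfg.quantile_fraction)
    _, sedentary = sex_stratified_quantile_cut(df["sit_hours"], df["sex"], "highest",
                                               cfg.quantile_fraction)
    _, weak_grip = sex_stratified_quantile_cut(df["hgs_kg"], df["sex"], "lowest",
                                               cfg.quantile_fraction)

    out["weight_loss"] = df["weight_loss"].astype("boolean")
    out["low_activity"] = pd.array(low_act, dtype="boolean")
    out["sedentary"] = pd.array(sedentary, dtype="boolean")
    out["slow_tug"] = (df["tug_s"] > cfg.tug_slow_s).astype("boolean").mask(df["tug_s"].isna())
    out["weak_grip"] = pd.array(weak_grip, dtype="boolean")
    out["exhaustion"] = df["exhaustion"].astype("boolean")
    out["adl_compromised"] = (df["adl"] <= cfg.adl_compromised).astype("boolean").mask(df["adl"].isna())
    out["cognition_impaired"] = (df["moca"] < cfg.moca_impaired).astype("boolean").mask(df["moca"].isna())
    out["slow_gait"] = (df["gait_speed"] <= cfg.gait_slow_ms).astype("boolean").mask(df["gait_speed"].isna())
    out["balance_impaired"] = (df["fr_cm"] < cfg.fr_impaired_cm).astype("boolean").mask(df["fr_cm"].isna())
    out["recent_fall"] = df["fall"].astype("boolean")

    activity = out["low_activity"] | out["sedentary"]  # Kleene or: True|NA = True
    fried = (
        out["weight_loss"].astype("Int64") + activity.astype("Int64")
        + out["slow_tug"].astype("Int64") + out["weak_grip"].astype("Int64")
        + out["exhaustion"].astype("Int64")
    )
    out["fried_count"] = fried
    out["fried_positive"] = (fried >= 2).astype("boolean").mask(fried.isna())
    return out[INDICATOR_COLUMNS]


def dichotomize(participant: pd.Series, cfg: AnalysisConfig,
                cohort: pd.DataFrame) -> pd.Series:
    """Indicators for one participant, with quantile cuts taken from ``cohort``."""
    frame = pd.concat([cohort, participant.to_frame().T], ignore_index=True)
    return dichotomize_cohort(frame, cfg).iloc[-1]


def odds_ratio_2x2(exposed_cases: int, n_exposed: int,
                   ref_cases: int, n_ref: int,
                   continuity: bool = False,
                   indicator: str | None = None,
                   cluster: str | None = None) -> AssociationResult:
    """Closed-form odds ratio with Wald 95% CI and p-value from a 2x2 table.

    Cells: (cases, non-cases) in the exposed (cluster) and reference (NOR)
    groups. A zero cell is an error unless the Haldane 0.5 continuity
    correction is requested.
    """
    a = float(exposed_cases)
    b = float(n_exposed - exposed_cases)
    c = float(ref_cases)
    d = float(n_ref - ref_cases)
    if min(a, b, c, d) < 0:
        raise ValueError("cases cannot exceed group size")
    if min(a, b, c, d) == 0:
        if not continuity:
            raise ValueError("zero cell in 2x2 table; use continuity=True")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_hat = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_hat)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return AssociationResult(
        indicator=indicator, cluster=cluster, model="unadjusted",
        or_hat=float(or_hat),
        ci_low=float(np.exp(log_or - Z_CRIT * se)),
        ci_high=float(np.exp(log_or + Z_CRIT * se)),
        wald_p=float(p),
        n=int(n_exposed + n_ref),
    )


def fit_logistic(outcome, design: pd.DataFrame, term: str,
                 model_name: str = "unadjusted",
                 indicator: str | None = None,
                 cluster: str | None = None) -> AssociationResult:
    """Maximum-likelihood logistic fit; Wald OR/CI/p for one design column.

    The design matrix should contain the cluster indicator named ``term`` plus
    any adjustment covariates; an intercept is added here. Separation or
    non-convergence raises with the offending term named.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(design.astype(float), has_constant="add")
    if term not in design.columns:
        raise ValueError(f"term {term!r} not in design matrix")
    import warnings

    try:
        # convergence/separation are detected and raised explicitly below
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise RuntimeError(f"logistic fit failed for term {term!r}: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(f"logistic fit did not converge for term {term!r}")
    beta = float(fit.params[term])
    se = float(fit.bse[term])
    if not np.isfinite(se) or se > 1e3:
        raise RuntimeError(f"quasi-separation on term {term!r} (unbounded SE)")
    z = beta / se
    return AssociationResult(
        indicator=indicator, cluster=cluster, model=model_name,
        or_hat=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_CRIT * se)),
        ci_high=float(np.exp(beta + Z_CRIT * se)),
        wald_p=float(2.0 * stats.norm.sf(abs(z))),
        n=int(len(y)),
    )


FULL_COVARIATES = ["age", "female", "bmi", "resting_sbp", "cvd", "diabetes",
                   "antihypertensives", "polypharmacy", "crp_high"]


def association_table(groups: pd.Series, indicators: pd.DataFrame,
                      covariates: pd.DataFrame | None = None,
                      models: tuple[str, ...] = ("unadjusted",),
                      reference: str = "NOR",
                      indicator_cols: list[str] | None = None,
                      on_error: str = "raise",
                      ) -> pd.DataFrame:
    """Cluster-vs-reference associations for every binary indicator.

    For each indicator and each non-reference group, fits the requested
    models on the complete cases of that indicator: ``unadjusted`` (group
    indicator only, equivalent to the 2x2 odds ratio), ``age_sex`` and
    ``full`` (age, sex, BMI, resting SBP, cardiovascular disease, diabetes,
    antihypertensive use, polypharmacy, elevated hsCRP).

    With ``on_error='skip'`` cells whose fit fails (separation at small
    counts) are omitted from the table instead of raising.
    """
    indicator_cols = indicator_cols or [
        c for c in indicators.columns if c != "fried_count"
    ]
    adjust = {"unadjusted": [], "age_sex": ["age", "female"], "full": FULL_COVARIATES}
    rows = []
    clusters = [g for g in pd.unique(groups) if g != reference]
    for ind in indicator_cols:
        y_all = indicators[ind]
        for cl in clusters:
            in_pair = groups.isin([cl, reference])
            for model_name in models:
                cols = adjust[model_name]
                mask = in_pair & y_all.notna()
                if cols:
                    mask &= covariates[cols].notna().all(axis=1)
                y = y_all[mask].astype(float)
                design = pd.DataFrame(
                    {"cluster": (groups[mask] == cl).astype(float)}, index=y.index
                )
                for c in cols:
                    design[c] = covariates.loc[mask, c].astype(float)
                try:
                    res = fit_logistic(y, design, "cluster", model_name=model_name,
                                       indicator=ind, cluster=cl)
                except RuntimeError:
                    if on_error == "skip":
                        continue
                    raise
                rows.append(vars(res))
    return pd.DataFrame(rows)


def compare_groups(df: pd.DataFrame, group_col: str,
                   categorical: list[str] = (), continuous: list[str] = (),
                   normal: list[str] = (),
                   alpha: float = 0.017) -> pd.DataFrame:
    """Overall and pairwise group comparisons per variable.

    Categorical variables: chi-squared overall and pairwise (proportion
    differences); continuous: Kruskal-Wallis overall (ANOVA for variables
    listed in ``normal``) with pairwise Student t-tests (mean differences).
    Pairwise significance is flagged at the Bonferroni threshold ``alpha``.
    """
    groups = [g for g in pd.unique(df[group_col]) if pd.notna(g)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    rows = []
    for var in list(categorical) + list(continuous):
        sub = df[[group_col, var]].dropna()
        per_group = [sub.loc[sub[group_col] == g, var] for g in groups]
        if any(len(v) == 0 for v in per_group):
            raise ValueError(f"empty group for variable {var!r}")
        is_cat = var in categorical
        if is_cat:
            counts = np.array([[v.sum(), len(v) - v.sum()] for v in per_group],
                              dtype=float)
            stat, p, _, _ = stats.chi2_contingency(counts)
            test = "chi2"
        elif var in normal:
            stat, p = stats.f_oneway(*[v.astype(float) for v in per_group])
            test = "anova"
        else:
            stat, p = stats.kruskal(*[v.astype(float) for v in per_group])
            test = "kruskal"
        pairwise = []
        for a, b in pairs:
            va = sub.loc[sub[group_col] == a, var].astype(float)
            vb = sub.loc[sub[group_col] == b, var].astype(float)
            if is_cat:
                tab = np.array([[va.sum(), len(va) - va.sum()],
                                [vb.sum(), len(vb) - vb.sum()]], dtype=float)
                _, pp, _, _ = stats.chi2_contingency(tab)
                diff = float(va.mean() - vb.mean())
            else:
                _, pp = stats.ttest_ind(va, vb)
                diff = float(va.mean() - vb.mean())
            pairwise.append(
                {"pair": (a, b), "difference": diff, "p": float(pp),
                 "significant": bool(pp < alpha)}
            )
        rows.append({"variable": var, "test": test, "statistic": float(stat),
                     "p": float(p), "pairwise": pairwise})
    return pd.DataFrame(rows)
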