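"""Group and correlation statistics for microstate studies.

Implements the statistical surface of a two-arm (patient vs control)
resting-state study: demographics tests from raw data or printed summary
moments (pooled-variance t with Cohen's d, Yates-corrected chi-square),
ANCOVA per microstate parameter with an education covariate and partial
eta squared, Benjamini-Hochberg FDR within parameter families, HAMD-24
factor scoring, and Pearson correlations with Fisher-z confidence
intervals computed within the patient arm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FactorMap",
    "DEFAULT_HAMD24_FACTORS",
    "TTestResult",
    "Chi2Result",
    "AncovaResult",
    "CorrelationResult",
    "hamd24_factor_scores",
    "summary_ttest",
    "ttest_from_data",
    "chi2_2x2",
    "ancova_group",
    "bh_fdr",
    "pearson_ci",
    "pearson_ci_from_summary",
    "run_group_analysis",
]

HAMD_ITEM_COLUMNS = tuple(f"hamd{i:02d}" for i in range(1, 25))

#: Conventional seven-factor structure of the 24-item Hamilton depression
#: scale (1-based item indices).  Anxiety/somatization pools psychic
#: anxiety, somatic anxiety, gastrointestinal, general somatic symptoms,
#: hypochondriasis and insight.  Override via the ``factor_map`` argument
#: of the scoring functions when a study uses a different composition.
DEFAULT_HAMD24_FACTORS: dict[str, tuple[int, ...]] = {
    "anxiety_somatization": (10, 11, 12, 13, 15, 17),
    "weight": (16,),
    "cognitive_impairment": (2, 3, 9, 19, 20, 21),
    "diurnal_variation": (18,),
    "retardation": (1, 7, 8, 14),
    "sleep_disorder": (4, 5, 6),
    "sense_of_despair": (22, 23, 24),
}


@dataclass(frozen=True)
class FactorMap:
    """Named groups of HAMD-24 items (1-based indices, no overlap)."""

    factors: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, items in self.factors.items():
            for i in items:
                if not 1 <= i <= 24:
                    raise ValueError(f"factor {name!r}: item {i} outside 1..24")
                if i in seen:
                    raise ValueError(f"item {i} assigned to two factors")
                seen.add(i)

    @classmethod
    def default(cls) -> "FactorMap":
        return cls(dict(DEFAULT_HAMD24_FACTORS))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    cohen_d: float


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class AncovaResult:
    f: float
    df_num: int
    df_denom: int
    p: float
    partial_eta_sq: float
    adjusted_means: dict[str, float]
    p_fdr: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float


def hamd24_factor_scores(items: np.ndarray | pd.DataFrame, factor_map: FactorMap | None = None) -> pd.DataFrame:
    """Sum HAMD-24 items into the seven factor scores.

    ``items`` is an ``(n_subjects, 24)`` array or a DataFrame carrying the
    ``hamd01``..``hamd24`` columns.  A factor containing any missing item
    is scored as missing for that subject.
    """
    fm = factor_map or FactorMap.default()
    if isinstance(items, pd.DataFrame):
        mat = items.loc[:, list(HAMD_ITEM_COLUMNS)].to_numpy(dtype=float)
        index = items.index
    else:
        mat = np.asarray(items, dtype=float)
        index = pd.RangeIndex(mat.shape[0])
    if mat.ndim != 2 or mat.shape[1] != 24:
        raise ValueError("expected 24 HAMD items per subject")
    out = {}
    for name, idx in fm.factors.items():
        cols = mat[:, [i - 1 for i in idx]]
        s = cols.sum(axis=1)
        s[np.isnan(cols).any(axis=1)] = np.nan
        out[name] = s
    out["hamd_total"] = np.where(np.isnan(mat).any(axis=1), np.nan, mat.sum(axis=1))
    return pd.DataFrame(out, index=index)


def summary_ttest(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int) -> TTestResult:
    """Student's pooled-variance two-sample t from summary moments.

    Also returns Cohen's d with the pooled SD as the standardizer.  Two
    groups with zero variance and equal means yield t = 0 by convention.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = m1 - m2
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0, 0.0)
        raise ValueError("zero pooled variance with unequal means")
    sp = math.sqrt(sp2)
    t = diff / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return TTestResult(t, df, p, diff / sp)


def ttest_from_data(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Pooled t-test on raw samples (consistent with :func:`summary_ttest`)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return summary_ttest(x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size)


def chi2_2x2(table: np.ndarray, yates: bool = True) -> Chi2Result:
    """Chi-square test of independence on a 2x2 count table.

    With ``yates`` the continuity correction |O-E| - 0.5 is applied,
    clipped at zero.  A zero row or column marginal leaves the statistic
    undefined and raises.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("expected a 2x2 table of non-negative counts")
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("chi-square undefined with a zero marginal")
    expected = rows @ cols / n
    dev = np.abs(obs - expected)
    if yates:
        dev = np.clip(dev - 0.5, 0.0, None)
    chi2 = float(np.sum(dev**2 / expected))
    return Chi2Result(chi2, 1, float(scipy.stats.chi2.sf(chi2, 1)))


def ancova_group(
    y: np.ndarray,
    arm: np.ndarray,
    covariate: np.ndarray,
) -> AncovaResult:
    """One-way ANCOVA: y ~ arm + covariate, F test for the arm effect.

    Fits the linear model by ordinary least squares and compares the full
    model with the covariate-only reduced model, so the arm sum of squares
    is adjusted for the covariate.  Partial eta squared is
    SS_arm / (SS_arm + SS_residual).  A constant covariate degenerates to
    a one-way ANOVA (with a warning).
    """
    y = np.asarray(y, float)
    arm = np.asarray(arm)
    cov = np.asarray(covariate, float)
    if y.shape != arm.shape or y.shape != cov.shape:
        raise ValueError("y, arm and covariate must have equal length")
    levels = np.unique(arm)
    if levels.size != 2:
        raise ValueError("exactly two arms required")
    for lev in levels:
        if np.sum(arm == lev) < 3:
            raise ValueError("each arm needs at least 3 subjects")
    g = (arm == levels[1]).astype(float)

    use_cov = np.ptp(cov) > 0
    if not use_cov:
        warnings.warn("constant covariate; reducing to one-way ANOVA")
    x_red = np.column_stack([np.ones_like(y)] + ([cov] if use_cov else []))
    x_full = np.column_stack([x_red, g])
    fit_full = sm.OLS(y, x_full).fit()
    fit_red = sm.OLS(y, x_red).fit()
    ss_arm = fit_red.ssr - fit_full.ssr
    ss_res = fit_full.ssr
    df_denom = int(fit_full.df_resid)
    f = (ss_arm / 1.0) / (ss_res / df_denom)
    p = float(scipy.stats.f.sf(f, 1, df_denom))
    eta = ss_arm / (ss_arm + ss_res) if (ss_arm + ss_res) > 0 else 0.0
    cbar = cov.mean() if use_cov else None
    adj = {}
    for lev in levels:
        xi = [1.0] + ([cbar] if use_cov else []) + [float(lev == levels[1])]
        adj[str(lev)] = float(fit_full.predict(np.array(xi))[0])
    return AncovaResult(float(f), 1, df_denom, p, float(eta), adj)


def bh_fdr(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_ci_from_summary(r: float, n: int, conf: float = 0.95) -> CorrelationResult:
    """Fisher-z confidence interval and t-based p from a sample r and n."""
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zc = scipy.stats.norm.ppf(0.5 + conf / 2.0)
    lo, hi = math.tanh(z - zc * se), math.tanh(z + zc * se)
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r**2)
    p = 2.0 * scipy.stats.t.sf(abs(t), n - 2)
    return CorrelationResult(r, n, lo, hi, p)


def pearson_ci(x: np.ndarray, y: np.ndarray, conf: float = 0.95) -> CorrelationResult:
    """Pearson correlation of two samples with Fisher-z CI.

    Perfectly collinear data (|r| = 1) gets a degenerate CI at r with
    p = 0; zero-variance input raises.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need two equal-length samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        r = math.copysign(1.0, r)
        return CorrelationResult(r, x.size, r, r, 0.0)
    return pearson_ci_from_summary(r, x.size, conf)


# ---------------------------------------------------------------------------
# full group analysis

PARAM_FAMILIES = ("duration_ms", "occurrence_hz", "coverage_pct")
DEFAULT_SYMPTOM_SCORES = ("anxiety_somatization", "hamd_total", "hama", "madrs")


def run_group_analysis(
    params: pd.DataFrame,
    transitions: pd.DataFrame,
    clinical: pd.DataFrame,
    factor_map: FactorMap | None = None,
    alpha: float = 0.05,
    symptom_scores: tuple[str, ...] = DEFAULT_SYMPTOM_SCORES,
    correlate_all: bool = False,
) -> dict[str, pd.DataFrame]:
    """Run the full between-group and correlation analysis.

    Parameters
    ----------
    params
        Long table (subject, class, duration_ms, occurrence_hz,
        coverage_pct), one row per subject and microstate class.
    transitions
        Long table (subject, from, to, probability).
    clinical
        One row per subject: arm ("patient"/"control"), age, sex,
        education_years, hamd01..hamd24, hama, madrs.
    factor_map
        HAMD-24 factor composition; defaults to the conventional seven.
    alpha
        Two-tailed significance threshold.
    symptom_scores
        Clinical scores correlated with microstate parameters in the
        patient arm.
    correlate_all
        Correlate every parameter instead of only FDR-surviving ones.

    Returns
    -------
    dict with ``demographics``, ``ancova`` (12 parameter tests + 12
    transition tests, raw and FDR-adjusted p per family, partial eta
    squared, adjusted means) and ``correlations`` DataFrames.  Subjects
    missing from any table are dropped with a warning.
    """
    clinical = clinical.set_index("subject") if "subject" in clinical.columns else clinical
    subj_params = set(params["subject"])
    subj_trans = set(transitions["subject"])
    subj_clin = set(clinical.index)
    common = subj_params & subj_trans & subj_clin
    dropped = (subj_params | subj_trans | subj_clin) - common
    if dropped:
        warnings.warn(f"dropping {len(dropped)} subjects missing from some table: {sorted(dropped)}")
    params = params[params["subject"].isin(common)]
    transitions = transitions[transitions["subject"].isin(common)]
    clinical = clinical.loc[sorted(common)]

    arm = clinical["arm"]
    edu = clinical["education_years"]
    is_pat = arm == "patient"

    # --- demographics -----------------------------------------------------
    demo_rows = []
    for var in ("age", "education_years"):
        res = ttest_from_data(clinical.loc[is_pat, var], clinical.loc[~is_pat, var])
        demo_rows.append(
            {"variable": var, "test": "t", "statistic": res.t, "df": res.df, "p": res.p, "effect_size": res.cohen_d}
        )
    if "sex" in clinical.columns:
        tab = np.array(
            [
                [(clinical.loc[m, "sex"] == "male").sum(), (clinical.loc[m, "sex"] == "female").sum()]
                for m in (is_pat, ~is_pat)
            ]
        )
        try:
            res2 = chi2_2x2(tab, yates=True)
            demo_rows.append(
                {"variable": "sex", "test": "chi2", "statistic": res2.chi2, "df": res2.df, "p": res2.p, "effect_size": np.nan}
            )
        except ValueError:
            pass
    demographics = pd.DataFrame(demo_rows)

    # --- ANCOVA per parameter, FDR within families ------------------------
    anc_rows = []
    wide = params.pivot(index="subject", columns="class")
    classes = sorted(params["class"].unique())
    for family in PARAM_FAMILIES:
        for cls in classes:
            y = wide[(family, cls)].reindex(clinical.index)
            ok = y.notna()
            res = ancova_group(y[ok].to_numpy(), arm[ok].to_numpy(), edu[ok].to_numpy())
            anc_rows.append(
                {
                    "family": family,
                    "parameter": f"{family}:{cls}",
                    "F": res.f,
                    "df_num": res.df_num,
                    "df_denom": res.df_denom,
                    "p": res.p,
                    "partial_eta_sq": res.partial_eta_sq,
                    "mean_patient_adj": res.adjusted_means.get("patient", np.nan),
                    "mean_control_adj": res.adjusted_means.get("control", np.nan),
                }
            )
    twide = transitions.pivot_table(index="subject", columns=["from", "to"], values="probability")
    for frm, to in twide.columns:
        y = twide[(frm, to)].reindex(clinical.index)
        ok = y.notna()
        res = ancova_group(y[ok].to_numpy(), arm[ok].to_numpy(), edu[ok].to_numpy())
        anc_rows.append(
            {
                "family": "transition",
                "parameter": f"transition:{frm}->{to}",
                "F": res.f,
                "df_num": res.df_num,
                "df_denom": res.df_denom,
                "p": res.p,
                "partial_eta_sq": res.partial_eta_sq,
                "mean_patient_adj": res.adjusted_means.get("patient", np.nan),
                "mean_control_adj": res.adjusted_means.get("control", np.nan),
            }
        )
    ancova = pd.DataFrame(anc_rows)
    ancova["p_fdr"] = np.nan
    for family, idx in ancova.groupby("family").groups.items():
        ancova.loc[idx, "p_fdr"] = bh_fdr(ancova.loc[idx, "p"].to_numpy())

    # --- correlations in the patient arm ----------------------------------
    pat = clinical[is_pat]
    scores = hamd24_factor_scores(pat, factor_map)
    for extra in ("hama", "madrs"):
        if extra in pat.columns:
            scores[extra] = pat[extra]
    selected = ancova if correlate_all else ancova[ancova["p_fdr"] < alpha]
    corr_rows = []
    for _, prow in selected.iterrows():
        kind, name = prow["parameter"].split(":", 1)
        if kind == "transition":
            frm, to = name.split("->")
            y = twide[(frm, to)].reindex(pat.index)
        else:
            y = wide[(kind, name)].reindex(pat.index)
        for score in symptom_scores:
            if score not in scores.columns:
                continue
            s = scores[score]
            ok = y.notna() & s.notna()
            if ok.sum() < 4 or np.std(y[ok]) == 0 or np.std(s[ok]) == 0:
                continue
            res = pearson_ci(y[ok].to_numpy(), s[ok].to_numpy())
            corr_rows.append(
                {
                    "parameter": prow["parameter"],
                    "score": score,
                    "r": res.r,
                    "n": res.n,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                }
            )
    correlations = pd.DataFrame(corr_rows)
    return {"demographics": demographics, "ancova": ancova, "correlations": correlations}
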