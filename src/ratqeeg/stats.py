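"""Mixed repeated-measures statistics for the qEEG pipeline.

Implements, from first principles: the Box-Cox ratio normalisation
(lambda = 0 -> log ratio to the subject's own baseline), the mixed
(between treatment x within time) repeated-measures ANOVA with the
Greenhouse-Geisser sphericity correction, Bonferroni-corrected post-hoc
contrasts gated on the interaction, and the decision rule used to read a
global connectivity effect off the ANOVA table.

Model
-----
For subject i in treatment group g with response ``Y_ij`` at time j::

    Y_ij = mu + alpha_g + pi_{i(g)} + beta_j + (alpha beta)_{gj} + e_ij

Sums of squares partition the total variation into between-subject parts
(treatment, subjects-within-groups) and within-subject parts (time,
treatment x time, subject x time error).  Within-subject F tests are
corrected by multiplying both degrees of freedom with the
Greenhouse-Geisser epsilon estimated from the pooled within-group
covariance of the repeated measures.

The heavy lifting is vectorised over arbitrary leading axes so that the
same code tests one response or every pixel of a topographic map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "boxcox_ratio",
    "normality_check",
    "NormalityResult",
    "gg_epsilon",
    "rm_anova",
    "mixed_anova_arrays",
    "EffectResult",
    "AnovaResult",
    "bonferroni_posthoc",
    "gfc_inference",
    "GFCInference",
]


# ---------------------------------------------------------------------------
# transforms


def boxcox_ratio(value, baseline_value, lam: float = 0.0):
    """Box-Cox transform of the ratio ``value / baseline_value``.

    ``lam = 0`` gives ``log(value / baseline)``; otherwise
    ``((value/baseline)**lam - 1) / lam``.  Non-positive inputs are an
    error — masking belongs upstream, where a floor is meaningful.
    """
    value = np.asarray(value, dtype=float)
    baseline_value = np.asarray(baseline_value, dtype=float)
    if np.any(value <= 0) or np.any(baseline_value <= 0):
        raise ValueError("Box-Cox ratio requires strictly positive inputs")
    r = value / baseline_value
    if lam == 0.0:
        return np.log(r)
    return (r**lam - 1.0) / lam


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p: float
    degenerate: bool = False


def normality_check(sample) -> NormalityResult:
    """Shapiro-Wilk test; reported, not used to gate the parametric tests."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above n = 5000")
    if np.ptp(x) == 0.0:
        return NormalityResult(np.nan, np.nan, degenerate=True)
    stat, p = sstats.shapiro(x)
    return NormalityResult(float(stat), float(p))


# ---------------------------------------------------------------------------
# Greenhouse-Geisser


def gg_epsilon(within_covariance: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon-hat from a t x t within-subject covariance.

    The covariance is double-centered (``P S P`` with ``P = I - J/t``) and
    epsilon is ``(sum lambda)^2 / ((t-1) * sum lambda^2)`` over its
    eigenvalues, clamped to [1/(t-1), 1].  Under compound symmetry the
    centered matrix is spherical and epsilon = 1.
    """
    S = np.asarray(within_covariance, dtype=float)
    t = S.shape[-1]
    if S.shape[-2:] != (t, t) or t < 2:
        raise ValueError("covariance must be square with t >= 2")
    eps = _gg_epsilon_core(S[np.newaxis, ...] if S.ndim == 2 else S)
    return float(eps[0]) if S.ndim == 2 else eps


def _gg_epsilon_core(S: np.ndarray) -> np.ndarray:
    """Vectorised epsilon-hat for stacked covariance matrices (..., t, t)."""
    t = S.shape[-1]
    P = np.eye(t) - np.full((t, t), 1.0 / t)
    C = P @ S @ P
    tr = np.trace(C, axis1=-2, axis2=-1)
    tr2 = np.einsum("...ij,...ji->...", C, C)
    with np.errstate(invalid="ignore", divide="ignore"):
        eps = np.where(tr2 > 0, tr**2 / ((t - 1) * np.where(tr2 > 0, tr2, 1.0)), np.nan)
    return np.clip(eps, 1.0 / (t - 1), 1.0)


# ---------------------------------------------------------------------------
# mixed ANOVA core


def mixed_anova_arrays(Y: np.ndarray, group_codes: np.ndarray) -> dict:
    """Mixed-design RM-ANOVA, vectorised over leading axes of ``Y``.

    Parameters
    ----------
    Y : ndarray, (..., N, t)
        Complete response matrix (subjects x within levels).
    group_codes : ndarray, (N,)
        Integer between-factor level per subject (0..k-1).

    Returns
    -------
    dict with, per effect (``treatment``, ``time``, ``treatment:time``):
    ``F``, ``df1``, ``df2``, ``p``, plus ``eps`` (GG epsilon), ``p_gg``
    for the within effects, and the sums of squares for oracle checks.
    """
    Y = np.asarray(Y, dtype=float)
    group_codes = np.asarray(group_codes)
    N, t = Y.shape[-2], Y.shape[-1]
    codes, counts = np.unique(group_codes, return_counts=True)
    k = len(codes)
    if k < 2 or t < 2:
        raise ValueError("need at least 2 groups and 2 within levels")
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 subjects")

    subj_mean = Y.mean(axis=-1)                    # (..., N)
    grand = Y.mean(axis=(-2, -1))[..., None]       # (..., 1)
    time_mean = Y.mean(axis=-2)                    # (..., t)

    group_masks = [group_codes == c for c in codes]
    cell_mean = np.stack([Y[..., m, :].mean(axis=-2) for m in group_masks], axis=-2)
    group_mean = cell_mean.mean(axis=-1)           # (..., k)

    n_g = counts.astype(float)
    ss_between_subj = t * ((subj_mean - grand) ** 2).sum(axis=-1)
    ss_treat = t * (n_g * (group_mean - grand) ** 2).sum(axis=-1)
    ss_subj_within = ss_between_subj - ss_treat

    ss_within = ((Y - subj_mean[..., None]) ** 2).sum(axis=(-2, -1))
    ss_time = N * ((time_mean - grand) ** 2).sum(axis=-1)
    inter_dev = (
        cell_mean
        - group_mean[..., None]
        - time_mean[..., None, :]
        + grand[..., None]
    )
    ss_inter = (n_g[:, None] * inter_dev**2).sum(axis=(-2, -1))
    ss_err_within = ss_within - ss_time - ss_inter

    df_treat, df_subj = k - 1, N - k
    df_time, df_inter = t - 1, (k - 1) * (t - 1)
    df_err = (N - k) * (t - 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        ms_subj = ss_subj_within / df_subj
        ms_err = ss_err_within / df_err
        F_treat = (ss_treat / df_treat) / ms_subj
        F_time = (ss_time / df_time) / ms_err
        F_inter = (ss_inter / df_inter) / ms_err

    # pooled within-group covariance of the repeated measures
    resid = Y - np.stack(
        [cell_mean[..., np.searchsorted(codes, g), :] for g in group_codes], axis=-2
    )
    S_pool = np.einsum("...it,...is->...ts", resid, resid) / (N - k)
    eps = _gg_epsilon_core(S_pool)

    def _p(F, d1, d2):
        return sstats.f.sf(F, d1, d2)

    eps_arr = np.asarray(eps)
    out = {
        "treatment": {
            "F": F_treat, "df1": df_treat, "df2": df_subj,
            "p": _p(F_treat, df_treat, df_subj), "ss": ss_treat,
        },
        "time": {
            "F": F_time, "df1": df_time, "df2": df_err,
            "p": _p(F_time, df_time, df_err),
            "eps": eps_arr, "p_gg": _p(F_time, df_time * eps_arr, df_err * eps_arr),
            "ss": ss_time,
        },
        "treatment:time": {
            "F": F_inter, "df1": df_inter, "df2": df_err,
            "p": _p(F_inter, df_inter, df_err),
            "eps": eps_arr, "p_gg": _p(F_inter, df_inter * eps_arr, df_err * eps_arr),
            "ss": ss_inter,
        },
        "ss_subj_within": ss_subj_within,
        "ss_err_within": ss_err_within,
        "ss_total": ((Y - grand[..., None]) ** 2).sum(axis=(-2, -1)),
        "zero_error_variance": np.asarray(ms_err == 0) | np.asarray(ms_subj == 0),
    }
    return out


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: float
    df_den: float
    p_uncorrected: float
    gg_epsilon: float | None = None
    p_gg: float | None = None

    @property
    def p(self) -> float:
        """GG-corrected p where applicable, uncorrected otherwise."""
        return self.p_gg if self.p_gg is not None else self.p_uncorrected


@dataclass
class AnovaResult:
    effects: dict
    n_subjects: int
    n_groups: int
    n_times: int
    group_sizes: dict
    alpha: float = 0.05
    posthoc: pd.DataFrame | None = None
    degenerate: bool = False

    @property
    def interaction_significant(self) -> bool:
        return self.effects["treatment:time"].p < self.alpha

    @property
    def main_treatment_significant(self) -> bool:
        return self.effects["treatment"].p < self.alpha

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append({
                "effect": name, "F": e.F, "df_num": e.df_num, "df_den": e.df_den,
                "gg_epsilon": e.gg_epsilon, "p_uncorrected": e.p_uncorrected,
                "p_gg": e.p_gg,
            })
        return pd.DataFrame(rows)


def _pivot_design(design: pd.DataFrame):
    """Long design (subject, group, time, value) -> (Y, groups, labels).

    Subjects with incomplete time series are dropped (complete-case
    analysis), keeping the design rectangular.
    """
    required = {"subject", "group", "time", "value"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design is missing columns: {sorted(missing)}")
    if isinstance(design["time"].dtype, pd.CategoricalDtype):
        time_levels = [t for t in design["time"].cat.categories
                       if t in set(design["time"].dropna())]
    else:
        time_levels = list(dict.fromkeys(design["time"]))
    wide = design.pivot_table(index="subject", columns="time", values="value",
                              aggfunc="first", observed=True)
    wide = wide.reindex(columns=time_levels)
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    groups_by_subject = design.drop_duplicates("subject").set_index("subject")["group"]
    group_labels = groups_by_subject.loc[complete.index]
    return complete, group_labels, time_levels, dropped


def rm_anova(design: pd.DataFrame, alpha: float = 0.05) -> AnovaResult:
    """Mixed repeated-measures ANOVA from a long-format design table.

    ``design`` columns: ``subject``, ``group`` (between factor), ``time``
    (within factor), ``value``.  Returns F, degrees of freedom, GG epsilon
    and corrected p per effect.  The interaction carries
    ``(k-1)(t-1)`` numerator and ``(N-k)(t-1)`` denominator df.
    """
    wide, group_labels, time_levels, dropped = _pivot_design(design)
    Y = wide.to_numpy()
    uniq = list(dict.fromkeys(group_labels))
    codes = np.array([uniq.index(g) for g in group_labels])
    res = mixed_anova_arrays(Y, codes)

    effects = {}
    for name in ("treatment", "time", "treatment:time"):
        e = res[name]
        effects[name] = EffectResult(
            F=float(np.squeeze(e["F"])),
            df_num=float(e["df1"]), df_den=float(e["df2"]),
            p_uncorrected=float(np.squeeze(e["p"])),
            gg_epsilon=float(np.squeeze(e["eps"])) if "eps" in e else None,
            p_gg=float(np.squeeze(e["p_gg"])) if "p_gg" in e else None,
        )
    sizes = {g: int((group_labels == g).sum()) for g in uniq}
    return AnovaResult(
        effects=effects, n_subjects=len(wide), n_groups=len(uniq),
        n_times=len(time_levels), group_sizes=sizes, alpha=alpha,
        degenerate=bool(np.squeeze(res["zero_error_variance"])),
    )


# ---------------------------------------------------------------------------
# post-hoc contrasts and the GFC decision rule


def _pairwise_groups(values: pd.DataFrame, label: str):
    """Pooled-variance two-sample t-tests between all group pairs."""
    rows = []
    groups = list(dict.fromkeys(values["group"]))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = values.loc[values["group"] == groups[i], "value"].to_numpy()
            b = values.loc[values["group"] == groups[j], "value"].to_numpy()
            tt = sstats.ttest_ind(a, b, equal_var=True)
            rows.append({
                "level": label, "group_a": groups[i], "group_b": groups[j],
                "diff": float(a.mean() - b.mean()),
                "t": float(tt.statistic), "p_raw": float(tt.pvalue),
            })
    return rows


def bonferroni_posthoc(design: pd.DataFrame, anova: AnovaResult,
                       force: bool = False) -> pd.DataFrame:
    """Pairwise between-group contrasts at each time level, Bonferroni-adjusted.

    Executed only when the treatment:time interaction is significant at
    the ANOVA's alpha (``force=True`` overrides the gate).  The family
    size is the number of comparisons actually performed; adjusted p
    values are clipped at 1.
    """
    cols = ["level", "group_a", "group_b", "diff", "t", "p_raw", "p_bonferroni"]
    if not force and not anova.interaction_significant:
        return pd.DataFrame(columns=cols)
    rows = []
    for time_level in dict.fromkeys(design["time"]):
        sub = design[design["time"] == time_level]
        rows.extend(_pairwise_groups(sub, str(time_level)))
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = np.minimum(out["p_raw"] * m, 1.0)
    return out[cols]


@dataclass
class GFCInference:
    """Which branch of the global-connectivity decision rule fired."""

    branch: str  # 'interaction' | 'main_effect' | 'none'
    anova: AnovaResult
    posthoc: pd.DataFrame


def gfc_inference(design: pd.DataFrame, anova: AnovaResult | None = None,
                  alpha: float = 0.05) -> GFCInference:
    """Decision rule for a global connectivity effect.

    A significant treatment x time interaction triggers per-time
    post-hocs; otherwise a significant treatment main effect is read as
    an overall (time-collapsed) connectivity change, tested by pairwise
    group contrasts on subject means; otherwise no effect is declared.
    """
    if anova is None:
        anova = rm_anova(design, alpha=alpha)
    if anova.interaction_significant:
        ph = bonferroni_posthoc(design, anova, force=True)
        return GFCInference("interaction", anova, ph)
    if anova.main_treatment_significant:
        collapsed = (
            design.groupby(["subject", "group"], sort=False, observed=True)["value"]
            .mean()
            .reset_index()
        )
        rows = _pairwise_groups(collapsed, "overall")
        ph = pd.DataFrame(rows)
        if len(ph):
            ph["p_bonferroni"] = np.minimum(ph["p_raw"] * len(ph), 1.0)
        return GFCInference("main_effect", anova, ph)
    return GFCInference(
        "none", anova,
        pd.DataFrame(columns=["level", "group_a", "group_b", "diff", "t",
                              "p_raw", "p_bonferroni"]),
    )
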