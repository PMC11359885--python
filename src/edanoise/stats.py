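"""Dose-response statistics for the graded-noise design.

Two analyses over a subjects x levels feature table:

* one-way repeated-measures ANOVA (within-subject factor: noise level)
  with Sidak-corrected paired post hoc comparisons, and
* a linear mixed model y_ij = (b0 + u0_i) + (b1 + u1_i) * x_ij + e_ij with
  the level coded in 5 dB steps above 70 dB (x = (dB - 70) / 5), a
  per-subject random intercept and slope with free correlation, fitted by
  REML; the per-5 dB fixed slope b1 and its Wald 95% CI are the headline
  estimates.

The ANOVA is computed directly from the sums-of-squares decomposition
(complete cases only); the mixed model delegates to statsmodels' MixedLM,
which implements the stated model and criterion.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .synthetic import BASE_LEVEL_DB

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "LMMFit",
    "to_wide",
    "rm_anova",
    "pairwise_sidak",
    "fit_lmm",
]


class StatsError(ValueError):
    """Invalid statistical input."""


class ConvergenceError(RuntimeError):
    """Mixed-model optimization failed; diagnostics in the message."""


@dataclass(frozen=True)
class PairwiseComparison:
    level_a: float
    level_b: float
    mean_diff: float
    raw_p: float
    sidak_p: float


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_treatment: int
    df_error: int
    p_value: float
    pairwise: tuple[PairwiseComparison, ...] = ()


@dataclass(frozen=True)
class LMMFit:
    beta0: float
    beta1_per5db: float
    ci95_low: float
    ci95_high: float
    p_value: float
    var_b0: float
    var_b1: float
    corr_b0b1: float
    sigma2: float
    n_subjects: int
    n_obs: int
    converged: bool = True


def to_wide(features: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Pivot a long feature table to subjects x levels for one feature."""
    if dv not in features.columns:
        raise StatsError(f"feature {dv!r} not in table")
    wide = features.pivot_table(
        index="subject_id", columns="level_db", values=dv, aggfunc="mean"
    )
    return wide[sorted(wide.columns)]


def _complete(mat: pd.DataFrame) -> pd.DataFrame:
    out = mat.dropna(axis=0, how="any")
    if out.shape[1] < 2 or out.shape[0] < 2:
        raise StatsError(
            f"repeated-measures ANOVA needs >= 2 subjects and >= 2 levels "
            f"after complete-case filtering, got {out.shape[0]} x {out.shape[1]}"
        )
    return out


def rm_anova(mat: pd.DataFrame) -> AnovaResult:
    """One-way within-subject ANOVA from the sums-of-squares decomposition.

    SS_total is partitioned into between-subject, between-level and error
    components; F = MS_treatment / MS_error on (k-1, (n-1)(k-1)) degrees of
    freedom. No sphericity correction is applied. Exact additivity (zero
    error SS with distinct level means) is reported as F = +inf, p = 0.
    """
    m = _complete(mat).to_numpy(dtype=float)
    n, k = m.shape
    grand = m.mean()
    ss_total = float(((m - grand) ** 2).sum())
    ss_subj = float(k * ((m.mean(axis=1) - grand) ** 2).sum())
    ss_treat = float(n * ((m.mean(axis=0) - grand) ** 2).sum())
    ss_err = max(ss_total - ss_subj - ss_treat, 0.0)
    df_t, df_e = k - 1, (n - 1) * (k - 1)

    scale = max(ss_total, 1.0)
    if ss_err / scale < 1e-14:  # exact additivity (or all-equal)
        if ss_treat / scale < 1e-14:
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
    else:
        f = (ss_treat / df_t) / (ss_err / df_e)
        p = float(spstats.f.sf(f, df_t, df_e))
    return AnovaResult(f_stat=float(f), df_treatment=df_t, df_error=df_e, p_value=p)


def pairwise_sidak(mat: pd.DataFrame) -> tuple[PairwiseComparison, ...]:
    """All paired t tests between levels with Sidak-adjusted p values.

    sidak_p = 1 - (1 - raw_p)^m with m = k(k-1)/2 comparisons. Zero-variance
    difference columns get raw_p = 0 when the means differ and 1 otherwise.
    """
    w = _complete(mat)
    levels = list(w.columns)
    m = len(levels) * (len(levels) - 1) // 2
    out = []
    for a, b in itertools.combinations(levels, 2):
        d = (w[b] - w[a]).to_numpy(dtype=float)
        mean_diff = float(d.mean())
        if np.allclose(d.std(ddof=1), 0.0):
            raw_p = 1.0 if np.isclose(mean_diff, 0.0) else 0.0
        else:
            raw_p = float(spstats.ttest_rel(w[b], w[a]).pvalue)
        sidak_p = float(min(1.0, 1.0 - (1.0 - raw_p) ** m))
        out.append(
            PairwiseComparison(
                level_a=float(a), level_b=float(b),
                mean_diff=mean_diff, raw_p=raw_p, sidak_p=sidak_p,
            )
        )
    return tuple(out)


def fit_lmm(
    features: pd.DataFrame,
    dv: str,
    base_level_db: float = BASE_LEVEL_DB,
) -> LMMFit:
    """REML fit of the random-intercept-and-slope dose-response model.

    ``features`` is a long table with ``subject_id``, ``level_db`` and the
    dependent variable ``dv``; rows with a missing ``dv`` are dropped (all
    remaining observations are used — no complete-case restriction). The
    fixed slope is reported per 5 dB step above ``base_level_db``.

    Raises :class:`ConvergenceError` when the optimizer fails, rather than
    silently falling back to a simpler model.
    """
    if dv not in features.columns:
        raise StatsError(f"feature {dv!r} not in table")
    data = features[["subject_id", "level_db", dv]].dropna().copy()
    data["x"] = (data["level_db"].astype(float) - base_level_db) / 5.0
    data = data.rename(columns={dv: "y"})

    per_subj = data.groupby("subject_id")["level_db"].nunique()
    n_subj = int((per_subj >= 2).sum())
    if n_subj < 5:
        raise StatsError(
            f"mixed model needs >= 5 subjects with >= 2 observed levels, "
            f"got {n_subj}"
        )
    data = data[data["subject_id"].isin(per_subj[per_subj >= 2].index)]

    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    model = smf.mixedlm("y ~ x", data, groups=data["subject_id"], re_formula="~x")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            res = model.fit(reml=True, method=["lbfgs", "powell", "cg"])
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise ConvergenceError(
                f"mixed-model fit failed for {dv!r}: {exc}"
            ) from exc
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError(
            f"mixed-model fit for {dv!r} returned non-finite parameters: "
            f"{dict(res.params)}"
        )

    beta0 = float(res.params["Intercept"])
    beta1 = float(res.params["x"])
    se = float(res.bse["x"])
    if not np.isfinite(se) or se == 0.0:
        se = 1e-12  # degenerate (noise-free) fit: zero-width interval padded
    z = spstats.norm.ppf(0.975)
    p = float(2.0 * spstats.norm.sf(abs(beta1) / se)) if se > 0 else 0.0

    cov = np.asarray(res.cov_re, dtype=float)
    var_b0 = max(float(cov[0, 0]), 0.0)
    var_b1 = max(float(cov[1, 1]), 0.0)
    denom = np.sqrt(var_b0 * var_b1)
    corr = float(cov[0, 1] / denom) if denom > 0 else 0.0
    corr = float(np.clip(corr, -1.0, 1.0))

    return LMMFit(
        beta0=beta0,
        beta1_per5db=beta1,
        ci95_low=beta1 - z * se,
        ci95_high=beta1 + z * se,
        p_value=p,
        var_b0=var_b0,
        var_b1=var_b1,
        corr_b0b1=corr,
        sigma2=float(res.scale),
        n_subjects=int(data["subject_id"].nunique()),
        n_obs=int(len(data)),
        converged=bool(getattr(res, "converged", True)),
    )
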