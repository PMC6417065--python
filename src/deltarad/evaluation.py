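"""Survival evaluation and 2D-vs-3D score comparison.

Kaplan-Meier / log-rank and Cox proportional-hazards models are delegated
to lifelines; Harrell's C-index and its paired bootstrap comparison are
implemented here (the test-suite checks them against brute-force
enumeration). AUC / Hosmer-Lemeshow target binary event occurrence
(censoring times ignored) after a logistic recalibration of the score,
since a raw Rad score is not a probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "km_logrank",
    "cox_fit",
    "c_index",
    "compare_c",
    "auc_hl",
    "pearson_vif",
    "vif_from_r",
]


def km_logrank(times, events, groups):
    """Two-sample log-rank test plus Kaplan-Meier curves.

    Returns ``(chi2, p, curves)`` where curves maps group label to a fitted
    :class:`lifelines.KaplanMeierFitter`.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"km_logrank: need exactly 2 groups, got {len(labels)}")
    if events.sum() < 1:
        raise ValueError("km_logrank: no events")
    a = groups == labels[0]
    res = logrank_test(times[a], times[~a], events[a], events[~a])
    curves = {}
    for lab in labels:
        sel = groups == lab
        kmf = KaplanMeierFitter(label=str(lab))
        kmf.fit(times[sel], events[sel])
        curves[lab] = kmf
    return float(res.test_statistic), float(res.p_value), curves


def cox_fit(covariates: pd.DataFrame, times, events, mode: str = "univariate") -> pd.DataFrame:
    """Cox proportional-hazards tables (Efron ties via lifelines).

    ``mode="univariate"`` fits each column alone; ``mode="multivariate"``
    first screens columns univariately and jointly fits those with p < 0.05.
    Non-convergence / monotone likelihood is flagged in the ``flag`` column
    rather than raised.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"cox_fit: unknown mode {mode!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)

    def _fit_one(cols) -> pd.DataFrame | None:
        df = covariates[cols].copy()
        df["time"] = times
        df["event"] = events
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        out = cph.summary[["exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]]
        out = out.rename(
            columns={
                "exp(coef)": "HR",
                "exp(coef) lower 95%": "HR_lower95",
                "exp(coef) upper 95%": "HR_upper95",
            }
        )
        return out

    rows = []
    uni_p = {}
    for col in covariates.columns:
        try:
            tab = _fit_one([col])
            flag = ""
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            tab = pd.DataFrame(
                {"HR": [np.nan], "HR_lower95": [np.nan], "HR_upper95": [np.nan], "p": [np.nan]},
                index=[col],
            )
            flag = f"non-convergence: {exc}"
        tab = tab.assign(mode="univariate", flag=flag)
        uni_p[col] = float(tab["p"].iloc[0]) if np.isfinite(tab["p"].iloc[0]) else np.nan
        rows.append(tab)
    result = pd.concat(rows)
    if mode == "univariate":
        return result

    selected = [c for c, p in uni_p.items() if np.isfinite(p) and p < 0.05]
    if not selected:
        return result.assign(mode="univariate")
    sub = covariates[selected]
    # collinearity guard: flag (do not crash on) rank-deficient designs
    flag = ""
    if np.linalg.matrix_rank(np.corrcoef(sub.to_numpy(), rowvar=False).reshape(len(selected), -1)) < len(selected):
        flag = "collinear covariates"
    try:
        multi = _fit_one(selected)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        multi = pd.DataFrame(
            {
                "HR": np.nan,
                "HR_lower95": np.nan,
                "HR_upper95": np.nan,
                "p": np.nan,
            },
            index=selected,
        )
        flag = (flag + "; " if flag else "") + f"non-convergence: {exc}"
    multi = multi.assign(mode="multivariate", flag=flag)
    return pd.concat([result, multi])


def _concordance_counts(scores, times, events):
    """Vectorized concordant / tied counts over usable pairs.

    A pair (i, j) is usable when the earlier time is an event (Harrell's
    event-anchored comparability). Ties in score count 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(scores)
    ti = times[:, None]
    tj = times[None, :]
    # i is the anchor: event at the earlier time
    usable = (events[:, None] == 1) & ((ti < tj) | ((ti == tj) & (events[None, :] == 0)))
    si = scores[:, None]
    sj = scores[None, :]
    conc = usable & (si > sj)
    tied = usable & (si == sj)
    per_subject = usable.sum(axis=1) + usable.sum(axis=0)
    num = conc.sum(axis=1) + conc.sum(axis=0) + 0.5 * (tied.sum(axis=1) + tied.sum(axis=0))
    return float(usable.sum()), float(conc.sum() + 0.5 * tied.sum()), per_subject, num


def c_index(scores, times, events):
    """Harrell's concordance index with a U-statistic standard error.

    Returns ``(C, SE)``. SE follows the degree-2 U-statistic approximation
    from per-subject concordance contributions.
    """
    n_pairs, n_conc, per_subject, num = _concordance_counts(scores, times, events)
    if n_pairs == 0:
        raise ValueError("c_index: no comparable pairs")
    c = n_conc / n_pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(per_subject > 0, num / per_subject, c)
    m = per_subject > 0
    n_eff = int(m.sum())
    se = float(2.0 * np.sqrt(max(np.var(u[m], ddof=1), 0.0) / n_eff)) if n_eff > 1 else float("nan")
    return float(c), se


def compare_c(scores_a, scores_b, times, events, n_boot: int = 1000, seed: int = 0) -> float:
    """Two-sided p for C(A) - C(B) from a paired bootstrap.

    Resamples patients with replacement, recomputes both C-indices on each
    replicate, and applies a normal approximation to the bootstrap
    distribution of the difference.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if scores_a.shape != scores_b.shape:
        raise ValueError("compare_c: score vectors must cover the same patients")
    if n_boot < 100:
        warnings.warn("compare_c: fewer than 100 bootstrap replicates is unreliable")
    if np.array_equal(scores_a, scores_b):
        return 1.0
    rng = np.random.default_rng(seed)
    n = len(times)
    diffs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            ca, _ = c_index(scores_a[idx], times[idx], events[idx])
            cb, _ = c_index(scores_b[idx], times[idx], events[idx])
        except ValueError:
            continue
        diffs.append(ca - cb)
    diffs = np.asarray(diffs)
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 1.0
    z = diffs.mean() / sd
    return float(2.0 * stats.norm.sf(abs(z)))


def auc_hl(scores, event_indicators, n_groups: int = 10):
    """AUC and Hosmer-Lemeshow calibration for binary event occurrence.

    The raw score is logistically recalibrated before deciling; the HL
    statistic uses g - 2 degrees of freedom. Requires both classes and,
    for HL, at least 30 subjects.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(event_indicators, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("auc_hl: need both event and non-event subjects")
    # AUC as the Mann-Whitney rank statistic
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    auc = float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
    if len(y) < 30:
        return auc, float("nan"), float("nan")
    # logistic recalibration
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    lr.fit(scores[:, None], y)
    prob = lr.predict_proba(scores[:, None])[:, 1]
    edges = np.quantile(prob, np.linspace(0, 1, n_groups + 1))
    edges[0] -= 1e-9
    bins = np.clip(np.searchsorted(edges, prob, side="left") - 1, 0, n_groups - 1)
    chi2 = 0.0
    used = 0
    for g in range(n_groups):
        sel = bins == g
        ng = sel.sum()
        if ng == 0:
            continue
        used += 1
        obs = y[sel].sum()
        exp = prob[sel].sum()
        var = exp * (1.0 - exp / ng)
        if var > 1e-12:
            chi2 += (obs - exp) ** 2 / var
    df = max(used - 2, 1)
    p = float(stats.chi2.sf(chi2, df))
    return auc, float(chi2), p


def vif_from_r(r: float) -> float:
    """Variance inflation factor for a predictor pair: 1 / (1 - r^2)."""
    if abs(r) >= 1.0:
        raise ValueError("vif_from_r: |r| must be < 1")
    return 1.0 / (1.0 - r * r)


def pearson_vif(scores_3d, scores_2d):
    """Pearson r with Fisher-z 95% CI, t-test p, and VIF = 1/(1-r^2).

    Returns ``(r, (lo, hi), p, vif)``; the VIF is rounded to two decimals
    as reported.
    """
    x = np.asarray(scores_3d, dtype=float)
    y = np.asarray(scores_2d, dtype=float)
    if len(x) < 3:
        raise ValueError("pearson_vif: need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("pearson_vif: zero variance in a score vector")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0 - 1e-12:
        raise ValueError("pearson_vif: |r| = 1, VIF diverges")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(len(x) - 3)
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return r, (float(lo), float(hi)), float(p), round(vif_from_r(r), 2)
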