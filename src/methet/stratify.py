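"""Epi-mutation-burden stratification and survival comparison.

Burden counts per cancer type are split into low/high groups with a
deterministic one-dimensional two-component Gaussian EM on log10(count + 1)
(quantile initialisation, no random restarts).  Two independent EM fits —
one on N_hyper, one on N_hypo — combine into four patient categories
(hyper, hypo, intermediate, control).  Cancer types are assigned pattern
N1/N2/N3 from their fraction of high-epi-mutation samples (thresholds 0.8
and 0.4), and for N2/N3 cohorts the LowEpiMut group is the bottom 70% / 30%
by the weighted burden score N_hyper + 4*N_hypo (N2) or N_hyper + 2*N_hypo
(N3), with a purity exclusion against contamination from low-purity samples.
Survival is compared between groups with Kaplan-Meier curves and the
two-group log-rank test (via lifelines).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.special import logsumexp
from scipy.stats import norm

from .purity_window import PurityWindow

VARIANCE_FLOOR = 1e-6

#: weight on N_hypo in the burden score, by cancer pattern
PATTERN_K_HYPO = {"N2": 4, "N3": 2}

#: fraction of samples taken as LowEpiMut, by cancer pattern
PATTERN_LOW_FRAC = {"N2": 0.7, "N3": 0.3}


# ---------------------------------------------------------------------------
# 1D Gaussian EM
# ---------------------------------------------------------------------------


@dataclass
class EMFit:
    """Two-component 1D Gaussian mixture fit (component 1 = larger mean)."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray  # n x 2, columns ordered (low, high)
    labels: pd.Series             # "low" / "high" per sample
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    degenerate: bool = False


def _log10p1(x: np.ndarray) -> np.ndarray:
    return np.log10(np.asarray(x, dtype=float) + 1.0)


def em_fit_1d(
    values,
    transform="log10p1",
    max_iter: int = 500,
    tol: float = 1e-8,
    init_quantiles: tuple[float, float] = (0.25, 0.75),
) -> EMFit:
    """Deterministic two-component Gaussian EM on (transformed) values.

    Initial means sit at the 25th/75th percentiles; variances are floored at
    1e-6.  The log-likelihood trace is monotone non-decreasing by
    construction (iteration stops rather than record a floored-variance
    decrease).  Zero overall variance yields a degenerate single-label fit
    with ``converged=False``.
    """
    series = pd.Series(values, dtype=float)
    if series.notna().sum() < 4:
        raise ValueError("need at least 4 finite values")
    idx = series.index
    x = series.to_numpy()
    if transform == "log10p1":
        x = _log10p1(x)
    elif callable(transform):
        x = np.asarray(transform(x), dtype=float)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values after transform")

    if np.var(x) < 1e-12:
        labels = pd.Series("low", index=idx)
        resp = np.column_stack([np.ones_like(x), np.zeros_like(x)])
        return EMFit(
            means=np.array([x.mean(), x.mean()]),
            variances=np.array([VARIANCE_FLOOR, VARIANCE_FLOOR]),
            weights=np.array([1.0, 0.0]),
            responsibilities=resp, labels=labels,
            converged=False, degenerate=True,
        )

    means = np.quantile(x, init_quantiles).astype(float)
    if means[0] == means[1]:
        means[1] = means[0] + max(x.std(), 1e-3)
    variances = np.full(2, max(np.var(x), VARIANCE_FLOOR))
    weights = np.array([0.5, 0.5])

    trace: list[float] = []
    converged = False
    resp = np.full((x.size, 2), 0.5)
    for _ in range(max_iter):
        log_comp = (
            np.log(np.maximum(weights, 1e-300))[None, :]
            + norm.logpdf(x[:, None], means[None, :], np.sqrt(variances)[None, :])
        )
        ll = float(logsumexp(log_comp, axis=1).sum())
        if trace and ll < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
            # floored variances can break strict monotonicity; stop here so
            # the recorded trace stays non-decreasing
            converged = True
            break
        if trace and abs(ll - trace[-1]) <= tol * max(1.0, abs(trace[-1])):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        resp = np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])
        nk = resp.sum(axis=0)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / np.maximum(
            nk, 1e-12
        )
        variances = np.maximum(variances, VARIANCE_FLOOR)

    # responsibilities under the final parameters
    log_comp = (
        np.log(np.maximum(weights, 1e-300))[None, :]
        + norm.logpdf(x[:, None], means[None, :], np.sqrt(variances)[None, :])
    )
    resp = np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])

    order = np.argsort(means)  # component 0 = low mean, 1 = high mean
    means, variances, weights = means[order], variances[order], weights[order]
    resp = resp[:, order]
    hard = np.where(resp[:, 1] > resp[:, 0], "high", "low")
    return EMFit(
        means=means, variances=variances, weights=weights,
        responsibilities=resp, labels=pd.Series(hard, index=idx),
        loglik_trace=trace, converged=converged,
    )


# ---------------------------------------------------------------------------
# Category and pattern assignment
# ---------------------------------------------------------------------------

FOUR_CATEGORY = {
    ("high", "low"): "hyper",
    ("low", "high"): "hypo",
    ("high", "high"): "intermediate",
    ("low", "low"): "control",
}


def four_categories(em_hyper: EMFit, em_hypo: EMFit) -> pd.Series:
    """Combine hyper- and hypo-burden EM labels into four patient categories."""
    if not em_hyper.labels.index.equals(em_hypo.labels.index):
        raise ValueError("EM fits cover different samples")
    cats = [
        FOUR_CATEGORY[(h, l)]
        for h, l in zip(em_hyper.labels, em_hypo.labels)
    ]
    return pd.Series(cats, index=em_hyper.labels.index, name="category")


def burden_score(burdens: pd.DataFrame, k_hypo: int) -> pd.Series:
    """Weighted epi-mutation burden N_hyper + k_hypo * N_hypo."""
    return (burdens["N_hyper"] + k_hypo * burdens["N_hypo"]).rename("score")


def classify_epimut(
    burdens: pd.DataFrame,
    method: str = "em_total",
    **params,
) -> pd.Series:
    """Per-sample HighEpiMut / LowEpiMut labels.

    ``em_total`` runs the EM on N_hyper + N_hypo and maps the high cluster to
    HighEpiMut.  ``fixed_thresholds`` needs ``t_hyper`` and ``t_hypo``
    (HighEpiMut iff either count reaches its threshold).  ``rank_frac`` needs
    ``frac`` and ``k_hypo`` and labels the bottom ``frac`` by the weighted
    burden score as LowEpiMut (ties: smaller score first, then sample id).
    """
    if method == "em_total":
        fit = em_fit_1d(burdens["N_hyper"] + burdens["N_hypo"], **params)
        lab = fit.labels.map({"high": "HighEpiMut", "low": "LowEpiMut"})
        return lab.rename("epimut")
    if method == "fixed_thresholds":
        try:
            t_hyper, t_hypo = params["t_hyper"], params["t_hypo"]
        except KeyError as exc:
            raise ValueError("fixed_thresholds requires t_hyper and t_hypo") from exc
        high = (burdens["N_hyper"] >= t_hyper) | (burdens["N_hypo"] >= t_hypo)
        return pd.Series(np.where(high, "HighEpiMut", "LowEpiMut"),
                         index=burdens.index, name="epimut")
    if method == "rank_frac":
        try:
            frac, k_hypo = params["frac"], params["k_hypo"]
        except KeyError as exc:
            raise ValueError("rank_frac requires frac and k_hypo") from exc
        score = burden_score(burdens, k_hypo)
        order = score.to_frame().assign(sid=score.index.astype(str))
        order = order.sort_values(["score", "sid"], kind="mergesort")
        n_low = int(round(frac * len(score)))
        low_ids = set(order.index[:n_low])
        return pd.Series(
            ["LowEpiMut" if i in low_ids else "HighEpiMut" for i in burdens.index],
            index=burdens.index, name="epimut",
        )
    raise ValueError(f"unknown method {method!r}")


def cancer_pattern(high_frac: float) -> str:
    """Pattern from the fraction of HighEpiMut samples (thresholds 0.8 / 0.4)."""
    if not 0 <= high_frac <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if high_frac >= 0.8:
        return "N1"
    if high_frac >= 0.4:
        return "N2"
    return "N3"


def low_epimut_purity_exclusion(
    labels: pd.Series,
    samples: pd.DataFrame,
    window: PurityWindow,
    purity_col: str = "purity",
) -> pd.Series:
    """Drop LowEpiMut samples whose purity falls below the window's lower bound.

    Removed samples leave the labelling entirely (they are not relabelled);
    purity exactly at the bound is retained; HighEpiMut samples are untouched.
    """
    purity = samples[purity_col].reindex(labels.index)
    drop = (labels == "LowEpiMut") & (purity < window.lo - 1e-9)
    return labels[~drop.fillna(False)]


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve as a (time, survival) step table."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(uniq)}")
    mask = groups == uniq[0]
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("each group needs at least one subject")
    res = logrank_test(times[mask], times[~mask], events[mask], events[~mask])
    return float(res.test_statistic), float(res.p_value)
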