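"""Association machinery: correlations, signature scores, partial R²,
biomarker affected/unaffected classification, panel scoring and AUC.

Hypermethylation biomarkers are classified by how strongly their methylation
tracks global hypomethylation (the maintenance-loss proxy) across tumors:
markers with Pearson r < -0.3 at P < .05 are *affected* (their signal is
attenuated in maintenance-deficient tumors), markers with r > -0.1 are
*not affected*, and the rest are intermediate.  For cfDNA evaluation, panel
scores are per-sample means over the panel's markers and discrimination is
measured as the Mann-Whitney AUC (ties count 1/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .io_formats import BetaMatrix

logger = logging.getLogger("methet")

AFFECTED_R = -0.3
AFFECTED_P = 0.05
NOT_AFFECTED_R = -0.1


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    method: str
    defined: bool = True


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with pairwise-complete missing handling.

    Pearson p-values come from the t distribution with n-2 df; Spearman uses
    average ranks for ties with the t approximation.  Zero variance in either
    vector yields an undefined (flagged) result rather than an exception.
    """
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    ok = x.notna() & y.notna()
    xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 paired finite values, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        logger.warning("zero variance: correlation undefined")
        return CorrelationResult(np.nan, n, np.nan, method, defined=False)
    if method == "pearson":
        r, p = stats.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = stats.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(r), n, float(p), method)


def signature_score(expr: pd.DataFrame, gene_list) -> pd.Series:
    """Mean per-gene Z-score over a gene list (genes x samples input).

    Z-scores use the sample standard deviation (n - 1) across samples per
    gene; absent and zero-variance genes are dropped with a log message.
    """
    present = [g for g in gene_list if g in expr.index]
    absent = len(list(gene_list)) - len(present)
    if absent:
        logger.info("%d signature genes absent from the expression matrix", absent)
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    sub = expr.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.info("dropping %d zero-variance signature genes", int(zero.sum()))
        sub, sd = sub[~zero], sd[~zero]
    if sub.empty:
        raise ValueError("all signature genes have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0).rename("signature_score")


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def partial_r2(y, covariates: pd.DataFrame, focal_column: str) -> float:
    """Partial R² of the focal covariate: (SSE_reduced - SSE_full) / SSE_reduced.

    Both models include an intercept; the reduced model drops the focal
    column.  Rank deficiency raises with the offending columns named.
    """
    y = np.asarray(y, dtype=float)
    cov = pd.DataFrame(covariates).astype(float)
    if focal_column not in cov.columns:
        raise ValueError(f"focal column {focal_column!r} not among covariates")
    n, p = cov.shape
    if n <= p + 1:
        raise ValueError("need n > number of covariates + 1")
    X_full = np.column_stack([np.ones(n), cov.to_numpy()])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError(
            f"rank-deficient design; check collinearity among {list(cov.columns)}"
        )
    reduced = cov.drop(columns=[focal_column])
    X_red = np.column_stack([np.ones(n), reduced.to_numpy()])
    sse_full = _sse(y, X_full)
    sse_red = _sse(y, X_red)
    if sse_red <= 0:
        return 0.0  # reduced model already fits exactly
    return float(max(0.0, (sse_red - sse_full) / sse_red))


def assess_markers(
    marker_betas: BetaMatrix,
    global_hypo: pd.Series,
    r_affected: float = AFFECTED_R,
    p_affected: float = AFFECTED_P,
    r_not_affected: float = NOT_AFFECTED_R,
) -> pd.DataFrame:
    """Classify each marker by its Pearson correlation with global hypomethylation.

    Returns one row per assessable marker (marker_id index; r, p, n, class).
    Markers with all-missing betas or undefined correlations are skipped with
    a log message.
    """
    hypo = global_hypo.reindex(marker_betas.sample_ids)
    rows = {}
    skipped = 0
    for marker in marker_betas.probe_ids:
        betas = marker_betas.data.loc[marker]
        ok = betas.notna() & hypo.notna()
        if ok.sum() < 3:
            skipped += 1
            continue
        res = correlate(betas[ok], hypo[ok])
        if not res.defined:
            skipped += 1
            continue
        if res.r < r_affected and res.p < p_affected:
            klass = "affected"
        elif res.r > r_not_affected:
            klass = "not_affected"
        else:
            klass = "intermediate"
        rows[marker] = {"r": res.r, "p": res.p, "n": res.n, "class": klass}
    if skipped:
        logger.info("skipped %d markers with insufficient or degenerate data", skipped)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "marker_id"
    return out


def panel_mean(signal: pd.DataFrame, panel) -> pd.Series:
    """Per-sample mean over a marker panel (samples x markers input).

    Missing markers are skipped per sample; a sample with no observed panel
    marker gets a missing score.  An empty panel (after intersecting with the
    columns) is an error.
    """
    cols = [m for m in panel if m in signal.columns]
    if not cols:
        raise ValueError("no panel markers present in the signal matrix")
    if len(cols) < len(list(panel)):
        logger.info("%d panel markers absent from the signal matrix",
                    len(list(panel)) - len(cols))
    return signal[cols].mean(axis=1, skipna=True).rename("panel_mean")


def combined_panel_score(
    signal: pd.DataFrame, hyper_panel, hypo_panel
) -> pd.Series:
    """Hyper-panel mean minus hypo-panel mean, so both signals point cancer-ward."""
    return (panel_mean(signal, hyper_panel) - panel_mean(signal, hypo_panel)).rename(
        "combined_score"
    )


def auc(scores, labels) -> float:
    """Mann-Whitney AUC of scores against binary labels (ties contribute 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.isnan(scores).any():
        raise ValueError("scores contain missing values")
    if len(np.unique(labels)) != 2:
        raise ValueError("need exactly two classes")
    return float(roc_auc_score(labels, scores))
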