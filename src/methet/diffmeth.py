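"""Differential CGI probe calling and per-sample epi-mutation burdens.

A tumor probe is differential when its beta value deviates by at least 0.2
from the mean of the matched normal samples, subject to a constraint on the
normal mean itself: hypermethylation calls require a normal mean below 0.3,
hypomethylation calls a normal mean above 0.7.  A probe-level recurrence
filter then clears calls at probes flagged in too small a fraction of tumors
(strictly more than 5% required for array cohorts, 10% for cell-line panels)
to suppress atypical single samples.  Per-sample burdens N_hyper / N_hypo
are the surviving call counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix

logger = logging.getLogger("methet")

HYPER, NONE, HYPO = 1, 0, -1


@dataclass(frozen=True)
class CallConfig:
    """Thresholds of the differential-probe rule."""

    delta: float = 0.2              # minimum |beta - normal mean|
    hyper_normal_max: float = 0.3   # normal mean must be below this for hyper
    hypo_normal_min: float = 0.7    # and above this for hypo


@dataclass
class DifferentialCalls:
    """Per-(probe, sample) flags (+1 hyper / -1 hypo / 0) and their config."""

    flags: pd.DataFrame  # int8, probes x samples
    config: CallConfig
    recurrence_frac: float | None = None  # None until the filter has run


def normal_reference(normals: BetaMatrix) -> pd.DataFrame:
    """Per-probe mean beta over non-missing normal samples.

    Probes whose normals are all missing are excluded (logged).  Returns a
    DataFrame with columns ``normal_mean`` and ``n_normals``.
    """
    if normals.data.empty:
        raise ValueError("empty normal matrix")
    n_obs = normals.data.notna().sum(axis=1)
    dropped = int((n_obs == 0).sum())
    if dropped:
        logger.info("excluding %d probes with all-missing normals", dropped)
    keep = n_obs > 0
    return pd.DataFrame({
        "normal_mean": normals.data.mean(axis=1, skipna=True)[keep],
        "n_normals": n_obs[keep].astype(int),
    })


def call_probes(
    tumors: BetaMatrix,
    ref: pd.DataFrame,
    cfg: CallConfig = CallConfig(),
) -> DifferentialCalls:
    """Flag each (probe, sample) cell as hyper / hypo / none (pre-recurrence).

    Tumor probes absent from the reference are dropped (logged); missing
    tumor betas are never imputed and yield no call.
    """
    shared = tumors.probe_ids.intersection(ref.index)
    missing = len(tumors.probe_ids) - len(shared)
    if missing:
        logger.info("dropping %d tumor probes without a normal reference", missing)
    beta = tumors.data.loc[shared]
    mean = ref.loc[shared, "normal_mean"].to_numpy()[:, None]
    vals = beta.to_numpy(dtype=float)

    with np.errstate(invalid="ignore"):  # NaN betas compare False -> no call
        hyper = (vals - mean >= cfg.delta) & (mean < cfg.hyper_normal_max)
        hypo = (mean - vals >= cfg.delta) & (mean > cfg.hypo_normal_min)
    flags = np.zeros(vals.shape, dtype=np.int8)
    flags[hyper] = HYPER
    flags[hypo] = HYPO
    return DifferentialCalls(
        pd.DataFrame(flags, index=beta.index, columns=beta.columns), cfg
    )


def recurrence_filter(
    calls: DifferentialCalls,
    min_frac: float,
    apply_to: tuple[str, ...] = ("hyper", "hypo"),
) -> DifferentialCalls:
    """Clear flags at probes whose flagged-tumor fraction is not > min_frac.

    Applied separately per flag type; a strict ``>`` is required to keep a
    probe.  The rule is usually motivated for hypermethylated probes; it is
    applied symmetrically to hypomethylated probes by default, since the same
    atypical-sample argument holds (restrict ``apply_to`` to turn that off).
    """
    if not 0 < min_frac < 1:
        raise ValueError("min_frac must be in (0, 1)")
    flags = calls.flags.to_numpy().copy()
    n_samples = flags.shape[1]
    if "hyper" in apply_to:
        frac = (flags == HYPER).sum(axis=1) / n_samples
        flags[(frac <= min_frac), :] = np.where(
            flags[(frac <= min_frac), :] == HYPER, NONE, flags[(frac <= min_frac), :]
        )
    if "hypo" in apply_to:
        frac = (flags == HYPO).sum(axis=1) / n_samples
        flags[(frac <= min_frac), :] = np.where(
            flags[(frac <= min_frac), :] == HYPO, NONE, flags[(frac <= min_frac), :]
        )
    return DifferentialCalls(
        pd.DataFrame(flags, index=calls.flags.index, columns=calls.flags.columns),
        calls.config,
        recurrence_frac=min_frac,
    )


def burden(calls: DifferentialCalls) -> pd.DataFrame:
    """Per-sample (N_hyper, N_hypo) counts."""
    return pd.DataFrame({
        "N_hyper": (calls.flags == HYPER).sum(axis=0).astype(int),
        "N_hypo": (calls.flags == HYPO).sum(axis=0).astype(int),
    })


def global_hypo_metric(
    tumors: BetaMatrix,
    calls: DifferentialCalls | None = None,
    mode: str = "count",
    panel: list[str] | None = None,
) -> pd.Series:
    """Per-sample global-hypomethylation proxy.

    ``count`` returns N_hypo (needs ``calls``); ``panel_mean`` the mean beta
    over a hypomethylation-prone probe panel (lower = more maintenance loss).
    """
    if mode == "count":
        if calls is None:
            raise ValueError("mode='count' requires differential calls")
        return burden(calls)["N_hypo"].rename("global_hypo")
    if mode == "panel_mean":
        if not panel:
            raise ValueError("mode='panel_mean' requires a probe panel")
        present = tumors.probe_ids.intersection(panel)
        if present.empty:
            raise ValueError("no panel probes present in the matrix")
        if len(present) < len(panel):
            logger.info("%d panel probes absent from the matrix", len(panel) - len(present))
        return tumors.data.loc[present].mean(axis=0, skipna=True).rename("global_hypo")
    raise ValueError(f"unknown mode {mode!r}")
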