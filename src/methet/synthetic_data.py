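"""Synthetic cohorts, bisulfite reads, survival endpoints and cfDNA panels.

Every generator here produces data with the statistical structure the
downstream analyses assume, together with a truth table, so that each stage
of the pipeline can be tested against known ground truth:

* :func:`synth_cohort` — purity-mixed beta matrices with planted hyper- and
  hypomethylation probe sets and per-sample latent epi-mutation burdens
  (``observed = purity * pure_tumor + (1 - purity) * normal + noise``);
* :func:`synth_reads` — region-level bisulfite reads whose epi-allele
  completeness degrades with a per-CpG maintenance-loss probability;
* :func:`synth_survival` — exponential event/censoring times tied to a
  two-group burden label through a hazard ratio;
* :func:`synth_cfdna` — plasma marker-panel signals for cancer vs non-cancer
  samples scaling with circulating tumor fraction.

All generators are deterministic given their spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BetaMatrix, Region, RegionSet

#: burden patterns: N1 = predominantly high-epi-mutation samples; N2/N3 mix
#: in 30% / 70% low-epi-mutation samples.
PATTERN_LOW_FRAC = {"N1": 0.0, "N2": 0.3, "N3": 0.7}

# low-burden subpopulation: truncated normal around 10% of the high-burden
# mean with an SD of 5% of that mean
_LOW_BURDEN_MEAN_FRAC = 0.10
_LOW_BURDEN_SD_FRAC = 0.05


def _truncnorm_nonneg(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if sd <= 0:
        return np.full(size, max(mean, 0.0))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


# ---------------------------------------------------------------------------
# Array cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Conditions for a simulated tumor/normal 450K-style cohort.

    ``burden_range`` bounds the latent per-sample burden multiplier ``b`` of
    high-epi-mutation samples; a planted probe is active in a sample with
    probability ``b``, so ``b`` scales the fraction of the planted set that
    sample carries.  ``negative_coupling`` is the Gaussian-copula correlation
    between a sample's hyper and hypo multipliers (``-1`` makes them exactly
    antitone).  Observed values are ``purity * pure + (1 - purity) * normal``
    plus truncated-Gaussian noise, clipped to [0, 1].
    """

    n_tumor: int = 100
    n_normal: int = 20
    n_probes: int = 2000
    frac_hyper_probes: float = 0.25
    frac_hypo_probes: float = 0.25
    effect_hyper: float = 0.4
    effect_hypo: float = 0.4
    purity_dist: tuple[float, float] = (0.1, 1.0)
    burden_pattern: str = "N1"
    frac_low_epimut: float | None = None  # default set by pattern
    burden_range: tuple[float, float] = (0.3, 1.0)
    noise_sd: float = 0.02
    negative_coupling: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_hyper_probes", "frac_hypo_probes"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_hyper_probes + self.frac_hypo_probes > 1:
            raise ValueError("planted probe fractions exceed 1")
        if self.burden_pattern not in PATTERN_LOW_FRAC:
            raise ValueError(f"unknown burden pattern {self.burden_pattern!r}")
        if self.frac_low_epimut is None:
            self.frac_low_epimut = PATTERN_LOW_FRAC[self.burden_pattern]
        if not 0 <= self.frac_low_epimut <= 1:
            raise ValueError("frac_low_epimut must be in [0, 1]")
        lo, hi = self.purity_dist
        if not (0 <= lo <= hi <= 1):
            raise ValueError("purity_dist bounds must satisfy 0 <= low <= high <= 1")
        if not -1 <= self.negative_coupling <= 0:
            raise ValueError("negative_coupling must be in [-1, 0]")
        # hyperable normal means reach 0.25 and hypoable means fall to 0.75,
        # so shifts beyond 0.75 would leave [0, 1] before clipping
        if not 0 <= self.effect_hyper <= 0.75:
            raise ValueError("effect_hyper infeasible: planted value would leave [0, 1]")
        if not 0 <= self.effect_hypo <= 0.75:
            raise ValueError("effect_hypo infeasible: planted value would leave [0, 1]")


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort.

    ``samples`` carries per-sample latent state (b_hyper, b_hypo, purity,
    subtype); ``probes`` the planted probe classes and normal means;
    ``expected_calls`` the noise-free differential-call truth (+1 hyper,
    -1 hypo, 0 none) under the standard thresholds; ``n_hyper_true`` /
    ``n_hypo_true`` its per-sample column sums.
    """

    samples: pd.DataFrame
    probes: pd.DataFrame
    expected_calls: pd.DataFrame

    @property
    def n_hyper_true(self) -> pd.Series:
        return (self.expected_calls == 1).sum(axis=0).rename("n_hyper_true")

    @property
    def n_hypo_true(self) -> pd.Series:
        return (self.expected_calls == -1).sum(axis=0).rename("n_hypo_true")


def _coupled_burdens(
    rng: np.random.Generator, n: int, rho: float, lo: float, hi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-copula pair of burden multipliers on [lo, hi] with coupling rho."""
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
    u1, u2 = stats.norm.cdf(z1), stats.norm.cdf(z2)
    return lo + u1 * (hi - lo), lo + u2 * (hi - lo)


def synth_cohort(spec: CohortSpec) -> tuple[BetaMatrix, BetaMatrix, pd.DataFrame, CohortTruth]:
    """Simulate (tumors, normals, sample table, truth) for one cohort.

    Normal probe means are bimodal: hyperable probes low (U(0.05, 0.25)),
    hypoable probes high (U(0.75, 0.95)), the rest spread over U(0.05, 0.95).
    The observed deviation of an active planted probe from the normal mean is
    ``purity * effect`` before noise.
    """
    rng = np.random.default_rng(spec.seed)
    n_hyper = int(round(spec.frac_hyper_probes * spec.n_probes))
    n_hypo = int(round(spec.frac_hypo_probes * spec.n_probes))
    n_rest = spec.n_probes - n_hyper - n_hypo

    probe_ids = pd.Index([f"cg{i:06d}" for i in range(spec.n_probes)], name="probe_id")
    planted = np.array(["hyper"] * n_hyper + ["hypo"] * n_hypo + ["none"] * n_rest)
    normal_mean = np.concatenate([
        rng.uniform(0.05, 0.25, n_hyper),
        rng.uniform(0.75, 0.95, n_hypo),
        rng.uniform(0.05, 0.95, n_rest),
    ])

    tumor_ids = pd.Index([f"T{i:04d}" for i in range(spec.n_tumor)], name="sample_id")
    normal_ids = pd.Index([f"N{i:04d}" for i in range(spec.n_normal)], name="sample_id")

    # latent per-sample burden multipliers
    n_low = int(round(spec.frac_low_epimut * spec.n_tumor))
    subtype = np.array(["low"] * n_low + ["high"] * (spec.n_tumor - n_low))
    subtype = subtype[rng.permutation(spec.n_tumor)]
    is_high = subtype == "high"
    b_hyper = np.zeros(spec.n_tumor)
    b_hypo = np.zeros(spec.n_tumor)
    lo_b, hi_b = spec.burden_range
    b_hyper[is_high], b_hypo[is_high] = _coupled_burdens(
        rng, int(is_high.sum()), spec.negative_coupling, lo_b, hi_b
    )
    mean_high = 0.5 * (lo_b + hi_b)
    n_lo = int((~is_high).sum())
    b_hyper[~is_high] = _truncnorm_nonneg(
        rng, _LOW_BURDEN_MEAN_FRAC * mean_high, _LOW_BURDEN_SD_FRAC * mean_high, n_lo
    )
    b_hypo[~is_high] = _truncnorm_nonneg(
        rng, _LOW_BURDEN_MEAN_FRAC * mean_high, _LOW_BURDEN_SD_FRAC * mean_high, n_lo
    )
    np.clip(b_hyper, 0.0, 1.0, out=b_hyper)
    np.clip(b_hypo, 0.0, 1.0, out=b_hypo)

    purity = rng.uniform(spec.purity_dist[0], spec.purity_dist[1], spec.n_tumor)

    # per (probe, sample) activation of planted effects
    active = np.zeros((spec.n_probes, spec.n_tumor), dtype=bool)
    hyper_rows = planted == "hyper"
    hypo_rows = planted == "hypo"
    active[hyper_rows] = rng.random((n_hyper, spec.n_tumor)) < b_hyper
    active[hypo_rows] = rng.random((n_hypo, spec.n_tumor)) < b_hypo

    pure = np.tile(normal_mean[:, None], (1, spec.n_tumor))
    pure[hyper_rows] += spec.effect_hyper * active[hyper_rows]
    pure[hypo_rows] -= spec.effect_hypo * active[hypo_rows]

    observed = purity[None, :] * pure + (1 - purity[None, :]) * normal_mean[:, None]
    if spec.noise_sd > 0:
        observed = observed + rng.normal(0, spec.noise_sd, observed.shape)
    observed = np.clip(observed, 0.0, 1.0)

    normals = np.tile(normal_mean[:, None], (1, spec.n_normal))
    if spec.noise_sd > 0:
        normals = normals + rng.normal(0, spec.noise_sd, normals.shape)
    normals = np.clip(normals, 0.0, 1.0)

    probe_meta = pd.DataFrame({"planted": planted, "normal_mean": normal_mean}, index=probe_ids)
    tumors = BetaMatrix(pd.DataFrame(observed, index=probe_ids, columns=tumor_ids), probe_meta)
    normals_bm = BetaMatrix(
        pd.DataFrame(normals, index=probe_ids, columns=normal_ids), probe_meta
    )

    samples = pd.DataFrame(
        {"purity": purity, "cancer_type": "SIM", "subtype": subtype,
         "b_hyper": b_hyper, "b_hypo": b_hypo},
        index=tumor_ids,
    )

    # noise-free call truth under the standard thresholds (delta 0.2,
    # normal mean < 0.3 for hyper / > 0.7 for hypo)
    deviation_hyper = purity[None, :] * spec.effect_hyper
    deviation_hypo = purity[None, :] * spec.effect_hypo
    exp = np.zeros((spec.n_probes, spec.n_tumor), dtype=np.int8)
    exp[hyper_rows] = np.where(
        active[hyper_rows]
        & (deviation_hyper >= 0.2)
        & (normal_mean[hyper_rows, None] < 0.3),
        1, 0,
    )
    exp[hypo_rows] = np.where(
        active[hypo_rows]
        & (deviation_hypo >= 0.2)
        & (normal_mean[hypo_rows, None] > 0.7),
        -1, 0,
    )
    truth = CohortTruth(
        samples=samples.copy(),
        probes=probe_meta,
        expected_calls=pd.DataFrame(exp, index=probe_ids, columns=tumor_ids),
    )
    return tumors, normals_bm, samples, truth


# ---------------------------------------------------------------------------
# Bisulfite reads
# ---------------------------------------------------------------------------


@dataclass
class ReadSimSpec:
    """Conditions for simulated region-level bisulfite reads.

    ``maintenance_loss`` is the per-CpG probability that a CpG on a
    methylated-origin allele has lost its methylation (independent per CpG),
    emulating incomplete maintenance after replication;
    ``background_unmeth_frac`` is the fraction of reads drawn from fully
    unmethylated alleles.
    """

    n_regions: int = 4
    reads_per_region: int = 1000
    cpgs_per_read: int = 10
    maintenance_loss: float = 0.1
    background_unmeth_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.maintenance_loss <= 1:
            raise ValueError("maintenance_loss must be in [0, 1]")
        if not 0 <= self.background_unmeth_frac <= 1:
            raise ValueError("background_unmeth_frac must be in [0, 1]")
        if self.cpgs_per_read < 1 or self.reads_per_region < 1 or self.n_regions < 1:
            raise ValueError("counts must be >= 1")


_CPG_SPACING = 10  # reference bp between planted CpGs
_REGION_PITCH = 1000  # reference bp between region starts


def synth_reads(spec: ReadSimSpec) -> tuple[str, RegionSet, list[tuple[int, int]]]:
    """Simulate Bismark-dialect SAM text plus region set and per-read truth.

    Each region carries ``cpgs_per_read`` CpGs at fixed reference offsets and
    every read spans all of them.  A fraction ``1 - background_unmeth_frac``
    of reads starts fully methylated and each CpG then flips unmethylated
    independently with probability ``maintenance_loss``; the remainder are
    fully unmethylated alleles.  Truth is the list of (n_cpg, n_meth) in
    emission order.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.cpgs_per_read
    read_len = _CPG_SPACING * (k - 1) + 2  # ends with the CG dinucleotide
    chrom = "chrS"

    regions = []
    for r in range(spec.n_regions):
        start = 100 + r * _REGION_PITCH
        regions.append(Region(chrom, start, start + read_len, f"CGI_{r:03d}"))
    region_set = RegionSet(regions)

    seq = ["A"] * read_len
    for j in range(k):
        seq[j * _CPG_SPACING] = "C"
        seq[j * _CPG_SPACING + 1] = "G"
    seq = "".join(seq)

    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{chrom}\tLN:{100 + spec.n_regions * _REGION_PITCH + read_len}",
        "@PG\tID:methet\tPN:methet",
    ]
    truth: list[tuple[int, int]] = []
    for region in region_set:
        n_reads = spec.reads_per_region
        from_meth = rng.random(n_reads) >= spec.background_unmeth_frac
        flips = rng.random((n_reads, k)) < spec.maintenance_loss
        meth = from_meth[:, None] & ~flips  # CpG-level methylation state
        for i in range(n_reads):
            xm = ["."] * read_len
            for j in range(k):
                xm[j * _CPG_SPACING] = "Z" if meth[i, j] else "z"
            truth.append((k, int(meth[i].sum())))
            lines.append(
                "\t".join([
                    f"{region.region_id}_read{i:06d}", "0", chrom,
                    str(region.start + 1), "42", f"{read_len}M", "*", "0", "0",
                    seq, "*", f"XM:Z:{''.join(xm)}",
                ])
            )
    return "\n".join(lines) + "\n", region_set, truth


# ---------------------------------------------------------------------------
# Survival endpoints
# ---------------------------------------------------------------------------


def synth_survival(
    burden_labels: Sequence[str],
    hazard_ratio: float,
    baseline_rate: float = 1e-3,
    censor_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival times for a two-group burden labelling.

    Samples labelled ``"HighEpiMut"`` get event rate
    ``baseline_rate * hazard_ratio``; everything else the baseline rate.
    Censoring is an independent exponential clock (``censor_rate == 0``
    disables it); ``event = 1`` iff the event precedes censoring.
    """
    if baseline_rate <= 0 or hazard_ratio <= 0:
        raise ValueError("rates and hazard ratio must be positive")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    rng = np.random.default_rng(seed)
    labels = np.asarray(burden_labels)
    rate = np.where(labels == "HighEpiMut", baseline_rate * hazard_ratio, baseline_rate)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=len(labels))
    else:
        t_cens = np.full(len(labels), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if isinstance(burden_labels, pd.Series):
        return pd.DataFrame({"time": time, "event": event}, index=burden_labels.index)
    return pd.DataFrame({"time": time, "event": event})


# ---------------------------------------------------------------------------
# cfDNA marker panels
# ---------------------------------------------------------------------------


def synth_cfdna(
    n_cancer: int,
    n_control: int,
    panel_hyper_size: int,
    panel_hypo_size: int,
    tumor_fraction_dist: float | tuple[float, float] = (0.01, 0.1),
    noise_sd: float = 0.02,
    seed: int = 0,
    frac_high_maintenance_loss: float = 0.0,
    hyper_attenuation: float = 0.8,
    baseline_maintenance_loss: float = 0.2,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Simulate plasma methylation signals over hyper and hypo marker panels.

    Controls sit at marker baselines (hyper markers low, hypo markers high);
    cancer samples shift each marker proportionally to their circulating
    tumor fraction, with additive truncated-Gaussian noise.  Each cancer
    sample carries a maintenance-loss level ``l`` (1 for the
    ``frac_high_maintenance_loss`` subset, ``baseline_maintenance_loss``
    otherwise): the hypermethylation shift scales with
    ``1 - hyper_attenuation * l`` (maintenance loss erodes hypermethylated
    epi-alleles) while the hypomethylation shift scales with ``l`` itself
    (global hypomethylation is the readout of maintenance loss) — so each
    panel is blind to the tumors the other one sees.  Returns
    (signal samples x markers, labels 1=cancer/0=control,
    {"hyper": ids, "hypo": ids}).
    """
    if min(n_cancer, n_control, panel_hyper_size, panel_hypo_size) < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    hyper_ids = [f"mh{i:03d}" for i in range(panel_hyper_size)]
    hypo_ids = [f"ml{i:03d}" for i in range(panel_hypo_size)]
    base_hyper = rng.uniform(0.02, 0.08, panel_hyper_size)
    base_hypo = rng.uniform(0.85, 0.95, panel_hypo_size)
    high_hyper = rng.uniform(0.7, 0.9, panel_hyper_size)   # fully-tumor level
    low_hypo = rng.uniform(0.1, 0.3, panel_hypo_size)

    if np.isscalar(tumor_fraction_dist):
        tf = np.full(n_cancer, float(tumor_fraction_dist))
    else:
        tf = rng.uniform(tumor_fraction_dist[0], tumor_fraction_dist[1], n_cancer)
    affected = rng.random(n_cancer) < frac_high_maintenance_loss
    loss_level = np.where(affected, 1.0, baseline_maintenance_loss)
    hyper_scale = 1.0 - hyper_attenuation * loss_level

    n = n_cancer + n_control
    sig_hyper = np.tile(base_hyper, (n, 1)).astype(float)
    sig_hypo = np.tile(base_hypo, (n, 1)).astype(float)
    sig_hyper[:n_cancer] += (tf * hyper_scale)[:, None] * (high_hyper - base_hyper)[None, :]
    sig_hypo[:n_cancer] -= (tf * loss_level)[:, None] * (base_hypo - low_hypo)[None, :]
    signal = np.hstack([sig_hyper, sig_hypo])
    if noise_sd > 0:
        signal = signal + rng.normal(0, noise_sd, signal.shape)
    signal = np.clip(signal, 0.0, 1.0)

    sample_ids = [f"C{i:04d}" for i in range(n_cancer)] + [
        f"H{i:04d}" for i in range(n_control)
    ]
    signal_df = pd.DataFrame(signal, index=pd.Index(sample_ids, name="sample_id"),
                             columns=hyper_ids + hypo_ids)
    labels = pd.Series([1] * n_cancer + [0] * n_control, index=signal_df.index, name="cancer")
    return signal_df, labels, {"hyper": hyper_ids, "hypo": hypo_ids}
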