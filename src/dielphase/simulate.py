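"""Synthetic data generators for every pipeline stage.

Each generator inverts the model its downstream estimator assumes, so that
noiseless output is exactly recoverable and noisy output carries a known
planted truth:

* growth curves: exponential OD720, optionally with a logistic approach to a
  saturation density, with multiplicative log-normal noise;
* diel TPM matrices: planted Class I / Class II / noncircadian structure on
  the log2(TPM+1) scale with additive Gaussian replicate noise (log-normal on
  TPM), and an "inverted" mode that suppresses nighttime expression of
  Class II genes so their phase flips to dusk, as observed in clock-perturbed
  strains;
* paired repression profiles with a planted Pearson correlation;
* single-cell reporter traces: cosine + linear trend + Gaussian noise, with a
  controllable arrhythmic fraction and per-cell phase jitter emulating a
  presynchronized population.

All generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .compare import RepressionProfile
from .errors import InvalidInputError
from .growth import GrowthCurve
from .matrix import TIMEPOINTS, DielMatrix, build_matrix
from .rhythm import TraceSet

CLASSES = ("I", "II", "NC")
# distinct substream tags so one master seed can drive all generators
_STREAMS = {"growth": 1, "diel": 2, "profiles": 3, "traces": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a planted diel TPM matrix.

    Defaults reproduce the scale of a real diel transcriptome: 2159 Class I,
    428 Class II and 128 noncircadian genes, a 2.0 log2-unit dusk-dawn
    separation, replicate noise SD 0.25 on the log2 scale, baselines
    log-uniform over [2, 12] (TPM ~ 3 to 4000), three replicates.
    """

    seed: int = 0
    n_genes_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"I": 2159, "II": 428, "NC": 128}
    )
    amplitude_log2: float = 2.0
    noise_sd_log2: float = 0.25
    baseline_log2_range: tuple[float, float] = (2.0, 12.0)
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if any(c not in CLASSES for c in self.n_genes_per_class):
            raise InvalidInputError(f"classes must be among {CLASSES}")
        if any(v < 0 for v in self.n_genes_per_class.values()):
            raise InvalidInputError("gene counts must be nonnegative")
        if sum(self.n_genes_per_class.values()) == 0:
            raise InvalidInputError("at least one gene must be generated")
        if self.amplitude_log2 <= 0:
            raise InvalidInputError("amplitude_log2 must be positive")
        if self.noise_sd_log2 < 0:
            raise InvalidInputError("noise_sd_log2 must be nonnegative")
        if self.n_replicates < 2:
            raise InvalidInputError("n_replicates must be >= 2")
        lo, hi = self.baseline_log2_range
        if not hi > lo:
            raise InvalidInputError("baseline_log2_range must be a proper interval")


def gen_growth_curve(
    kprime: float,
    od0: float,
    t_grid: np.ndarray,
    saturation_od: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GrowthCurve:
    """Exponential (optionally saturating) OD720 curve.

    Without saturation, OD(t) = od0 * exp(K' t) exactly. With a saturation
    density S the curve is logistic, OD(t) = S / (1 + ((S - od0)/od0) e^{-K't}),
    which reduces to the exponential as S -> inf. ``noise_sd`` is the SD of
    multiplicative log-normal noise on OD (0.01 ~ 1% of OD).
    """
    if not od0 > 0:
        raise InvalidInputError("od0 must be positive")
    t = np.asarray(t_grid, dtype=float)
    if len(t) and not np.all(np.diff(t) > 0):
        raise InvalidInputError("t_grid must be strictly increasing")
    if saturation_od is None:
        od = od0 * np.exp(kprime * t)
    else:
        s = float(saturation_od)
        if not s > od0:
            raise InvalidInputError("saturation_od must exceed od0")
        od = s / (1.0 + ((s - od0) / od0) * np.exp(-kprime * t))
    if noise_sd > 0:
        od = od * np.exp(_rng(seed, "growth").normal(0.0, noise_sd, size=len(t)))
    return GrowthCurve(time=t, od720=od)


def gen_diel_matrix(
    cfg: SimConfig,
    mode: str = "wt",
    condition: str | None = None,
) -> tuple[DielMatrix, pd.DataFrame]:
    """Diel TPM matrix with planted class structure plus its truth table.

    Noise-free planted levels on log2(TPM+1), per gene with baseline b:

    =======  ==================  ==================
    class    dusk3 / dusk4       dawn4
    =======  ==================  ==================
    I        b + amplitude       b
    II       b                   b + amplitude
    NC       b                   b
    =======  ==================  ==================

    ``mode="inverted"`` suppresses the nighttime (dawn-peaking) expression of
    Class II genes, planting dawn = b - amplitude so every Class II gene
    becomes dusk-peaked, the inversion signature of clock-output mutants.

    The truth table has one row per gene: ``true_class``, the signed planted
    amplitude (dusk minus dawn), the planted standardized amplitude
    ``true_z`` (|amplitude| over the SE implied by the configured noise SD),
    and an ``inverted`` flag.
    """
    if mode not in ("wt", "inverted"):
        raise InvalidInputError("mode must be 'wt' or 'inverted'")
    counts = {c: int(cfg.n_genes_per_class.get(c, 0)) for c in CLASSES}
    n_total = sum(counts.values())
    rng = _rng(cfg.seed, "diel")
    lo, hi = cfg.baseline_log2_range
    R = cfg.n_replicates

    gene_ids, classes = [], []
    for c in CLASSES:
        for k in range(counts[c]):
            gene_ids.append(f"g{c}_{k:05d}")
            classes.append(c)
    classes = np.array(classes)
    baselines = rng.uniform(lo, hi, size=n_total)

    levels = np.tile(baselines[:, None], (1, len(TIMEPOINTS)))  # (genes, [dusk3,dawn4,dusk4])
    amp = cfg.amplitude_log2
    is1, is2 = classes == "I", classes == "II"
    levels[is1, 0] += amp
    levels[is1, 2] += amp
    inverted_flag = np.zeros(n_total, dtype=bool)
    if mode == "wt":
        levels[is2, 1] += amp
    else:
        levels[is2, 1] -= amp          # nighttime expression suppressed below baseline
        inverted_flag[is2] = True

    x = np.repeat(levels[:, :, None], R, axis=2)
    if cfg.noise_sd_log2 > 0:
        x = x + rng.normal(0.0, cfg.noise_sd_log2, size=x.shape)
    x = np.maximum(x, 0.0)
    matrix = build_matrix(x, gene_ids, R, condition=condition or mode)

    planted_amp = np.where(is1, amp, np.where(is2, (amp if mode == "inverted" else -amp), 0.0))
    se = max(cfg.noise_sd_log2, 1e-300) * np.sqrt(3.0 / (2.0 * R))
    truth = pd.DataFrame(
        {
            "true_class": classes,
            "true_amplitude": planted_amp,
            "true_z": np.abs(planted_amp) / se,
            "inverted": inverted_flag,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return matrix, truth


def gen_correlated_profiles(
    n_genes: int,
    rho_target: float,
    spread_log10: float = 0.5,
    seed: int = 0,
) -> tuple[RepressionProfile, RepressionProfile]:
    """Two per-gene repression profiles with planted population correlation.

    Values are bivariate normal with SD ``spread_log10`` on the log10
    repression-fold scale and correlation ``rho_target``; |rho| = 1 yields an
    exactly (anti)collinear pair.
    """
    if n_genes < 3:
        raise InvalidInputError("need at least 3 genes")
    if not -1.0 <= rho_target <= 1.0:
        raise InvalidInputError("rho_target must lie in [-1, 1]")
    rng = _rng(seed, "profiles")
    x = rng.normal(0.0, 1.0, size=n_genes)
    if abs(rho_target) == 1.0:
        y = np.sign(rho_target) * x
    else:
        y = rho_target * x + np.sqrt(1.0 - rho_target**2) * rng.normal(0.0, 1.0, size=n_genes)
    idx = pd.Index([f"g{k:05d}" for k in range(n_genes)], name="gene_id")
    s = spread_log10
    mk = lambda v: RepressionProfile(values=pd.Series(s * v, index=idx), gene_filter="synthetic")
    return mk(x), mk(y)


def gen_trace_set(
    n_cells: int,
    period_h: float = 23.8,
    amplitude: float = 100.0,
    baseline: float = 500.0,
    trend_per_h: float = 0.0,
    noise_sd: float = 5.0,
    frac_arrhythmic: float = 0.0,
    duration_h: float = 72.0,
    dt_h: float = 0.5,
    phase_jitter_sd_h: float = 0.5,
    seed: int = 0,
) -> tuple[TraceSet, pd.DataFrame]:
    """Single-cell fluorescence traces with a planted circadian oscillation.

    Rhythmic cells follow baseline + trend*t + amplitude*cos(2 pi (t - phi)/T)
    plus Gaussian noise, with per-cell phase phi ~ N(0, phase_jitter_sd_h)
    emulating a presynchronized population released into continuous light at
    t = 0 (peak at release, as for a dusk-phased Class I reporter). A fraction
    of cells omit the oscillation entirely. Truth rows carry the planted
    period, amplitude, phase and rhythmic flag per cell.
    """
    if n_cells < 1:
        raise InvalidInputError("need at least one cell")
    if not period_h > 0:
        raise InvalidInputError("period_h must be positive")
    if dt_h >= period_h / 2.0:
        raise InvalidInputError(
            f"sampling interval {dt_h} h undersamples a {period_h} h oscillation"
        )
    if not 0.0 <= frac_arrhythmic <= 1.0:
        raise InvalidInputError("frac_arrhythmic must lie in [0, 1]")
    rng = _rng(seed, "traces")
    t = np.arange(0.0, duration_h + dt_h / 2.0, dt_h)
    n_arr = int(round(frac_arrhythmic * n_cells))
    rhythmic_flags = np.ones(n_cells, dtype=bool)
    rhythmic_flags[:n_arr] = False
    rng.shuffle(rhythmic_flags)

    frames, truth_rows = [], []
    for k in range(n_cells):
        cid = f"cell{k:04d}"
        phi = rng.normal(0.0, phase_jitter_sd_h)
        y = baseline + trend_per_h * t
        if rhythmic_flags[k]:
            y = y + amplitude * np.cos(2.0 * np.pi * (t - phi) / period_h)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=len(t))
        frames.append(pd.DataFrame({"cell_id": cid, "time_h": t, "fluorescence": y}))
        truth_rows.append(
            {
                "cell_id": cid,
                "true_period_h": period_h if rhythmic_flags[k] else np.nan,
                "true_amplitude": amplitude if rhythmic_flags[k] else 0.0,
                "true_phase_h": phi if rhythmic_flags[k] else np.nan,
                "rhythmic": bool(rhythmic_flags[k]),
            }
        )
    ts = TraceSet(
        data=pd.concat(frames, ignore_index=True),
        meta={"duration_h": duration_h, "dt_h": dt_h, "presynchronized": True},
    )
    return ts, pd.DataFrame(truth_rows).set_index("cell_id")


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write a planted-truth table next to its simulated dataset."""
    truth.to_csv(path, sep="\t")
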