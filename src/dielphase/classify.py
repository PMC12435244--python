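"""Diel phase classification from the dusk/dawn/dusk three-timepoint design.

In *S. elongatus*, circadian output genes split into Class I (RpaA-activated,
peaking at dusk) and Class II (RpaA-repressed, peaking at dawn). With samples
taken at dusk of day 3 and dawn and dusk of day 4, each gene's diel amplitude
is summarized on the variance-stabilized log2(TPM + pseudocount) scale as

    A = mean(dusk3 mean, dusk4 mean) - dawn4 mean

so A > 0 marks a dusk peak (Class I phase) and A < 0 a dawn peak (Class II).
The amplitude is standardized by its standard error propagated from the
(empirical-Bayes moderated) pooled within-timepoint replicate SD; genes whose
standardized amplitude exceeds 4 are "strong circadian" (for a ~normal
statistic this corresponds to p < 1e-4, comfortably below the 0.001 used to
restrict attention to strongly rhythmic genes), and genes below a lower
threshold are called noncircadian.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import squeeze_variances
from .errors import InvalidInputError
from .matrix import TIMEPOINTS, DielMatrix

Z_NC_DEFAULT = 2.0
Z_STRONG_DEFAULT = 4.0
VAR_FLOOR_SD = 0.05
CALL_COLUMNS = ("cls", "amplitude", "z_amp", "strong", "low_expression")


def classify_phase(
    m: DielMatrix,
    z_nc: float = Z_NC_DEFAULT,
    z_strong: float = Z_STRONG_DEFAULT,
    pseudocount: float = 1.0,
    min_mean_tpm: float = 1.0,
    var_floor: float = VAR_FLOOR_SD,
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-gene phase class calls.

    Returns a DataFrame indexed by gene_id with columns:

    * ``cls`` in {"I", "II", "NC"}: Class I iff amplitude > 0 and z >= z_nc,
      Class II iff amplitude < 0 and z >= z_nc, NC otherwise;
    * ``amplitude``: signed dusk-minus-dawn contrast on log2(TPM+pseudocount);
    * ``z_amp``: |amplitude| / SE(amplitude), the standardized amplitude;
    * ``strong``: z_amp > z_strong (the 4-SD rule) and not NC;
    * ``low_expression``: mean TPM < ``min_mean_tpm``; such genes are forced
      to NC and never strong (ratios of near-zero TPMs are noise).

    The replicate noise scale is the pooled within-timepoint SD, moderated
    across genes (``moderate=True``) to avoid the heavy t-tails of a
    3-replicate variance estimate; ``var_floor`` guards degenerate
    zero-variance genes (a warning is emitted when it engages).
    """
    if m.n_replicates < 2:
        raise InvalidInputError("classification requires >= 2 replicates per timepoint")
    R = m.n_replicates
    x = {tp: np.log2(m.timepoint_values(tp) + pseudocount) for tp in TIMEPOINTS}
    means = {tp: x[tp].mean(axis=1) for tp in TIMEPOINTS}
    variances = np.column_stack([x[tp].var(axis=1, ddof=1) for tp in TIMEPOINTS])

    amplitude = 0.5 * (means["dusk3"] + means["dusk4"]) - means["dawn4"]

    s2 = variances.mean(axis=1)              # pooled across the three timepoints
    df = len(TIMEPOINTS) * (R - 1)
    if moderate and len(s2) >= 2:
        s2_post, _, _ = squeeze_variances(s2, df)
    else:
        s2_post = s2
    sigma = np.sqrt(np.maximum(s2_post, 0.0))
    floored = sigma < var_floor
    near_zero = s2 <= 1e-20  # numerically zero replicate variance
    if (floored & near_zero).any():
        warnings.warn(
            f"variance floor {var_floor} applied to "
            f"{int((floored & near_zero).sum())} zero-variance genes",
            stacklevel=2,
        )
    sigma = np.maximum(sigma, var_floor)
    # Var(A) = sigma^2 * (1/(4R) + 1/(4R) + 1/R) = sigma^2 * 3/(2R)
    se = sigma * np.sqrt(3.0 / (2.0 * R))
    z = np.abs(amplitude) / se

    mean_tpm = np.mean(
        np.column_stack([m.timepoint_values(tp) for tp in TIMEPOINTS]), axis=1
    )
    low = mean_tpm < min_mean_tpm

    cls = np.where(
        low | (z < z_nc) | (amplitude == 0),
        "NC",
        np.where(amplitude > 0, "I", "II"),
    )
    strong = (z > z_strong) & (cls != "NC")
    return pd.DataFrame(
        {
            "cls": cls,
            "amplitude": amplitude,
            "z_amp": z,
            "strong": strong,
            "low_expression": low,
        },
        index=m.gene_ids,
    )


def strong_circadian_filter(calls: pd.DataFrame, z_threshold: float = Z_STRONG_DEFAULT) -> pd.DataFrame:
    """Retain genes whose standardized amplitude exceeds ``z_threshold``.

    Recomputes the flag from ``z_amp`` so a non-default threshold can be
    applied to existing calls; NC genes are never retained.
    """
    keep = (calls["z_amp"] > z_threshold) & (calls["cls"] != "NC")
    return calls[keep]


def class_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Counts per class in a calls table (zero-filled)."""
    counts = calls["cls"].value_counts()
    return {c: int(counts.get(c, 0)) for c in ("I", "II", "NC")}


@dataclass
class InversionSummary:
    """Phase-inversion accounting between a reference and a test condition."""

    inverted: pd.Series                  # bool per gene (phase flipped vs reference class)
    fraction_class2_inverted: float      # reference Class II genes dusk-peaked in test
    transitions: pd.DataFrame            # reference class x test class counts


def phase_inversion(calls_ref: pd.DataFrame, calls_test: pd.DataFrame) -> InversionSummary:
    """Detect phase inversions of reference-classified genes in a test condition.

    A reference Class II (dawn-peaked) gene is inverted iff its amplitude in
    the test condition is positive (dusk-peaked); symmetrically a reference
    Class I gene is inverted iff its test amplitude is negative. The headline
    fraction is over reference Class II genes, the class whose nighttime
    expression collapses in clock-perturbed strains.
    """
    if set(calls_ref.index) != set(calls_test.index):
        raise InvalidInputError("call sets cover different gene universes")
    test = calls_test.loc[calls_ref.index]
    ref_cls = calls_ref["cls"]
    inverted = pd.Series(False, index=calls_ref.index)
    inverted[(ref_cls == "II") & (test["amplitude"] > 0)] = True
    inverted[(ref_cls == "I") & (test["amplitude"] < 0)] = True
    class2 = ref_cls == "II"
    frac = float((test.loc[class2, "amplitude"] > 0).mean()) if class2.any() else float("nan")
    transitions = (
        pd.crosstab(ref_cls, test["cls"])
        .reindex(index=["I", "II", "NC"], columns=["I", "II", "NC"], fill_value=0)
        .rename_axis(index="reference", columns="test")
    )
    return InversionSummary(
        inverted=inverted,
        fraction_class2_inverted=frac,
        transitions=transitions,
    )


def dawn_dusk_scatter(m: DielMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Dawn/dusk reproducibility scatter coordinates on the log10 TPM scale.

    For each gene, x is the day-3 dusk mean and the two y values are the day-4
    dusk and dawn means (all log10(TPM + pseudocount)). Sequential dusk points
    should hug the diagonal; Class I genes place their dawn point below it,
    Class II above. The dusk-dusk deviation |y_dusk4 - x| scores replicate-day
    reproducibility.
    """
    tm = m.timepoint_means()
    lg = np.log10(tm + pseudocount)

    def side(y, x):
        return np.where(y > x, "above", np.where(y < x, "below", "on"))

    return pd.DataFrame(
        {
            "dusk3": lg["dusk3"],
            "dawn4": lg["dawn4"],
            "dusk4": lg["dusk4"],
            "dawn_side": side(lg["dawn4"], lg["dusk3"]),
            "dusk_side": side(lg["dusk4"], lg["dusk3"]),
            "dusk_dev": (lg["dusk4"] - lg["dusk3"]).abs(),
        },
        index=m.gene_ids,
    )
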