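"""End-to-end orchestration: simulate -> analyse -> report.

A run is described by a flat YAML mapping (seed, thresholds, simulation
scale, optional external input paths). Every stage writes its tables under
the output directory and contributes a section to a single ``report.json``;
the report is deterministic for a fixed config (no timestamps), and carries
provenance (seed, config hash, package version).
"""
from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import yaml

from ._version import __version__
from .classify import class_counts, classify_phase, phase_inversion
from .compare import correlate_profiles, top_repressed
from .errors import ConfigError
from .growth import GrowthCurve, fit_growth_rate, percent_rate_increase
from .matrix import DielMatrix
from .rhythm import TraceSet, population_rhythm
from .simulate import (
    SimConfig,
    gen_correlated_profiles,
    gen_diel_matrix,
    gen_growth_curve,
    gen_trace_set,
    write_truth,
)

ALL_STAGES = ("simulate", "growth", "classify", "rhythm", "compare")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": "all",
    # simulation scale (kept modest so a demo run takes seconds)
    "n_class1": 300,
    "n_class2": 80,
    "n_nc": 40,
    "amplitude_log2": 2.0,
    "noise_sd_log2": 0.1,
    "n_replicates": 3,
    "n_cells": 15,
    "trace_period_h": 23.8,
    "rho_target": 0.89,
    "n_profile_genes": 2500,
    # analysis thresholds
    "z_nc": 2.0,
    "z_strong": 4.0,
    "pseudocount": 1.0,
    "min_mean_tpm": 1.0,
    # reference doubling times used for the demo growth curves (hours)
    "ref_doubling_h": 12.07,
    "test_kprime": 0.4332,
}

_PATH_KEYS = ("matrix_ref", "matrix_test", "growth_curve", "traces", "traces_ref")


def load_config(path) -> dict:
    """Load a flat YAML config, merged over defaults; validate paths."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: config must be a flat key-value mapping")
    cfg = {**DEFAULT_CONFIG, **user}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    for key in _PATH_KEYS:
        if key in cfg and cfg[key] is not None and not Path(cfg[key]).exists():
            raise ConfigError(f"config field {key!r} references missing file {cfg[key]!r}")
    for key in ("z_nc", "z_strong", "pseudocount"):
        if not float(cfg.get(key, DEFAULT_CONFIG[key])) > 0:
            raise ConfigError(f"config field {key!r} must be positive")
    stages = cfg.get("stages", "all")
    if stages != "all":
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")


def read_matrix(path, mapping: dict[str, str] | None = None) -> DielMatrix:
    """Read and validate a diel TPM matrix TSV (schema errors name the cell)."""
    return DielMatrix.from_tsv(path, mapping=mapping)


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(cfg: dict, out_dir=None) -> dict:
    """Execute the configured stages and write all outputs plus report.json.

    Synthetic inputs are generated for any stage without an external input
    path; child seeds for each generator are derived deterministically from
    the master seed. Returns the report dictionary.
    """
    cfg = {**DEFAULT_CONFIG, **cfg}
    validate_config(cfg)
    out = Path(out_dir if out_dir is not None else cfg.get("out", "dielphase_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = ALL_STAGES if cfg["stages"] == "all" else tuple(cfg["stages"])
    seed = int(cfg["seed"])
    child = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in
             zip(("diel", "growth", "traces", "profiles"),
                 np.random.SeedSequence(seed).spawn(4))}
    report: dict = {
        "provenance": {
            "seed": seed,
            "config_sha256": _config_hash(cfg),
            "version": __version__,
        },
        "warnings": [],
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # ---------------------------------------------------------- simulate
        sim = SimConfig(
            seed=child["diel"],
            n_genes_per_class={
                "I": int(cfg["n_class1"]), "II": int(cfg["n_class2"]), "NC": int(cfg["n_nc"])
            },
            amplitude_log2=float(cfg["amplitude_log2"]),
            noise_sd_log2=float(cfg["noise_sd_log2"]),
            n_replicates=int(cfg["n_replicates"]),
        )
        if "matrix_ref" in cfg and cfg["matrix_ref"]:
            m_ref = read_matrix(cfg["matrix_ref"])
            truth_ref = None
        else:
            m_ref, truth_ref = gen_diel_matrix(sim, mode="wt", condition="wt")
        if "matrix_test" in cfg and cfg["matrix_test"]:
            m_test = read_matrix(cfg["matrix_test"])
            truth_test = None
        else:
            m_test, truth_test = gen_diel_matrix(sim, mode="inverted", condition="evolved")
        if "simulate" in stages and truth_ref is not None and truth_test is not None:
            m_ref.to_tsv(out / "matrix_wt.tsv")
            m_test.to_tsv(out / "matrix_evolved.tsv")
            write_truth(truth_ref, out / "truth_wt.tsv")
            write_truth(truth_test, out / "truth_evolved.tsv")
            report["simulate"] = {
                "n_genes": m_ref.n_genes,
                "planted_counts": {k: int(v) for k, v in sim.n_genes_per_class.items()},
            }

        # ------------------------------------------------------------ growth
        if "growth" in stages:
            if "growth_curve" in cfg and cfg["growth_curve"]:
                curve_test = GrowthCurve.from_csv(cfg["growth_curve"])
                fit_test = fit_growth_rate(curve_test)
                report["growth"] = {
                    "kprime": fit_test.kprime,
                    "doubling_time_h": fit_test.doubling_time,
                    "r2": fit_test.r_squared,
                }
            else:
                k_ref = float(np.log(2.0) / cfg["ref_doubling_h"])
                k_test = float(cfg["test_kprime"])
                # sample each strain over its own exponential regime
                # (OD720 0.01 -> ~0.5, i.e. ~5.6 doublings), 180 points
                def _grid(k):
                    t_end = np.log(50.0) / k
                    return np.linspace(0.0, t_end, 180)

                curve_ref = gen_growth_curve(k_ref, 0.01, _grid(k_ref),
                                             noise_sd=0.01, seed=child["growth"])
                curve_test = gen_growth_curve(k_test, 0.01, _grid(k_test),
                                              noise_sd=0.01, seed=child["growth"] + 1)
                curve_ref.to_csv(out / "growth_wt.csv")
                curve_test.to_csv(out / "growth_evolved.csv")
                fit_ref = fit_growth_rate(curve_ref)
                fit_test = fit_growth_rate(curve_test)
                fit_ref.to_json(out / "fit_wt.json")
                fit_test.to_json(out / "fit_evolved.json")
                report["growth"] = {
                    "wt": {"kprime": fit_ref.kprime, "doubling_time_h": fit_ref.doubling_time},
                    "evolved": {"kprime": fit_test.kprime,
                                "doubling_time_h": fit_test.doubling_time},
                    "percent_rate_increase": percent_rate_increase(fit_test, fit_ref),
                }

        # ---------------------------------------------------------- classify
        if "classify" in stages:
            kw = dict(
                z_nc=float(cfg["z_nc"]),
                z_strong=float(cfg["z_strong"]),
                pseudocount=float(cfg["pseudocount"]),
                min_mean_tpm=float(cfg["min_mean_tpm"]),
            )
            calls_ref = classify_phase(m_ref, **kw)
            calls_test = classify_phase(m_test, **kw)
            calls_ref.to_csv(out / "calls_wt.tsv", sep="\t", index_label="gene_id")
            calls_test.to_csv(out / "calls_evolved.tsv", sep="\t", index_label="gene_id")
            inv = phase_inversion(calls_ref, calls_test)
            report["classify"] = {
                "counts_wt": class_counts(calls_ref),
                "counts_evolved": class_counts(calls_test),
                "strong_counts_wt": class_counts(calls_ref[calls_ref["strong"]]),
                "fraction_class2_inverted": inv.fraction_class2_inverted,
                "transitions": {
                    f"{a}->{b}": int(inv.transitions.loc[a, b])
                    for a in ("I", "II", "NC") for b in ("I", "II", "NC")
                },
            }

        # ------------------------------------------------------------ rhythm
        if "rhythm" in stages:
            if "traces" in cfg and cfg["traces"]:
                ts = TraceSet.from_csv(cfg["traces"])
                ref_ts = TraceSet.from_csv(cfg["traces_ref"]) if cfg.get("traces_ref") else None
            else:
                ts, truth_tr = gen_trace_set(
                    n_cells=int(cfg["n_cells"]),
                    period_h=float(cfg["trace_period_h"]),
                    seed=child["traces"],
                )
                ref_ts = None
                ts.to_csv(out / "traces_wt.csv")
                write_truth(truth_tr, out / "truth_traces.tsv")
            pop = population_rhythm(ts, ref=ref_ts)
            pop.per_cell.to_csv(out / "rhythm_per_cell.tsv", sep="\t", index=False)
            report["rhythm"] = pop.to_json_dict()

        # ----------------------------------------------------------- compare
        if "compare" in stages:
            p1, p2 = gen_correlated_profiles(
                n_genes=int(cfg["n_profile_genes"]),
                rho_target=float(cfg["rho_target"]),
                seed=child["profiles"],
            )
            p1.to_tsv(out / "profile_test.tsv")
            p2.to_tsv(out / "profile_reference.tsv")
            corr = correlate_profiles(p1, p2)
            top = top_repressed(p1, k=20, check_ref=p2, fold_threshold=5.0)
            top.table.to_csv(out / "top_repressed.tsv", sep="\t", index_label="gene_id")
            report["compare"] = {
                "pearson_r": corr.pearson_r,
                "n_genes": corr.n_genes,
                "top20_all_pass_5fold": top.all_pass,
            }

        report["warnings"] = sorted({str(w.message) for w in caught})

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
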