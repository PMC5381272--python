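"""Configuration-driven orchestration of the full synthetic pipeline.

Stages: simulate (generate every synthetic input), geometry (structural
order parameters, joint histogram, contact profile), msm (timescale table
over the estimator grid, with a glycosylated/non-glycosylated ratio column),
bootstrap (per-bin density comparison of the two conditions), doseresponse
(Hill fits and group comparison), report (run manifest). All randomness is
funnelled through per-stage seeds derived from the single config seed, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import copy
import difflib
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .doseresponse import compare_groups, fit_hill, normalize_curve
from .ensembles import ScalarEnsemble
from .geometry import joint_histogram, select_atoms, contact_fraction, trajectory_order_parameters
from .msm import cluster_features, count_transitions, estimate_transition_matrix, slowest_timescale, tica_timescales
from .stats import pdf_difference_bootstrap
from .structure import write_multimodel_pdb
from .synthetic import (
    DoseResponseSpec,
    ToyGlycoproteinSpec,
    TwoStateSpec,
    generate_dose_response,
    generate_toy_glycoprotein_ensemble,
    generate_two_state_ensemble,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "geometry", "msm", "bootstrap", "doseresponse", "report")

#: Full default configuration; every key a user config may set appears here.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "results",
    "bin_width_nm": 0.1,
    "subunit": "GluN1",
    "conditions": {
        "glycosylated": {
            "relaxation_ns": 333.0,
            "closed_fraction": 0.65,
            "n_traj": 262,
            "n_frames": 2000,
            "dt_ns": 0.2,
            "mean_closed_nm": 3.7,
            "mean_open_nm": 4.7,
            "sd_nm": 0.15,
        },
        "nonglycosylated": {
            "relaxation_ns": 333.0,
            "closed_fraction": 0.50,
            "n_traj": 196,
            "n_frames": 2000,
            "dt_ns": 0.2,
            "mean_closed_nm": 3.7,
            "mean_open_nm": 4.7,
            "sd_nm": 0.15,
        },
    },
    "estimators": {
        "cluster_counts": [99, 6],
        "lags_ns": [256.0, 128.0],
        "tica": True,
        "tica_lag_ns": 256.0,
        "reversible": True,
    },
    "bootstrap": {"n_boot": 1000, "level": 0.95},
    "toy_structure": {
        "n_frames": 200,
        "relaxation_ns": 6.0,
        "n_lobe_atoms": 16,
        "glycan_length": 11,
        "contact_when_closed": 0.8,
        "contact_cutoff_nm": 0.5,
    },
    "doseresponse": {
        "wildtype": {"ec50_uM": 2.28, "hill": 1.4, "n_curves": 12, "noise_sd": 0.03},
        "mutant": {"ec50_uM": 3.43, "hill": 1.4, "n_curves": 12, "noise_sd": 0.03},
    },
}


class ConfigError(ValueError):
    """Carries the exhaustive list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


def _merge(defaults: dict, user: dict, path: str, errors: list[str]) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        if key not in defaults:
            hint = difflib.get_close_matches(str(key), list(defaults), n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown key {path}{key}{suggestion}")
            continue
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                errors.append(f"{path}{key}: expected a mapping")
            else:
                out[key] = _merge(defaults[key], value, f"{path}{key}.", errors)
        else:
            out[key] = value
    return out


def _check_values(cfg: dict, errors: list[str]) -> None:
    if cfg["bin_width_nm"] <= 0:
        errors.append("bin_width_nm: must be positive")
    if not 0 < cfg["bootstrap"]["level"] < 1:
        errors.append("bootstrap.level: must be in (0, 1)")
    if cfg["bootstrap"]["n_boot"] < 1:
        errors.append("bootstrap.n_boot: must be >= 1")
    for lag in cfg["estimators"]["lags_ns"]:
        if lag <= 0:
            errors.append(f"estimators.lags_ns: lag {lag} must be positive")
    for k in cfg["estimators"]["cluster_counts"]:
        if k < 1:
            errors.append(f"estimators.cluster_counts: k {k} must be >= 1")
    for name, cond in cfg["conditions"].items():
        if cond["relaxation_ns"] <= 0:
            errors.append(f"conditions.{name}.relaxation_ns: must be positive")
        if not 0 < cond["closed_fraction"] < 1:
            errors.append(f"conditions.{name}.closed_fraction: must be in (0, 1)")
    for name, grp in cfg["doseresponse"].items():
        if grp["ec50_uM"] <= 0:
            errors.append(f"doseresponse.{name}.ec50_uM: must be positive")


def validate_config(source: str | Path | dict | None = None) -> dict:
    """Normalize a config (path to YAML, a dict, or None for pure defaults).

    All defaults are resolved and echoed in the returned dict; unknown keys
    and invalid values are rejected with an exhaustive error list.
    """
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    errors: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, user, "", errors)
    if not errors:
        _check_values(cfg, errors)
    if errors:
        raise ConfigError(errors)
    return cfg


def _condition_spec(cond: dict, seed: int) -> TwoStateSpec:
    return TwoStateSpec.with_relaxation(
        relaxation_ns=cond["relaxation_ns"],
        closed_fraction=cond["closed_fraction"],
        mean_closed=cond["mean_closed_nm"],
        mean_open=cond["mean_open_nm"],
        sd_closed=cond["sd_nm"],
        sd_open=cond["sd_nm"],
        dt=cond["dt_ns"],
        n_traj=cond["n_traj"],
        n_frames=cond["n_frames"],
        seed=seed,
    )


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _config_hash(cfg: dict) -> str:
    # outdir is excluded: the same analysis in a different directory is the
    # same analysis
    hashed = {k: v for k, v in cfg.items() if k != "outdir"}
    return hashlib.sha256(yaml.safe_dump(hashed, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(
    config: dict | str | Path | None = None,
    stages: tuple[str, ...] = STAGES,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Run the requested stages; returns a dict of in-memory results.

    Deterministic given the config seed. Any stage failure aborts with the
    stage name; outputs written by earlier stages are preserved on disk.
    """
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = seed
    if outdir is not None:
        cfg["outdir"] = str(outdir)
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    base_seed = int(cfg["seed"])
    meta_common = {"config_hash": _config_hash(cfg), "seed": base_seed, "version": __version__}
    results: dict = {"config": cfg}

    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; valid stages: {STAGES}")
        t0 = time.perf_counter()
        logger.info("stage %s: starting", stage)
        try:
            _STAGE_FUNCS[stage](cfg, out, base_seed, meta_common, results)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.1f s", stage, time.perf_counter() - t0)
    return results


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg, out, seed, meta, results):
    ensembles = {}
    for i, (name, cond) in enumerate(sorted(cfg["conditions"].items())):
        spec = _condition_spec(cond, seed + 10 + i)
        ens = generate_two_state_ensemble(spec)
        ens.label = name
        ensembles[name] = (spec, ens)
    results["ensembles"] = ensembles

    toy_cfg = cfg["toy_structure"]
    glyc_spec = ensembles["glycosylated"][0]
    # faster switching for the short structural trajectory so both basins
    # (and the open/contact exclusion) are actually visited
    lam = 1.0 / toy_cfg["relaxation_ns"]
    pc = glyc_spec.closed_fraction
    toy_spec = ToyGlycoproteinSpec.from_two_state(
        glyc_spec.replace(seed=seed + 20, rate_close=lam * pc, rate_open=lam * (1 - pc)),
        n_frames=toy_cfg["n_frames"],
        n_lobe_atoms=toy_cfg["n_lobe_atoms"],
        glycan_length=toy_cfg["glycan_length"],
        contact_when_closed=toy_cfg["contact_when_closed"],
    )
    toy = generate_toy_glycoprotein_ensemble(toy_spec)
    write_multimodel_pdb(toy, out / "toy_glycoprotein.pdb")
    results["toy_trajectory"] = toy

    dr = {}
    for j, (grp, params) in enumerate(sorted(cfg["doseresponse"].items())):
        spec = DoseResponseSpec(
            ec50=params["ec50_uM"],
            hill=params["hill"],
            n_curves=params["n_curves"],
            noise_sd=params["noise_sd"],
            seed=seed + 30 + j,
        )
        dr[grp] = generate_dose_response(spec)
        rows = [
            {"curve_id": c.curve_id, "concentration_uM": conc, "current": cur}
            for c in dr[grp]
            for conc, cur in zip(c.concentrations, c.currents)
        ]
        _write_tsv(pd.DataFrame(rows), out / f"doseresponse_{grp}.tsv", meta)
    results["doseresponse_curves"] = dr


def _stage_geometry(cfg, out, seed, meta, results):
    toy = results.get("toy_trajectory")
    if toy is None:
        raise ValueError("geometry stage needs the simulate stage (or a loaded trajectory)")
    d, dgol = trajectory_order_parameters(toy)
    results["toy_series"] = (d, dgol)

    width = cfg["bin_width_nm"]
    d_edges = np.arange(np.floor(d.min() * 10) / 10, d.max() + width, width)
    dgol_edges = np.arange(0.0, dgol.max() + width, width)
    jh = joint_histogram(d, dgol, d_edges, dgol_edges)
    results["joint_histogram"] = jh
    jh_df = pd.DataFrame(
        jh.counts,
        index=[f"{lo:.2f}" for lo in jh.d_edges[:-1]],
        columns=[f"{lo:.2f}" for lo in jh.dgol_edges[:-1]],
    )
    with open(out / "joint_histogram.tsv", "w") as fh:
        for key, value in {**meta, "overflow": jh.overflow}.items():
            fh.write(f"# {key}={value}\n")
        jh_df.to_csv(fh, sep="\t", index_label="d_bin_lo_nm")

    frame0 = toy.frames[0]
    gly = select_atoms(frame0, chain="G", heavy_only=True)
    lobe = select_atoms(frame0, residue_numbers=set(range(710, 724)), heavy_only=True)
    frac, profile = contact_fraction(toy, gly, lobe, cutoff=cfg["toy_structure"]["contact_cutoff_nm"])
    results["contact_fraction"] = frac
    results["contact_profile"] = profile
    prof = pd.DataFrame(profile.sorted_items(), columns=["residue", "contact_fraction"])
    _write_tsv(prof, out / "contact_profile.tsv", {**meta, "overall_fraction": f"{frac:.4f}", "cutoff_nm": profile.cutoff})


def _stage_msm(cfg, out, seed, meta, results):
    est = cfg["estimators"]
    ensembles = results["ensembles"]
    rows = []
    per_condition: dict[str, dict] = {name: {} for name in ensembles}
    for name, (spec, ens) in sorted(ensembles.items()):
        for k in est["cluster_counts"]:
            _, dtrajs = cluster_features(ens, k=k, seed=seed + 40)
            for lag_ns in est["lags_ns"]:
                lag_frames = int(round(lag_ns / ens.dt))
                cm = count_transitions(dtrajs, lag_frames, dt=ens.dt)
                model = estimate_transition_matrix(cm, reversible=est["reversible"])
                per_condition[name][("MSM", k, lag_ns)] = slowest_timescale(model)
                if ("msm_models" not in results):
                    results["msm_models"] = {}
                results["msm_models"][(name, k, lag_ns)] = (model, dtrajs)
        if est["tica"]:
            lag_frames = int(round(est["tica_lag_ns"] / ens.dt))
            tica = tica_timescales(ens, lag_frames)
            per_condition[name][("tICA", None, est["tica_lag_ns"])] = tica.slowest_timescale

    keys = list(per_condition["glycosylated"])
    for key in keys:
        estimator, k, lag_ns = key
        with_g = per_condition["glycosylated"][key]
        without_g = per_condition["nonglycosylated"].get(key, float("nan"))
        rows.append(
            {
                "estimator": estimator,
                "k": k if k is not None else "",
                "lag_ns": lag_ns,
                "timescale_us_with_glycans": with_g / 1000.0,
                "timescale_us_without": without_g / 1000.0,
                "ratio": with_g / without_g if without_g else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    results["timescale_table"] = table
    _write_tsv(table, out / "timescale_table.tsv", meta)


def _stage_bootstrap(cfg, out, seed, meta, results):
    ens_a = results["ensembles"]["glycosylated"][1]
    ens_b = results["ensembles"]["nonglycosylated"][1]
    boot = pdf_difference_bootstrap(
        ens_a,
        ens_b,
        n_boot=cfg["bootstrap"]["n_boot"],
        level=cfg["bootstrap"]["level"],
        seed=seed + 50,
        bin_width=cfg["bin_width_nm"],
    )
    results["bootstrap"] = boot
    df = pd.DataFrame(
        {
            "bin_lo_nm": boot.bin_edges[:-1],
            "bin_hi_nm": boot.bin_edges[1:],
            "pdf_a": boot.pdf_a,
            "pdf_b": boot.pdf_b,
            "diff": boot.difference,
            "ci_lo": boot.ci_low,
            "ci_hi": boot.ci_high,
            "significant": boot.significant.astype(int),
        }
    )
    _write_tsv(
        df,
        out / "pdf_bootstrap.tsv",
        {**meta, "level": boot.level, "n_boot": boot.n_boot,
         "multiple_testing_correction": boot.multiple_testing_correction},
    )


def _stage_doseresponse(cfg, out, seed, meta, results):
    curves = results["doseresponse_curves"]
    fits = {
        grp: [fit_hill(normalize_curve(c)) for c in grp_curves]
        for grp, grp_curves in sorted(curves.items())
    }
    comparison = compare_groups(fits["wildtype"], fits["mutant"])
    results["hill_fits"] = fits
    results["group_comparison"] = comparison
    summary = pd.DataFrame(
        [
            {"group": "wildtype", "n": comparison.n_a, "mean_ec50_uM": comparison.mean_a, "sem": comparison.sem_a},
            {"group": "mutant", "n": comparison.n_b, "mean_ec50_uM": comparison.mean_b, "sem": comparison.sem_b},
        ]
    )
    summary["percent_change"] = ["", f"{comparison.percent_change:.2f}"]
    summary["t"] = ["", f"{comparison.t_statistic:.3f}"]
    summary["p"] = ["", f"{comparison.p_value:.3g}"]
    _write_tsv(summary, out / "doseresponse_summary.tsv", meta)


def _stage_report(cfg, out, seed, meta, results):
    manifest = {
        "config_hash": meta["config_hash"],
        "seed": seed,
        "version": __version__,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        "config": cfg,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "geometry": _stage_geometry,
    "msm": _stage_msm,
    "bootstrap": _stage_bootstrap,
    "doseresponse": _stage_doseresponse,
    "report": _stage_report,
}
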