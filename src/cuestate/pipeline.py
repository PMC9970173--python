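"""End-to-end orchestration: simulate → preprocess → microstates → statistics.

`run_full` drives the whole chain from one validated configuration
document and writes a deterministic artifact directory. All randomness
flows from the single config seed; re-running with the same config
reproduces byte-identical parameter and report files. There is no
command-line layer: these functions, and the scripts in ``examples/``,
are the interface.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as csio
from .microstate import (
    backfit,
    build_level_templates,
    compute_gev,
    compute_parameters,
    extract_peak_maps,
    modified_kmeans,
    select_k_kl,
)
from .montage import POSTERIOR_DEFAULT
from .preprocess import EEGRecording, posterior_alpha_power, preprocess_recording
from .stats import AnalysisConfig, analyze_cohort
from .synthetic import CONDITIONS, EffectConfig, default_ground_truth, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "PipelineError", "validate_config", "load_config", "run_full"]


DEFAULT_CONFIG: dict = {
    "version": "1",
    "seed": 0,
    "cohort": {
        "n_subjects": 40,
        "n_trials": 4,
        "trial_s": 88.0,
        "srate": 250.0,
        "snr": 3.0,
        "effects": "default",  # "default" | "null"
    },
    "preprocess": {
        "broadband": [0.1, 80.0],
        "microstate_band": [2.0, 20.0],
        "reject_uv": 100.0,
        "target_hz": 250.0,
        "posterior_set": None,  # None -> built-in parieto-occipital nine
    },
    "microstate": {
        "k_mode": "fixed",  # "fixed" | "kl"
        "k": 4,
        "k_range": [2, 8],
        "n_restarts": 20,
        "max_iter": 100,
    },
    "stats": {
        "alpha": 0.05,
        "n_boot": 5000,
        "ci": 0.95,
    },
    "output": {
        "save_recordings": False,
        "save_segmentations": True,
    },
}


class PipelineError(RuntimeError):
    """A pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


def _validate_section(cfg: dict, defaults: dict, prefix: str, errors: list[str]) -> None:
    for key in cfg:
        if key not in defaults:
            errors.append(f"unknown key: {prefix}{key}")
    for key, val in defaults.items():
        if isinstance(val, dict) and key in cfg:
            if isinstance(cfg[key], dict):
                _validate_section(cfg[key], val, f"{prefix}{key}.", errors)
            else:
                errors.append(f"{prefix}{key} must be a mapping")


def validate_config(config) -> list[str]:
    """Validate a config dict or YAML path; returns a list of errors (empty = ok)."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    errors: list[str] = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    _validate_section(config, DEFAULT_CONFIG, "", errors)
    merged = merge_config(config, validate=False)
    co, pp, ms = merged["cohort"], merged["preprocess"], merged["microstate"]
    if co["n_subjects"] < 3:
        errors.append("cohort.n_subjects must be >= 3")
    if co["snr"] <= 0:
        errors.append("cohort.snr must be positive")
    if co["trial_s"] <= 2 or co["n_trials"] < 1:
        errors.append("cohort.trial_s must exceed 2 s and n_trials be >= 1")
    if co["effects"] not in ("default", "null"):
        errors.append("cohort.effects must be 'default' or 'null'")
    lo, hi = pp["broadband"]
    if not 0 <= lo < hi:
        errors.append("preprocess.broadband must satisfy 0 <= low < high")
    if pp["reject_uv"] <= 0:
        errors.append("preprocess.reject_uv must be positive")
    kr = ms["k_range"]
    if len(kr) != 2 or kr[0] < 2 or kr[1] < kr[0]:
        errors.append("microstate.k_range must be [kmin >= 2, kmax >= kmin]")
    if ms["k_mode"] not in ("fixed", "kl"):
        errors.append("microstate.k_mode must be 'fixed' or 'kl'")
    if ms["k"] < 2:
        errors.append("microstate.k must be >= 2")
    if merged["stats"]["n_boot"] < 1:
        errors.append("stats.n_boot must be positive")
    return errors


def merge_config(config: dict | None, validate: bool = True) -> dict:
    """Overlay a (partial) user config on the defaults."""
    merged = copy.deepcopy(DEFAULT_CONFIG)

    def overlay(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                overlay(dst[k], v)
            else:
                dst[k] = v

    if config:
        overlay(merged, config)
    if validate:
        errors = validate_config(merged)
        if errors:
            raise PipelineError("config", "; ".join(errors))
    return merged


def load_config(path) -> dict:
    """Load, validate and merge a YAML config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors = validate_config(raw)
    if errors:
        raise PipelineError("config", "; ".join(errors))
    return merge_config(raw)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_full(config: dict | None = None, out_dir="cuestate_run") -> Path:
    """Run the full pipeline and write the artifact directory.

    Layout: ``recordings/`` (optional), ``templates/``, ``segmentations/``,
    ``params.csv``, ``behaviour.csv``, ``report.json``, ``log.txt``,
    ``config_resolved.yaml``. The current stage is tracked in ``STAGE`` so a
    failed run names where it stopped.
    """
    cfg = merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    log_lines: list[str] = []
    t_start = time.time()

    def log(msg: str) -> None:
        line = f"[{time.time() - t_start:8.1f}s] {msg}"
        logger.info(msg)
        log_lines.append(line)

    def stage(name: str) -> None:
        (out / "STAGE").write_text(name + "\n")
        log(f"stage: {name}")

    (out / "config_resolved.yaml").write_text(
        yaml.safe_dump({**cfg, "config_hash": chash}, sort_keys=True)
    )
    log(f"config hash {chash}, seed {cfg['seed']}")

    try:
        stage("simulate")
        co = cfg["cohort"]
        effects = EffectConfig() if co["effects"] == "default" else EffectConfig.null()
        truth = default_ground_truth(seed=cfg["seed"], snr=co["snr"])
        cohort = generate_cohort(
            n_subjects=co["n_subjects"],
            truth=truth,
            effect_config=effects,
            seed=cfg["seed"],
            n_trials=co["n_trials"],
            trial_s=co["trial_s"],
            srate=co["srate"],
        )
        csio.write_montage(out / "montage.txt", truth.montage)
        if cfg["output"]["save_recordings"]:
            (out / "recordings").mkdir(exist_ok=True)

        stage("preprocess+cluster")
        pp, ms_cfg = cfg["preprocess"], cfg["microstate"]
        select = (1.0, 1.0 + co["trial_s"])
        rng = np.random.default_rng(cfg["seed"] + 1)
        individual_sets: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
        ms_epochs_store: dict[tuple[str, str], object] = {}
        alpha_rows: list[dict] = []
        kl_choices: list[int] = []
        for sp in cohort.subjects:
            for cond in CONDITIONS:
                rec_sim = cohort.recording(sp.subject_id, cond)
                if cfg["output"]["save_recordings"]:
                    csio.write_recording(
                        out / "recordings" / f"{sp.subject_id}_{cond}", rec_sim
                    )
                rec = EEGRecording(
                    data=rec_sim.data,
                    srate=rec_sim.srate,
                    channel_names=truth.montage.names,
                    montage=truth.montage,
                )
                broad, msep = preprocess_recording(
                    rec,
                    rec_sim.onsets_s,
                    broadband=tuple(pp["broadband"]),
                    microstate_band=tuple(pp["microstate_band"]),
                    reject_uv=pp["reject_uv"],
                    target_hz=pp["target_hz"],
                    select=select,
                    context=f"{sp.subject_id}/{cond}",
                )
                alpha = posterior_alpha_power(
                    broad, electrode_set=pp["posterior_set"] or POSTERIOR_DEFAULT
                )
                alpha_rows.append(
                    {
                        "subject": sp.subject_id,
                        "condition": cond,
                        "alpha_power": alpha.power,
                    }
                )
                peak_maps, _ = extract_peak_maps(msep)
                seed_i = int(rng.integers(2**31 - 1))
                if ms_cfg["k_mode"] == "kl":
                    sel_kl = select_k_kl(
                        peak_maps,
                        tuple(ms_cfg["k_range"]),
                        seed=seed_i,
                        n_restarts=ms_cfg["n_restarts"],
                    )
                    k_i = sel_kl.chosen_k
                    kl_choices.append(k_i)
                else:
                    k_i = ms_cfg["k"]
                km = modified_kmeans(
                    peak_maps,
                    k_i,
                    n_restarts=ms_cfg["n_restarts"],
                    max_iter=ms_cfg["max_iter"],
                    seed=seed_i,
                )
                individual_sets[cond].append(km.templates)
                ms_epochs_store[(sp.subject_id, cond)] = msep
                log(
                    f"{sp.subject_id}/{cond}: {msep.n_epochs} epochs kept "
                    f"({int((~msep.kept_mask).sum()) if msep.kept_mask.size else 0} rejected), "
                    f"{peak_maps.shape[0]} peaks, k={k_i}"
                )

        stage("templates")
        # individual sets may disagree on k when k_mode='kl'; harmonise to the
        # modal k by re-clustering the outliers is out of scope — require equal k
        ks = {s.shape[0] for sets in individual_sets.values() for s in sets}
        if len(ks) > 1:
            raise PipelineError(
                "templates",
                f"individual template sets disagree on k ({sorted(ks)}); "
                "use k_mode='fixed' for mixed cohorts",
            )
        cond_sets, overall = build_level_templates(
            individual_sets, montage=truth.montage
        )
        (out / "templates").mkdir(exist_ok=True)
        csio.write_templates(out / "templates" / "overall", overall)
        for cond, ts in cond_sets.items():
            csio.write_templates(out / "templates" / f"condition_{cond}", ts)

        stage("backfit")
        if cfg["output"]["save_segmentations"]:
            (out / "segmentations").mkdir(exist_ok=True)
        rows = []
        for (sid, cond), msep in ms_epochs_store.items():
            seg = backfit(msep, overall)
            par = compute_parameters(
                seg, overall.chosen_k, class_labels=overall.class_labels
            )
            gev = compute_gev(seg, overall)
            for j, cls in enumerate(overall.class_labels):
                rows.append(
                    {
                        "subject": sid,
                        "condition": cond,
                        "class": cls,
                        "duration_ms": par.duration_ms[j],
                        "occurrence_per_s": par.occurrence_per_s[j],
                        "contribution": par.contribution_fraction[j],
                        "gev": gev,
                    }
                )
            if cfg["output"]["save_segmentations"]:
                np.savetxt(
                    out / "segmentations" / f"{sid}_{cond}_labels.txt",
                    seg.labels,
                    fmt="%d",
                )
        params = pd.DataFrame(rows)
        params.to_csv(out / "params.csv", index=False, float_format="%.10g")

        stage("stats")
        behaviour = cohort.behaviour.merge(
            pd.DataFrame(alpha_rows), on=["subject", "condition"]
        )
        behaviour.to_csv(out / "behaviour.csv", index=False, float_format="%.10g")
        st = cfg["stats"]
        report = analyze_cohort(
            params,
            behaviour,
            AnalysisConfig(
                alpha=st["alpha"], n_boot=st["n_boot"], ci=st["ci"], seed=cfg["seed"]
            ),
        )
        report["provenance"] = {
            "config_hash": chash,
            "seed": cfg["seed"],
            "n_subjects": co["n_subjects"],
            "mean_gev": {
                cond: float(params[params["condition"] == cond]["gev"].mean())
                for cond in CONDITIONS
            },
            "kl_chosen_k": kl_choices or None,
        }
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))

        stage("done")
    except PipelineError:
        (out / "log.txt").write_text("\n".join(log_lines) + "\n")
        raise
    except Exception as e:  # tag unexpected failures with the current stage
        (out / "log.txt").write_text("\n".join(log_lines) + "\n")
        current = (out / "STAGE").read_text().strip() if (out / "STAGE").exists() else "?"
        raise PipelineError(current, str(e)) from e
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out
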