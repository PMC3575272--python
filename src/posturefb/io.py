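"""Configuration files and trajectory CSV I/O.

Scenario configs are YAML with sections ``subject``, ``anthropometry``,
``controller``, ``biofeedback``, ``display``, ``perturbation`` and
``simulation``; unknown keys are rejected with their location, missing
optional sections fall back to documented defaults (demo LQR gains,
default biofeedback parameters, display off).  Trajectories are plain
CSV, one header row naming every channel with units; floats are written
at full repr precision so write -> read is exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .anthropometry import SubjectSpec, derive_body_params
from .biofeedback import BiofeedbackParams, DisplayConfig
from .controller import ControllerParams
from .perturbation import PerturbationSpec
from .simulation import Scenario, TRAJECTORY_COLUMNS, Trajectory

__all__ = ["load_scenario", "scenario_to_dict", "save_scenario",
           "write_trajectory", "read_trajectory"]

_SECTIONS = {"subject", "anthropometry", "controller", "biofeedback",
             "display", "perturbation", "simulation"}

_KEYS = {
    "subject": {"height_m", "mass_kg"},
    "controller": {"K_s", "K_c", "t_d_s"},
    "biofeedback": {"tau_f_s", "k_s", "k_c"},
    "display": {"preset", "columns_deg", "rows", "thresholds_deg"},
    "perturbation": {"direction_deg", "displacement_m", "t_accel_s",
                     "t_const_s", "t_decel_s", "onset_s"},
    "simulation": {"dt_s", "horizon_s", "initial_state", "seed"},
}


def _check_keys(section: str, d: dict, allowed: set[str]) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section "
            f"'{section}'")


def scenario_from_dict(cfg: dict) -> Scenario:
    if not isinstance(cfg, dict):
        raise ValueError("scenario config must be a mapping")
    _check_keys("<root>", cfg, _SECTIONS)
    if "subject" not in cfg:
        raise ValueError("config section 'subject' is required")
    sub = cfg["subject"]
    _check_keys("subject", sub, _KEYS["subject"])
    subject = SubjectSpec(height=float(sub["height_m"]),
                          mass=float(sub["mass_kg"]))
    fractions = cfg.get("anthropometry") or None
    body = derive_body_params(subject, fractions)

    c = cfg.get("controller", {})
    _check_keys("controller", c, _KEYS["controller"])
    if "K_s" in c or "K_c" in c:
        controller = ControllerParams(K_s=np.array(c["K_s"], float),
                                      K_c=np.array(c["K_c"], float),
                                      t_d=float(c.get("t_d_s", 0.05)))
    else:
        from .fixtures import demo_controller
        controller = demo_controller(body, t_d=float(c.get("t_d_s", 0.05)))

    b = cfg.get("biofeedback", {})
    _check_keys("biofeedback", b, _KEYS["biofeedback"])
    bio_kw = {}
    if "tau_f_s" in b:
        bio_kw["tau_f"] = float(b["tau_f_s"])
    for key in ("k_s", "k_c"):
        if key in b:
            bio_kw[key] = np.array(b[key], float)
    biofeedback = BiofeedbackParams(**bio_kw)

    d = cfg.get("display", {"preset": "off"})
    _check_keys("display", d, _KEYS["display"])
    if "preset" in d:
        over = {}
        if "columns_deg" in d:
            over["columns"] = tuple(float(v) for v in d["columns_deg"])
        if "rows" in d:
            over["rows"] = int(d["rows"])
        display = DisplayConfig.preset(
            d["preset"],
            thresholds=tuple(float(v) for v in
                             d.get("thresholds_deg", (1.0, 2.0, 3.0))),
            **over)
    else:
        display = DisplayConfig(
            columns=tuple(float(v) for v in d.get("columns_deg", ())),
            rows=int(d.get("rows", 3)),
            thresholds=tuple(float(v) for v in
                             d.get("thresholds_deg", (1.0, 2.0, 3.0))))

    p = cfg.get("perturbation", {})
    _check_keys("perturbation", p, _KEYS["perturbation"])
    pert = PerturbationSpec(
        direction=float(p.get("direction_deg", 180.0)),
        displacement=float(p.get("displacement_m", 0.060)),
        t_accel=float(p.get("t_accel_s", 0.100)),
        t_const=float(p.get("t_const_s", 0.200)),
        t_decel=float(p.get("t_decel_s", 0.100)),
        onset=float(p.get("onset_s", 0.5)))

    s = cfg.get("simulation", {})
    _check_keys("simulation", s, _KEYS["simulation"])
    kw = {}
    if "horizon_s" in s:
        kw["horizon"] = float(s["horizon_s"])
    if "initial_state" in s:
        st = tuple(float(v) for v in s["initial_state"])
        kw["initial_state"] = st
    if "seed" in s and s["seed"] is not None:
        kw["seed"] = int(s["seed"])
    return Scenario(body=body, controller=controller, biofeedback=biofeedback,
                    display=display, perturbation=pert,
                    dt=float(s.get("dt_s", 0.001)), subject=subject, **kw)


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        return scenario_from_dict(cfg)
    except (KeyError, TypeError) as exc:
        raise ValueError(f"invalid scenario config {path}: {exc}") from exc


def scenario_to_dict(sc: Scenario) -> dict:
    """Normalized, round-trippable dict form of a scenario.

    Requires the scenario to carry its SubjectSpec (configs define the
    body through anthropometry, not raw link parameters).
    """
    if sc.subject is None:
        raise ValueError("scenario has no subject spec; cannot serialize")
    d = {
        "subject": {"height_m": sc.subject.height, "mass_kg": sc.subject.mass},
        "controller": {"K_s": [[float(v) for v in row]
                               for row in sc.controller.K_s],
                       "K_c": [[float(v) for v in row]
                               for row in sc.controller.K_c],
                       "t_d_s": sc.controller.t_d},
        "biofeedback": {"tau_f_s": sc.biofeedback.tau_f,
                        "k_s": [[float(v) for v in row]
                                for row in sc.biofeedback.k_s],
                        "k_c": [[float(v) for v in row]
                                for row in sc.biofeedback.k_c]},
        "display": {"columns_deg": [float(c) for c in sc.display.columns],
                    "rows": sc.display.rows,
                    "thresholds_deg": [float(v)
                                       for v in sc.display.thresholds]},
        "perturbation": {"direction_deg": sc.perturbation.direction,
                         "displacement_m": sc.perturbation.displacement,
                         "t_accel_s": sc.perturbation.t_accel,
                         "t_const_s": sc.perturbation.t_const,
                         "t_decel_s": sc.perturbation.t_decel,
                         "onset_s": sc.perturbation.onset},
        "simulation": {"dt_s": sc.dt, "horizon_s": sc.horizon,
                       "initial_state": [float(v)
                                         for v in sc.initial_state],
                       "seed": sc.seed},
    }
    return d


def save_scenario(sc: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(sc), fh, sort_keys=False)


def write_trajectory(traj: Trajectory, path) -> None:
    """CSV with the full channel header; floats at repr precision."""
    traj.data.to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"trajectory file {path} missing column(s): {sorted(missing)}")
    t = df["t_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"trajectory file {path} has fewer than 2 samples")
    dt = float(t[1] - t[0])
    return Trajectory(df, dt)
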