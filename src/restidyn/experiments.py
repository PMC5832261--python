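"""Configuration-driven experiment runner and figure-protocol registry.

A config is a plain mapping (YAML/JSON-friendly) with blocks::

    protocol: rd | er | der | perturb | switch | clamp | clstats | train
    model:    {scale: {I_Ks: 0.4, ...}}        # conductance multipliers
    pacing:   {law, CL_star, clv, omega, seed, n_beats}
    solver:   {dt, n_cond}
    output:   {dir}

``run_experiment`` validates the config, executes the named protocol and
writes CSV/JSON artifacts whose header comments embed the resolved config.
The registry entries reproduce the study protocols at a reduced
conditioning length (the ``full`` flag restores 1000-beat conditioning).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clamp import fit_current_clamp
from .engine import classic_er, condition, rd_curve, run_train, snapshot
from .metrics import shift, space_of_states
from .pacing import (PacingSchedule, alternating_schedule, constant_schedule,
                     periodic_schedule, random_schedule)
from .stability import (average_delta_profile, cl_change_statistics,
                        mean_nb, switch_experiment)
from .tp06 import ModelParams, scale_conductances


class ConfigError(ValueError):
    pass


_LAWS = {"constant", "random", "periodic", "alternating"}
_PROTOCOLS = {"rd", "er", "der", "perturb", "switch", "clamp", "clstats",
              "train"}


def build_params(model_cfg: dict) -> ModelParams:
    params = ModelParams(values=dict(model_cfg.get("values", {})))
    scale = model_cfg.get("scale", {})
    if scale:
        params = scale_conductances(params, scale)
    return params


def build_schedule(pacing_cfg: dict) -> PacingSchedule:
    law = pacing_cfg.get("law", "constant")
    if law not in _LAWS:
        raise ConfigError(f"pacing.law must be one of {sorted(_LAWS)}, "
                          f"got {law!r}")
    n = int(pacing_cfg.get("n_beats", 200))
    cl_star = float(pacing_cfg.get("CL_star", 350.0))
    clv = float(pacing_cfg.get("clv", 0.0))
    if law == "constant":
        return constant_schedule(cl_star, n)
    if law == "random":
        return random_schedule(cl_star, clv, n,
                               int(pacing_cfg.get("seed", 0)))
    if law == "periodic":
        return periodic_schedule(cl_star, clv,
                                 float(pacing_cfg.get("omega", 2.4)), n)
    return alternating_schedule(cl_star, clv, n)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config: dict) -> None:
    header = (f"# restidyn {__version__} config_hash={_config_hash(config)}\n"
              f"# config: {json.dumps(config, sort_keys=True, default=str)}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_experiment(config: dict, out_dir=None) -> dict:
    """Execute the protocol named in ``config`` and write its artifacts.

    Returns a dict of result summaries (also written as JSON).
    """
    protocol = config.get("protocol")
    if protocol not in _PROTOCOLS:
        raise ConfigError(f"protocol must be one of {sorted(_PROTOCOLS)}, "
                          f"got {protocol!r}")
    out_dir = Path(out_dir or config.get("output", {}).get("dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    params = build_params(config.get("model", {}))
    solver = config.get("solver", {})
    dt = float(solver.get("dt", 0.02))
    n_cond = int(solver.get("n_cond", 300))
    summary: dict = {"protocol": protocol,
                     "config_hash": _config_hash(config)}

    if protocol == "train":
        sched = build_schedule(config.get("pacing", {}))
        train = run_train(params, sched, dt=dt)
        _write_csv(train.beats, out_dir / "train.csv", config)
        summary["n_beats"] = train.n_beats
    elif protocol == "rd":
        rd_cfg = config.get("rd", {})
        curve = rd_curve(params, float(rd_cfg.get("cl_min", 300)),
                         float(rd_cfg.get("cl_max", 1400)),
                         float(rd_cfg.get("step", 20)), n_cond=n_cond,
                         dt=dt)
        _write_csv(curve.points, out_dir / "rd_curve.csv", config)
        summary["n_points"] = len(curve.points)
    elif protocol == "er":
        er_cfg = config.get("er", {})
        cl_star = float(er_cfg.get("CL_star", 350))
        er_cl, er_di = classic_er(params, cl_star,
                                  float(er_cfg.get("range", 20)),
                                  float(er_cfg.get("step", 5)),
                                  n_cond=n_cond, dt=dt)
        _write_csv(er_cl.points, out_dir / "er_cl.csv", config)
        _write_csv(er_di.points, out_dir / "er_di.csv", config)
        summary["slope_cl"] = er_cl.slope_at(cl_star)
        summary["slope_di"] = er_di.slope_at(
            cl_star - er_cl.conditioning["APD_cond"])
    elif protocol == "der":
        sched = build_schedule(config.get("pacing", {}))
        cond = condition(params, sched.meta.get("CL_star", 350.0), n_cond,
                         dt=dt)
        train = run_train(params, sched, initial_state=snapshot(cond), dt=dt)
        discard = int(config.get("der", {}).get("discard", 50))
        for mode in ("vs_CL", "vs_DI"):
            space = space_of_states(train, mode, discard=discard)
            _write_csv(space.points, out_dir / f"space_{mode}.csv", config)
            try:
                summary[f"shift_{mode}"] = shift(space)
            except Exception as exc:   # insufficient coverage is data too
                summary[f"shift_{mode}"] = f"error: {exc}"
        _write_csv(train.beats, out_dir / "train.csv", config)
    elif protocol == "perturb":
        sched = build_schedule(config.get("pacing", {}))
        pert = config.get("perturb", {})
        cond = condition(params, sched.meta.get("CL_star", 350.0), n_cond,
                         dt=dt)
        drop0 = int(pert.get("first_drop", 10))
        n_drops = int(pert.get("n_drops", 20))
        profile, per_drop = average_delta_profile(
            params, sched, range(drop0, drop0 + n_drops),
            follow=int(pert.get("follow", 50)),
            initial_state=snapshot(cond), dt=dt)
        _write_csv(per_drop, out_dir / "per_drop.csv", config)
        _write_csv(pd.DataFrame({"beat": np.arange(1, profile.size + 1),
                                 "mean_delta_apd_ms": profile}),
                   out_dir / "delta_profile.csv", config)
        summary["mean_nb"] = mean_nb(per_drop)
    elif protocol == "switch":
        sw = config.get("switch", {})
        dyn = build_schedule(config.get("pacing", {}))
        cond = condition(params, float(sw.get("constant_CL", 350)), n_cond,
                         dt=dt)
        res = switch_experiment(
            params, float(sw.get("constant_CL", 350)),
            int(sw.get("constant_beats", 48)), dyn,
            int(sw.get("drop_index", 10)),
            initial_state=snapshot(cond), dt=dt)
        summary.update({k: res[k] for k in
                        ("valid", "quenched", "beats_to_quench")})
    elif protocol == "clamp":
        cname = config.get("clamp", {}).get("current", "I_CaL")
        cl_ref = float(config.get("clamp", {}).get("reference_CL", 350))
        clamp = fit_current_clamp(params, cname, reference_cl=cl_ref,
                                  n_cond=n_cond, dt=dt)
        (out_dir / f"clamp_{cname}.json").write_text(clamp.to_json())
        summary["rmse"] = clamp.rmse
        summary["fit_order"] = clamp.fit_order
    elif protocol == "clstats":
        pc = dict(config.get("pacing", {}), law="periodic")
        rc = dict(config.get("pacing", {}), law="random")
        stats = cl_change_statistics(build_schedule(pc), build_schedule(rc))
        _write_csv(stats.table, out_dir / "cl_change_stats.csv", config)
        summary["n_thresholds"] = len(stats.table)

    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, default=str))
    return summary


#: protocols of the study's main figures, at reduced conditioning
REGISTRY = {
    "fig5": {"protocol": "der",
             "pacing": {"law": "periodic", "CL_star": 350, "clv": 70,
                        "omega": 2.4, "n_beats": 250},
             "solver": {"n_cond": 300}},
    "fig8": {"protocol": "perturb",
             "pacing": {"law": "periodic", "CL_star": 350, "clv": 35,
                        "omega": 2.4, "n_beats": 90},
             "perturb": {"first_drop": 10, "n_drops": 20, "follow": 50},
             "solver": {"n_cond": 300}},
    "fig9": {"protocol": "er", "er": {"CL_star": 350, "range": 35},
             "solver": {"n_cond": 300}},
    "fig11": {"protocol": "switch",
              "model": {"scale": {"I_Ks": 0.4}},
              "pacing": {"law": "periodic", "CL_star": 350, "clv": 35,
                         "omega": 2.4, "n_beats": 120},
              "switch": {"constant_CL": 350, "constant_beats": 48,
                         "drop_index": 10},
              "solver": {"n_cond": 300}},
    "s2": {"protocol": "clstats",
           "pacing": {"CL_star": 350, "clv": 35, "omega": 2.4,
                      "n_beats": 2000, "seed": 7}},
}


def registry_config(name: str, full: bool = False) -> dict:
    if name not in REGISTRY:
        raise ConfigError(f"unknown registry entry {name!r}; "
                          f"choose from {sorted(REGISTRY)}")
    cfg = json.loads(json.dumps(REGISTRY[name]))
    if full:
        cfg.setdefault("solver", {})["n_cond"] = 1000
    return cfg
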