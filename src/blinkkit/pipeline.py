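"""End-to-end pipelines driven by a strict JSON configuration.

Two pipelines are provided: ``kinetics`` (simulate -> localize -> filter ->
drift-correct -> group/link -> summarize) and ``sofi`` (simulate -> SOFI ->
decorrelation + metrics).  A run writes its resolved configuration next to
its outputs and is byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .camera import CameraModel
from .errors import SchemaError
from .io import config_hash, write_events, write_json_report, \
    write_localizations, write_movie
from .kinetics import group_molecules, summarize_kinetics
from .localize import correct_drift, filter_localizations, find_fiducials, \
    localize_stack
from .simulate import EmitterTruth, StructureSpec, make_structure, \
    rates_for_duty, render_movie, simulate_switching
from .sofi import decorrelation, sofi2, sofi_metrics

__all__ = ["DEFAULTS", "load_config", "run_pipeline"]

DEFAULTS: dict = {
    "pipeline": "kinetics",           # "kinetics" | "sofi"
    "seed": 0,
    "out_dir": "blinkkit_run",
    "camera": {"pixel_size": 100.0, "exposure": 0.008, "cycle": 0.01,
               "em_gain": 1.0, "quantum_efficiency": 0.9,
               "read_noise": 1.0, "offset": 100.0, "conversion": 0.5},
    "structure": {"pattern": "point_field", "field_size": [6400.0, 6400.0],
                  "n": 20, "density": None, "n_filaments": 5,
                  "filament_width": 50.0, "radius": None},
    "dye": {"mean_on": 0.01, "on_off_ratio": 1e-3, "photon_rate": 5e5},
    "movie": {"n_frames": 500, "shape": [64, 64], "psf_sigma": 130.0,
              "background": 5.0},
    "localize": {"dog_sigma": 1.2, "dynamic_factor": 1.7, "roi_size": 7,
                 "sigma_start": 2.0, "max_iterations": 25},
    "filter": {"max_uncertainty": 40.0, "min_photons": 40.0},
    "kinetics": {"radius": 100.0, "gap": 5, "eps": 100.0},
    "sofi": {"lag": 1, "max_lag": 20},
    "drift_correction": False,
    "save_movie": False,
}


def _merge_strict(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, val in user.items():
        if key not in defaults:
            raise SchemaError(f"unknown config key {path + key!r}")
    for key, dval in defaults.items():
        if key in user:
            uval = user[key]
            if isinstance(dval, dict) and isinstance(uval, dict):
                out[key] = _merge_strict(dval, uval, path + key + ".")
            else:
                out[key] = uval
        else:
            out[key] = dval
    return out


def load_config(path_or_dict) -> dict:
    """Resolve a user config against the defaults, rejecting unknown keys."""
    if isinstance(path_or_dict, (str, Path)):
        user = json.loads(Path(path_or_dict).read_text())
    else:
        user = dict(path_or_dict)
    cfg = _merge_strict(DEFAULTS, user)
    if cfg["pipeline"] not in ("kinetics", "sofi"):
        raise SchemaError("pipeline must be 'kinetics' or 'sofi'")
    return cfg


def _simulate(cfg: dict, rng: np.random.Generator):
    cam = CameraModel(**cfg["camera"])
    st = cfg["structure"]
    spec = StructureSpec(pattern=st["pattern"],
                         field_size=tuple(st["field_size"])
                         if st["field_size"] else None,
                         n=st["n"], density=st["density"],
                         n_filaments=st["n_filaments"],
                         filament_width=st["filament_width"],
                         radius=st["radius"])
    positions = make_structure(spec, rng)
    dye = cfg["dye"]
    rate_on, rate_off = rates_for_duty(dye["on_off_ratio"], dye["mean_on"])
    mv = cfg["movie"]
    duration = mv["n_frames"] * cam.cycle
    emitters, traces = [], []
    for p in positions:
        emitters.append(EmitterTruth(p[0], p[1], p[2], rate_on, rate_off,
                                     dye["photon_rate"]))
        traces.append(simulate_switching(rate_on, rate_off, duration,
                                         seed=rng))
    stack = render_movie(emitters, traces, mv["psf_sigma"], cam,
                         mv["n_frames"], tuple(mv["shape"]),
                         background=mv["background"], seed=rng)
    return stack, emitters, traces


def run_pipeline(config) -> dict:
    """Execute a configured pipeline; returns the machine-readable summary.

    Artifacts (resolved config, localization/event CSVs, summary JSON and
    optionally the movie TIFF) are written to ``config['out_dir']``.
    """
    cfg = load_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.resolved.json").write_text(
        json.dumps(cfg, indent=2, sort_keys=True))
    rng = np.random.default_rng(cfg["seed"])

    stack, emitters, traces = _simulate(cfg, rng)
    if cfg["save_movie"]:
        write_movie(out_dir / "movie.tif", stack,
                    meta={"seed": cfg["seed"]})

    summary: dict = {"pipeline": cfg["pipeline"], "seed": cfg["seed"],
                     "n_emitters": len(emitters),
                     "n_frames": stack.n_frames}
    if cfg["pipeline"] == "kinetics":
        loc = cfg["localize"]
        table = localize_stack(stack, **loc)
        filt, report = filter_localizations(table, **cfg["filter"])
        if cfg["drift_correction"]:
            fids = find_fiducials(filt, stack.n_frames)
            if fids:
                filt, _ = correct_drift(filt, fids)
        write_localizations(out_dir / "localizations.csv", filt,
                            meta={"config_hash": config_hash(cfg)})
        kin = cfg["kinetics"]
        groups = group_molecules(filt, eps=kin["eps"], radius=kin["radius"],
                                 gap=kin["gap"])
        write_events(out_dir / "events.csv", groups, stack.camera.cycle,
                     meta={"config_hash": config_hash(cfg)})
        summary["filter_report"] = report
        if groups and any(g.events for g in groups):
            ks = summarize_kinetics(groups, stack.camera.cycle,
                                    n_frames=stack.n_frames)
            summary["kinetics"] = ks.to_dict()
        else:
            summary["kinetics"] = None
    else:
        sf = cfg["sofi"]
        img = sofi2(stack, lag=sf["lag"])
        curve = decorrelation(stack, max_lag=sf["max_lag"])
        metrics = sofi_metrics(img, stack)
        summary["sofi"] = {
            "tau_frames": curve.tau, "amplitude": curve.amplitude,
            "offset": curve.offset, "diagnostic": curve.diagnostic,
            "snr": metrics.snr, "pct_useful": metrics.pct_useful,
        }
    # hash the scientific parameters only: where outputs land must not
    # change the provenance identity of the run
    hashed = {k: v for k, v in cfg.items() if k != "out_dir"}
    write_json_report(out_dir / "summary.json", summary, config=hashed)
    return summary
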