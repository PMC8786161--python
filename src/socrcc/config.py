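"""Flat YAML (de)serialisation of a full run configuration.

A run is one mapping with ``model``, ``rcc``, ``network``, ``schedule`` and
``integrator`` sections; the named model preset ``berry-2022`` carries the
published kinetic constants and control parameters as defaults, so a config
file only needs to state deviations.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .berry import BerryParams, RCCParams
from .network import NetworkConfig, PerturbationSchedule
from .integrate import IntegratorSpec

__all__ = ["MODEL_PRESETS", "dump_config", "load_config"]

#: Named (BerryParams, RCCParams) presets.  "berry-2022" is the published
#: parameterisation of the controlled bienzymatic oscillator.
MODEL_PRESETS = {
    "berry-2022": (BerryParams(), RCCParams()),
    "berry-2022-enhanced": (BerryParams(), RCCParams(xi_p=-3.0, xi_g=-3.0)),
}


def _asdict(obj) -> dict:
    d = dataclasses.asdict(obj)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = [float(x) for x in v]
        elif hasattr(v, "item"):  # numpy scalar
            d[k] = v.item()
    return d


def dump_config(cfg: NetworkConfig, schedule: PerturbationSchedule,
                spec: IntegratorSpec, path) -> None:
    doc = {
        "model": _asdict(cfg.bp),
        "rcc": _asdict(cfg.rcc),
        "network": {k: v for k, v in _asdict(cfg).items()
                    if k not in ("bp", "rcc")},
        "schedule": _asdict(schedule),
        "integrator": _asdict(spec),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _tupled(d: dict, *keys) -> dict:
    out = dict(d)
    for k in keys:
        if out.get(k) is not None:
            out[k] = tuple(out[k])
    return out


def load_config(path) -> tuple[NetworkConfig, PerturbationSchedule, IntegratorSpec]:
    doc = yaml.safe_load(Path(path).read_text())
    model = doc.get("model", "berry-2022")
    if isinstance(model, str):
        bp, rcc_default = MODEL_PRESETS[model]
    else:
        bp = BerryParams(**model)
        rcc_default = RCCParams()
    rcc = RCCParams(**doc["rcc"]) if "rcc" in doc else rcc_default
    net = _tupled(doc["network"], "weights", "nominal_weights", "grid_shape")
    cfg = NetworkConfig(bp=bp, rcc=rcc, **net)
    sched = PerturbationSchedule(
        **_tupled(doc.get("schedule", {}), "column_scales", "per_unit_scales"))
    spec = IntegratorSpec(**doc.get("integrator", {}))
    return cfg, sched, spec
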