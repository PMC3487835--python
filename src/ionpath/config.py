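"""Pipeline configuration: a single YAML file with validated keys.

The bundled default configuration documents every choice; values the
underlying protocol does not pin down are flagged ``# assumed`` in the
rendered file.  Unknown keys are rejected with the list of valid keys.
"""
from __future__ import annotations

import copy
import importlib.resources
from pathlib import Path

import yaml

from .kmc import KMCConfig
from .metad import MetadSchedule, Wall
from .toy import ToyFilterSystem, build_toy_system

__all__ = [
    "default_config",
    "load_config",
    "apply_overrides",
    "system_from_config",
    "schedule_1d_from_config",
    "kmc_config_from_config",
]


def default_config() -> dict:
    text = (
        importlib.resources.files("ionpath.data")
        .joinpath("default_config.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def _valid_paths(tree: dict, prefix: str = "") -> list[str]:
    out = []
    for k, v in tree.items():
        dotted = f"{prefix}{k}"
        out.append(dotted)
        if isinstance(v, dict):
            out.extend(_valid_paths(v, dotted + "."))
    return out


def _check_keys(cfg: dict, ref: dict, prefix: str = "") -> None:
    valid = _valid_paths(ref)
    for k, v in cfg.items():
        dotted = f"{prefix}{k}"
        if k not in ref:
            raise KeyError(
                f"unknown configuration key {dotted!r}; valid keys: "
                + ", ".join(sorted(valid))
            )
        if isinstance(v, dict) and isinstance(ref[k], dict):
            _check_keys(v, ref[k], dotted + ".")


def _merge(base: dict, update: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in update.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None, overrides: list[str] = ()) -> dict:
    """Load the default config, overlay a user file and ``key=value`` overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _check_keys(user, cfg)
        cfg = _merge(cfg, user)
    return apply_overrides(cfg, overrides)


def apply_overrides(cfg: dict, overrides: list[str] = ()) -> dict:
    cfg = copy.deepcopy(cfg)
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form key=value")
        dotted, raw = item.split("=", 1)
        value = yaml.safe_load(raw)
        node = cfg
        parts = dotted.split(".")
        for p in parts[:-1]:
            if p not in node or not isinstance(node[p], dict):
                raise KeyError(
                    f"unknown configuration key {dotted!r}; valid keys: "
                    + ", ".join(sorted(_valid_paths(default_config())))
                )
            node = node[p]
        if parts[-1] not in node:
            raise KeyError(
                f"unknown configuration key {dotted!r}; valid keys: "
                + ", ".join(sorted(_valid_paths(default_config())))
            )
        node[parts[-1]] = value
    return cfg


def system_from_config(cfg: dict) -> ToyFilterSystem:
    s = cfg["system"]
    return build_toy_system(
        n_sites=s["n_sites"],
        site_spacing=s["site_spacing"],
        well_depths=s["well_depths"],
        barrier_heights=s["barrier_heights"],
        repulsion_strength=s["repulsion_strength"],
        screening_length=s["screening_length"],
        n_ions=s["n_ions"],
        temperature=s["temperature"],
    )


def schedule_1d_from_config(cfg: dict, n_cvs: int = 1) -> MetadSchedule:
    m = cfg["metadynamics"]
    widths = tuple(m["widths"][:n_cvs]) if n_cvs > 1 else (m["widths"][0],)
    walls: list[Wall] = []
    if n_cvs >= 2 and m.get("wall_z_max") is not None:
        walls.append(Wall(axis=1, bound=m["wall_z_max"], side="upper", k=m["wall_k"]))
    if n_cvs >= 3 and m.get("wall_ntheta_min") is not None:
        walls.append(
            Wall(axis=2, bound=m["wall_ntheta_min"], side="lower", k=m["wall_k"])
        )
    return MetadSchedule(
        height=m["height"],
        deposition_period=m["deposition_period"],
        widths=widths,
        walls=tuple(walls),
        n_walkers=m["n_walkers"],
    )


def kmc_config_from_config(cfg: dict, voltage: float | None = None) -> KMCConfig:
    k = cfg["kmc"]
    return KMCConfig(
        voltage=k["voltage"] if voltage is None else voltage,
        conc_in=k["conc_in"],
        conc_out=k["conc_out"],
        total_time=k["total_time"],
        seed=cfg["seed"],
        entry_rate_scale=k["entry_rate_scale"],
    )
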