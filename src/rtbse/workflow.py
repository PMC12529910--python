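"""Config-file driven workflow: generate -> propagate -> spectrum -> lr -> compare.

The configuration is a YAML mapping with the sections ``system``, ``field``,
``propagation``, ``spectrum``, ``lr``, ``compare``, ``shg_scan`` and
``outputs``.  Physical quantities may be plain numbers (atomic units) or
strings with an explicit unit suffix: ``"6.0 eV"``, ``"0.22 Ha"``,
``"12.6 fs"``, ``"1 as"``, ``"0.04 au"``.  Schema violations are reported
with their field path.  Every output table carries a header with the resolved
configuration, and a JSON run manifest records what was produced.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .linear_response import lr_polarizability, solve_lr
from .pipelines import kick_absorption_spectrum, rt_lr_comparison, shg_scan
from .propagator import propagate
from .spectra import SpectrumConfig, Spectrum, WindowSpec
from .system import FieldSpec, PropagationConfig, load_bundle
from .synthetic import (
    make_noncentrosymmetric_model,
    make_random_bundle,
    make_two_level,
)
from .units import HARTREE_EV, fs_to_au

__all__ = ["ConfigError", "run_workflow", "parse_quantity"]

_UNIT_TO_AU = {
    "au": 1.0,
    "ha": 1.0,
    "hartree": 1.0,
    "ev": 1.0 / HARTREE_EV,
    "fs": fs_to_au(1.0),
    "as": fs_to_au(1.0) * 1e-3,
}


class ConfigError(ValueError):
    """A workflow configuration violates the schema; message carries the path."""


def parse_quantity(value, path: str = "") -> float:
    """Number in atomic units from a float or a "value unit" string."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 2:
            try:
                num = float(parts[0])
            except ValueError:
                raise ConfigError(f"{path}: cannot parse number in {value!r}")
            unit = parts[1].lower()
            if unit not in _UNIT_TO_AU:
                raise ConfigError(f"{path}: unknown unit {parts[1]!r}")
            return num * _UNIT_TO_AU[unit]
        try:
            return float(value)
        except ValueError:
            pass
    raise ConfigError(f"{path}: expected a number or 'value unit' string, got {value!r}")


def _section(cfg: dict, name: str, allowed: set[str], required: set[str] = frozenset()) -> dict:
    sec = cfg.get(name, {})
    if sec is None:
        sec = {}
    if not isinstance(sec, dict):
        raise ConfigError(f"{name}: expected a mapping")
    for key in sec:
        if key not in allowed:
            raise ConfigError(f"{name}.{key}: unknown key (allowed: {sorted(allowed)})")
    for key in required:
        if key not in sec:
            raise ConfigError(f"{name}.{key}: required key missing")
    return sec


def _build_system(sec: dict):
    if "bundle" in sec:
        return load_bundle(sec["bundle"])
    gen = sec.get("generate")
    if not isinstance(gen, dict) or "model" not in gen:
        raise ConfigError("system.generate.model: required")
    model = gen["model"]
    if model in ("two_level", "two-level"):
        return make_two_level(
            gap=float(gen.get("gap_ev", 6.0)),
            dipole_strength=float(gen.get("dipole_strength", 1.0)),
            interaction=gen.get("interaction", "none"),
        )
    if model in ("noncentro", "noncentrosymmetric"):
        return make_noncentrosymmetric_model(
            target_excitation=float(gen.get("target_excitation_ev", 6.0)),
            n_levels=int(gen.get("n_levels", 4)),
            asymmetry=float(gen.get("asymmetry", 0.5)),
        )
    if model == "random":
        return make_random_bundle(
            n_ao=int(gen.get("n_ao", 6)),
            n_occ=int(gen.get("n_occ", 2)),
            n_aux=int(gen.get("n_aux", 12)),
            seed=int(gen.get("seed", 0)),
        )
    raise ConfigError(f"system.generate.model: unknown model {model!r}")


def _build_field(sec: dict) -> FieldSpec:
    kind = sec.get("kind", "none")
    pol = sec.get("polarization", [1.0, 0.0, 0.0])
    if kind == "kick":
        return FieldSpec.kick(parse_quantity(sec.get("strength", 1e-3),
                                             "field.strength"), pol)
    if kind == "pulse":
        for key in ("amplitude", "carrier", "center", "width"):
            if key not in sec:
                raise ConfigError(f"field.{key}: required for a pulse")
        return FieldSpec.pulse(
            amplitude=parse_quantity(sec["amplitude"], "field.amplitude"),
            carrier=parse_quantity(sec["carrier"], "field.carrier"),
            center=parse_quantity(sec["center"], "field.center"),
            width=parse_quantity(sec["width"], "field.width"),
            polarization=pol,
        )
    if kind == "none":
        return FieldSpec.none()
    raise ConfigError(f"field.kind: unknown kind {kind!r}")


def _build_propagation(sec: dict) -> PropagationConfig:
    dt = parse_quantity(sec.get("dt", "1 as"), "propagation.dt")
    if dt <= 0:
        raise ConfigError("propagation.dt: must be positive")
    n_steps = int(sec.get("n_steps", 20000))
    if n_steps <= 0:
        raise ConfigError("propagation.n_steps: must be positive")
    return PropagationConfig(
        dt=dt,
        n_steps=n_steps,
        sc_threshold=float(sec.get("sc_threshold", 1e-7)),
        max_sc_iters=int(sec.get("max_sc_iters", 50)),
        exp_method=sec.get("exp_method", "bch"),
        bch_threshold=float(sec.get("bch_threshold", 1e-14)),
    )


def _build_spectrum(sec: dict) -> SpectrumConfig:
    wsec = sec.get("window", {"kind": "exponential", "gamma_fs": 0.2})
    window = WindowSpec(
        kind=wsec.get("kind", "exponential"),
        gamma_fs=float(wsec.get("gamma_fs", 0.2)),
        center_fs=float(wsec.get("center_fs", 0.0)),
        spread_fs=float(wsec.get("spread_fs", 4.0)),
    )
    grid = sec.get("grid", {})
    return SpectrumConfig(
        window=window,
        pade_enabled=bool(sec.get("pade", True)),
        pade_fit_max_energy=float(sec.get("pade_fit_max_energy_ev", 200.0)),
        grid_min=float(grid.get("min", 0.0)),
        grid_max=float(grid.get("max", 20.0)),
        grid_step=float(grid.get("step", 0.02)),
    )


def _header(config: dict) -> str:
    return "rtbse version " + __version__ + "\nresolved config: " + json.dumps(
        config, default=str
    )


def run_workflow(config, outdir) -> dict:
    """Execute the stages requested in ``config``; returns the run manifest.

    ``config`` is a path to a YAML file or an already-parsed mapping.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("top level: expected a mapping")
    for key in config:
        if key not in {"system", "field", "propagation", "spectrum", "lr",
                       "compare", "shg_scan", "outputs"}:
            raise ConfigError(f"{key}: unknown section")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "outputs": {}}

    sys_sec = _section(config, "system", {"bundle", "generate"})
    system = _build_system(sys_sec)
    field = _build_field(_section(
        config, "field",
        {"kind", "polarization", "strength", "amplitude", "carrier", "center",
         "width"}))
    prop_cfg = _build_propagation(_section(
        config, "propagation",
        {"dt", "n_steps", "sc_threshold", "max_sc_iters", "exp_method",
         "bch_threshold"}))
    spec_cfg = _build_spectrum(_section(
        config, "spectrum",
        {"window", "pade", "pade_fit_max_energy_ev", "grid"}))
    stages = _section(config, "outputs", {"stages", "directory"}).get(
        "stages", ["spectrum", "lr", "compare"])
    header = _header(config)

    if "propagate" in stages:
        traj = propagate(system, field, prop_cfg)
        path = outdir / "trajectory.dat"
        traj.save(path, header_extra=header)
        manifest["outputs"]["trajectory"] = str(path)

    if "spectrum" in stages or "compare" in stages:
        if "compare" in stages:
            comp_sec = _section(config, "compare", {"tolerance_ev", "min_rel_intensity"})
            comparison, spectrum, lr = rt_lr_comparison(
                system, prop_cfg, spec_cfg,
                matching_tolerance=float(comp_sec.get("tolerance_ev", 0.3)),
            )
            path = outdir / "compare.dat"
            rows = [(rt.position, l.position, d) for rt, l, d in comparison.pairs]
            np.savetxt(path, np.asarray(rows).reshape(-1, 3),
                       header="rt_peak_ev lr_peak_ev abs_dev_ev\n"
                              f"mad_ev {comparison.mad:.6f} "
                              f"mad_bright_ev {comparison.mad_bright:.6f}\n"
                              + header)
            manifest["outputs"]["compare"] = str(path)
            manifest["mad_ev"] = comparison.mad
        else:
            spectrum = kick_absorption_spectrum(system, prop_cfg, spec_cfg)
        path = outdir / "spectrum.dat"
        spectrum.save(path, header_extra=header)
        manifest["outputs"]["spectrum"] = str(path)

    if "lr" in stages:
        lr_sec = _section(config, "lr", {"flavor", "eta_ev"})
        lr = solve_lr(system, flavor=lr_sec.get("flavor", "full"))
        grid = spec_cfg.grid_ev()
        iso = lr_polarizability(lr, grid, float(lr_sec.get("eta_ev", 0.1)))
        lr_spec = Spectrum(omega_ev=grid, alpha_iso=iso)
        path = outdir / "lr_spectrum.dat"
        lr_spec.save(path, header_extra=header)
        epath = outdir / "lr_excitations.dat"
        np.savetxt(epath, np.column_stack([lr.energies * HARTREE_EV,
                                           lr.transition_dipoles]),
                   header="energy_ev dip_x dip_y dip_z\n" + header)
        manifest["outputs"]["lr"] = str(path)
        manifest["outputs"]["lr_excitations"] = str(epath)

    if "shg_scan" in stages:
        shg_sec = _section(config, "shg_scan",
                           {"amplitudes", "carrier_ev", "pulse_center_fs",
                            "pulse_width_fs", "window_center_fs",
                            "window_spread_fs", "total_time_fs"})
        if "amplitudes" not in shg_sec:
            raise ConfigError("shg_scan.amplitudes: required")
        res = shg_scan(
            system,
            [parse_quantity(a, "shg_scan.amplitudes") for a in shg_sec["amplitudes"]],
            carrier_ev=float(shg_sec.get("carrier_ev", 6.0)),
            pulse_center_fs=float(shg_sec.get("pulse_center_fs", 12.6)),
            pulse_width_fs=float(shg_sec.get("pulse_width_fs", 4.2)),
            window_center_fs=float(shg_sec.get("window_center_fs", 32.6)),
            window_spread_fs=float(shg_sec.get("window_spread_fs", 4.0)),
            total_time_fs=float(shg_sec.get("total_time_fs", 52.6)),
        )
        path = outdir / "shg_scan.dat"
        names = sorted(res.features)
        table = np.column_stack([res.amplitudes] + [res.features[n] for n in names])
        exps = " ".join(f"{n}_exponent {res.exponents[n].exponent:.4f}"
                        for n in names)
        np.savetxt(path, table, header="E0_au " + " ".join(names) + "\n"
                   + exps + "\n" + header)
        manifest["outputs"]["shg_scan"] = str(path)
        manifest["exponents"] = {n: res.exponents[n].exponent for n in names}

    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest"] = str(mpath)
    return manifest
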