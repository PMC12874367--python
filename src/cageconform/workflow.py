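"""Config-driven orchestration of the full cage analysis.

One YAML config names the inputs (trajectory, scan grid, charge table,
energy table) and the analysis parameters (state thresholds, burn-in,
Boltzmann temperature, density estimator, atom selection).  Each
configured stage writes its own CSV/JSON products plus a manifest
recording the package version, the seed, the fully-defaulted config and
its hash, and per-stage status — so a run is reproducible byte for byte
from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cage_model import detect_topology, read_structure
from .conformation import (
    Thresholds,
    angles_to_frame,
    classify_series,
    theta_series,
)
from .energetics import (
    method_agreement,
    read_energy_csv,
    relative_energies,
    state_energy_summary,
)
from .errors import CageError, ConfigError, DataError
from .populations import (
    BoltzmannSpec,
    angle_density,
    boltzmann_populations,
    integrate_density,
    residence_fractions,
)
from .surface import conformer_gaps, find_minima, read_scan
from .symmetry import (
    average_charges,
    compare_charge_models,
    equivalence_classes,
    read_charge_csv,
    write_charge_csv,
)

__all__ = ["RunConfig", "load_config", "run_analysis"]

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "analog": "endo-C",
    "thresholds": {"open_max": 55.0, "semiopen_max": 80.0},
    "rule": "min",
    "burn_in": 0,
    "temperature": 298.15,
    "density": {"estimator": "histogram", "bins": 90, "bandwidth": None},
    "selection": {
        "allowed_elements": None,
        "excluded_elements": None,
        "keep_resnames": None,
    },
    "trajectory": None,
    "scan": None,
    "scan_labels": None,
    "charges": None,
    "charge_structure": None,
    "energies": None,
    "reference_method": None,
}


class RunConfig(dict):
    """A fully-defaulted analysis configuration."""

    @property
    def thresholds(self) -> Thresholds:
        t = self["thresholds"]
        return Thresholds(
            open_max=float(t["open_max"]),
            semiopen_max=float(t["semiopen_max"]),
        )


def _merge(defaults: dict, user: dict) -> dict:
    out = dict(defaults)
    for k, v in user.items():
        if k not in defaults:
            raise ConfigError(f"unknown config key {k!r}")
        if isinstance(defaults[k], dict) and isinstance(v, dict):
            out[k] = _merge(defaults[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Load a YAML config, apply overrides, fill in every default."""
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        user.update(loaded)
    user.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(_merge(_DEFAULTS, user))
    cfg.thresholds  # validate
    if cfg["temperature"] <= 0:
        raise ConfigError("temperature must be > 0")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def _write_json(path: Path, payload: Any) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stages


def _stage_trajectory(cfg: RunConfig, out: Path) -> list[str]:
    sel = cfg["selection"]
    frames = read_structure(
        cfg["trajectory"], keep_resnames=sel["keep_resnames"]
    )
    frames = [
        f.filtered(sel["allowed_elements"], sel["excluded_elements"])
        for f in frames
    ]
    topo = detect_topology(frames[0])
    thresholds = cfg.thresholds
    angle_sets = theta_series(frames, topo)
    states = classify_series(angle_sets, thresholds, cfg["rule"])
    df = angles_to_frame(angle_sets, states)
    angles_csv = out / "angles.csv"
    df.to_csv(angles_csv, index=False, float_format="%.6f")

    dens_cfg = cfg["density"]
    theta_min = df["theta_min"].to_numpy()
    dens = angle_density(
        theta_min,
        bins=int(dens_cfg["bins"]),
        estimator=dens_cfg["estimator"],
        bandwidth=dens_cfg["bandwidth"],
        thresholds=thresholds,
    )
    density_csv = out / "density.csv"
    pd.DataFrame(
        {"bin_center": dens.centers, "density": dens.density}
    ).to_csv(density_csv, index=False, float_format="%.8f")

    pops = residence_fractions(states, burn_in=int(cfg["burn_in"]))
    integrated = integrate_density(dens, thresholds)
    pops_json = out / "populations.json"
    _write_json(
        pops_json,
        {
            "residence_fractions": pops.fractions,
            "frame_counts": pops.counts,
            "n_frames": pops.n_frames,
            "burn_in": pops.burn_in,
            "density_integrated_fractions": integrated,
            "thresholds": {
                "open_max": thresholds.open_max,
                "semiopen_max": thresholds.semiopen_max,
            },
        },
    )
    return [str(angles_csv), str(density_csv), str(pops_json)]


def _stage_scan(cfg: RunConfig, out: Path) -> list[str]:
    surf = read_scan(cfg["scan"])
    minima = find_minima(surf)
    labels = cfg["scan_labels"]
    payload: dict[str, Any] = {
        "n_points": surf.n_points,
        "rectangular": surf.is_rectangular,
        "minima": [
            {"d1": m.d1, "d2": m.d2, "energy_kcal_mol": m.energy}
            for m in minima
        ],
    }
    outputs = []
    scan_json = out / "scan_minima.json"
    if labels is not None:
        if len(labels) != len(minima):
            raise DataError(
                f"scan_labels has {len(labels)} entries for "
                f"{len(minima)} minima (minima are in energy order)"
            )
        table = conformer_gaps(minima, labels)
        payload["reference_state"] = table.reference_state
        payload["gaps_kcal_mol"] = table.gaps
        payload["warnings"] = table.warnings
        # Boltzmann populations of all scan points, each point assigned
        # to the basin of its nearest labelled minimum
        centers = np.array([[m.d1, m.d2] for m in minima])
        pts = np.column_stack([surf.d1, surf.d2])
        nearest = np.argmin(
            ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        point_labels = [str(labels[k]) for k in nearest]
        pops = boltzmann_populations(
            surf.energy,
            point_labels,
            BoltzmannSpec(temperature=float(cfg["temperature"])),
        )
        payload["boltzmann_populations"] = pops
        payload["boltzmann_temperature_K"] = float(cfg["temperature"])
    _write_json(scan_json, payload)
    outputs.append(str(scan_json))
    return outputs


def _stage_charges(cfg: RunConfig, out: Path) -> list[str]:
    if cfg["charge_structure"] is None:
        raise ConfigError("charges stage needs 'charge_structure'")
    sel = cfg["selection"]
    struct = read_structure(
        cfg["charge_structure"], keep_resnames=sel["keep_resnames"]
    )[0]
    struct = struct.filtered(sel["allowed_elements"], sel["excluded_elements"])
    if not struct.bonds:
        from .cage_model import perceive_bonds

        perceive_bonds(struct)
    partition = equivalence_classes(struct)
    elements, chargesets = read_charge_csv(cfg["charges"])
    if len(elements) != struct.n_atoms:
        raise DataError(
            f"charge table has {len(elements)} atoms, structure has "
            f"{struct.n_atoms}"
        )
    averaged = [average_charges(cs, partition) for cs in chargesets]
    avg_csv = out / "charges_averaged.csv"
    write_charge_csv(avg_csv, elements, averaged)
    part_json = out / "partition.json"
    _write_json(
        part_json,
        {
            "n_classes": partition.n_classes,
            "classes": {
                lab: cls
                for lab, cls in zip(partition.class_labels, partition.classes)
            },
        },
    )
    outputs = [str(avg_csv), str(part_json)]
    if len(chargesets) >= 2:
        cmp_df = compare_charge_models(chargesets, partition)
        cmp_csv = out / "charge_model_comparison.csv"
        cmp_df.to_csv(cmp_csv, float_format="%.8f")
        spread_json = out / "charge_model_spread.json"
        _write_json(spread_json, cmp_df.attrs["model_spread"])
        outputs += [str(cmp_csv), str(spread_json)]
    return outputs


def _stage_energetics(cfg: RunConfig, out: Path) -> list[str]:
    table = relative_energies(read_energy_csv(cfg["energies"]))
    summary = state_energy_summary(table)
    summary_csv = out / "energetics_summary.csv"
    summary.to_csv(summary_csv, index=False, float_format="%.6f")
    outputs = [str(summary_csv)]
    ref = cfg["reference_method"]
    if ref is not None:
        agree = method_agreement(table, ref)
        agree_csv = out / "method_agreement.csv"
        agree.to_csv(agree_csv, index=False, float_format="%.6f")
        outputs.append(str(agree_csv))
    return outputs


_STAGES = {
    "trajectory": (_stage_trajectory, "trajectory"),
    "scan": (_stage_scan, "scan"),
    "charges": (_stage_charges, "charges"),
    "energetics": (_stage_energetics, "energies"),
}


def run_analysis(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run every configured stage; write products and a manifest.

    Any stage failure is recorded in the manifest (with its error) and
    re-raised after the manifest is written, so partial outputs survive.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "cageconform",
        "version": __version__,
        "seed": int(cfg["seed"]),
        "config": dict(cfg),
        "config_sha256": _config_hash(dict(cfg)),
        "stages": [],
    }
    failure: CageError | None = None
    for name, (fn, key) in _STAGES.items():
        if cfg.get(key) is None:
            continue
        entry: dict[str, Any] = {"name": name}
        try:
            # record outputs relative to the run directory so identical
            # configs reproduce byte-identical manifests anywhere
            entry["outputs"] = [
                str(Path(p).relative_to(out)) for p in fn(cfg, out)
            ]
            entry["status"] = "completed"
        except FileNotFoundError as exc:
            entry["status"] = "failed"
            entry["error"] = f"missing input file: {exc.filename or exc}"
            failure = DataError(str(exc))
        except CageError as exc:
            entry["status"] = "failed"
            entry["error"] = str(exc)
            failure = exc
        manifest["stages"].append(entry)
        if failure is not None:
            break
    _write_json(out / "manifest.json", manifest)
    if failure is not None:
        raise failure
    return manifest
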