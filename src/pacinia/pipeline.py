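"""Seeded, file-to-file runs of each analysis stage.

A :class:`RunConfig` names a stage, its inputs/outputs and parameters; every
stage writes a JSON report carrying a provenance block (package version,
seed, parameters) so that identical configurations reproduce identical
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import (
    __version__,
    demo,
    entrainment,
    io,
    morphometry,
    psychophysics,
    stereology,
    tuning,
)
from .synthetic import PhantomSpec, make_corpuscle_phantom

STAGES = ("simulate", "morpho", "stereo", "entrain", "tune", "psycho", "demo")


@dataclass(frozen=True)
class RunConfig:
    """One stage invocation: inputs, outputs, seed and parameters."""

    stage: str
    output: Path
    inputs: dict[str, Path] = field(default_factory=dict)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        object.__setattr__(self, "output", Path(self.output))
        object.__setattr__(
            self, "inputs", {k: Path(v) for k, v in self.inputs.items()}
        )


def _provenance(config: RunConfig) -> dict:
    return {
        "version": __version__,
        "stage": config.stage,
        "seed": config.seed,
        "params": {k: str(v) for k, v in config.params.items()},
    }


def _require_inputs(config: RunConfig, *names: str) -> None:
    for name in names:
        if name not in config.inputs:
            raise ValueError(f"stage {config.stage!r} requires input {name!r}")
        if not config.inputs[name].exists():
            raise FileNotFoundError(config.inputs[name])


def run_stage(config: RunConfig) -> Path:
    """Execute one stage and return the path of its JSON report."""
    handler = {
        "simulate": _stage_simulate,
        "morpho": _stage_morpho,
        "stereo": _stage_stereo,
        "entrain": _stage_entrain,
        "tune": _stage_tune,
        "psycho": _stage_psycho,
        "demo": _stage_demo,
    }[config.stage]
    config.output.parent.mkdir(parents=True, exist_ok=True)
    report = handler(config)
    report["provenance"] = _provenance(config)
    return io.write_json_report(config.output, report)


def _stage_simulate(config: RunConfig) -> dict:
    """Write a corpuscle phantom volume (+ sidecar) next to the report."""
    spec_kwargs = dict(config.params)
    volume_path = Path(spec_kwargs.pop("volume_path", config.output.with_suffix(".tif")))
    spec = PhantomSpec(rng_seed=config.seed, **spec_kwargs)
    vol, truth = make_corpuscle_phantom(spec)
    io.save_labeled_volume(volume_path, vol, truth)
    return {
        "volume": str(volume_path),
        "labels": {str(k): v for k, v in vol.label_table.items()},
        "shape_zyx": list(vol.labels.shape),
    }


def _stage_morpho(config: RunConfig) -> dict:
    """Surface areas for all labels and contacts for requested pairs."""
    _require_inputs(config, "volume")
    vol, _ = io.load_labeled_volume(config.inputs["volume"])
    gap_nm = float(config.params.get("gap_nm", morphometry.DEFAULT_GAP_NM))
    labels = config.params.get("labels") or sorted(vol.label_table)
    areas = {}
    for lbl in labels:
        est = morphometry.surface_area(vol, int(lbl))
        areas[str(lbl)] = {
            "total_perimeter_um": est.total_perimeter_um,
            "surface_area_um2": est.surface_area_um2,
        }
    contacts = {}
    pairs = config.params.get("pairs") or []
    for a, b in pairs:
        s = morphometry.contact_map(vol, int(a), int(b), gap_nm=gap_nm)
        contacts[f"{min(a,b)}-{max(a,b)}"] = {
            "total_arc_um": s.total_arc_um,
            "contact_area_um2": morphometry.contact_area_from_overlap(s, vol.dz_um),
            "n_components": s.n_components_total,
            "first_contact_z_um": s.first_contact_z_um(vol.dz_um),
        }
    return {"gap_nm": gap_nm, "surface_areas": areas, "contacts": contacts}


def _stage_stereo(config: RunConfig) -> dict:
    """Densities and extrapolated totals from a CSV of counted structures.

    Expected columns: structure, count, extent, kind, total_extent, n_cells.
    """
    _require_inputs(config, "counts")
    df = pd.read_csv(config.inputs["counts"])
    required = {"structure", "count", "extent", "kind", "total_extent", "n_cells"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts CSV missing columns: {sorted(missing)}")
    rows = {}
    for _, row in df.iterrows():
        d = stereology.density_estimate(row["count"], row["extent"], row["kind"])
        totals = stereology.extrapolate_totals(
            d, row["total_extent"], row["kind"], n_cells=int(row["n_cells"])
        )
        rows[str(row["structure"])] = {
            "density": d.density,
            "estimated_total": totals.estimated_total,
            "estimated_total_rounded": totals.estimated_total_rounded,
            "per_cell_rounded": totals.per_cell_rounded,
        }
    return {"structures": rows}


def _stage_entrain(config: RunConfig) -> dict:
    """SISI entrainment statistics per unit from spike CSV + epoch JSON."""
    _require_inputs(config, "spikes", "epoch")
    trains = io.load_spike_trains(config.inputs["spikes"])
    epoch = io.load_epoch(config.inputs["epoch"])
    n_boot = int(config.params.get("n_boot", 1999))
    units = {}
    for train in trains:
        try:
            isis = entrainment.pairwise_isis(train, epoch)
        except entrainment.InsufficientSpikesError as exc:
            units[str(train.unit_id)] = {"error": str(exc)}
            continue
        res = entrainment.bootstrap_entrainment_test(
            isis, epoch.period_s, n_boot=n_boot, seed=config.seed
        )
        units[str(train.unit_id)] = {
            "n_isis": int(isis.size),
            "entrainment_probability": res.entrainment_probability,
            "significant": res.significant,
            "n_boot": res.n_boot,
        }
    return {"frequency_hz": epoch.frequency_hz, "units": units}


def _stage_tune(config: RunConfig) -> dict:
    """Per-unit tuning curves from a trial-rate CSV.

    Expected columns: unit, frequency_hz, amplitude_um, trial, rate_hz.
    """
    _require_inputs(config, "rates")
    df = pd.read_csv(config.inputs["rates"])
    required = {"unit", "frequency_hz", "rate_hz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rates CSV missing columns: {sorted(missing)}")
    units = {}
    for unit, sub in df.groupby("unit"):
        means = sub.groupby("frequency_hz")["rate_hz"].mean()
        try:
            curve = tuning.fit_tuning(means.index.to_numpy(), means.to_numpy())
        except ValueError as exc:
            units[str(unit)] = {"error": str(exc)}
            continue
        units[str(unit)] = {
            "preferred_frequency_hz": curve.preferred_frequency_hz,
            "half_width_hz": curve.half_width_hz,
            "tuning_index": curve.tuning_index_value,
            "fit_r": curve.fit_r,
            "fit_p": curve.fit_p,
            "selective": curve.selective,
        }
    return {"units": units}


def _stage_psycho(config: RunConfig) -> dict:
    """Simulated staircase sessions and their binomial thresholds."""
    _require_inputs(config, "observer")
    observer = io.load_observer(config.inputs["observer"])
    freqs = config.params.get("frequency_set_hz", psychophysics.DEFAULT_FREQUENCY_SET_HZ)
    n_trials = int(config.params.get("n_trials", 300))
    start = float(config.params.get("start_amplitude_um", 10.0))
    cfg = psychophysics.StaircaseConfig(start_amplitude_um=start)
    thresholds = []
    for i, f in enumerate(freqs):
        log = psychophysics.run_session(observer, cfg, float(f), n_trials,
                                        seed=config.seed + i)
        thresholds.append(psychophysics.binomial_threshold(log))
    curve = psychophysics.sensitivity_curve(thresholds, freqs)
    return {
        "thresholds_um": {str(t.frequency_hz): t.threshold_um for t in thresholds},
        "sensitivity_curve_um": {str(k): v for k, v in curve.items()},
    }


def _stage_demo(config: RunConfig) -> dict:
    """Full synthetic validation suite (see :mod:`pacinia.demo`)."""
    return demo.run_all(config.seed)
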