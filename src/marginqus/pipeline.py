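"""Design-of-simulation study orchestration.

Runs the margin-model study — pathologies x duct positions x measurement
modes — collects spectra, reduces them to quantitative-ultrasound response
values and writes spectra CSVs, a per-case metrics table, group summaries
(mean +/- SD over duct positions) and optional bar-chart/overlay plots.

Three fidelity presets are provided:

* ``full`` — the study settings: 22-41 MHz band, 100 kHz step (190
  frequencies), mesh divisor 8, all five duct positions.  This is a large
  computation (many hours on one CPU with this solver).
* ``reduced`` — 22-41 MHz, 0.5 MHz step, divisor 6, three duct positions.
* ``desk`` — the whole band compressed by 4 (5.5-10.25 MHz, 100 kHz step,
  48 frequencies), divisor 6, geometry unchanged.  Duct-scale interference
  survives the compression (the duct is still several wavelengths wide), so
  the qualitative pathology contrasts remain observable at workstation scale.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import MarginModel, Pathology, build_margin_model, standard_offsets
from .materials import MaterialDB, builtin_db
from .meshing import generate_mesh
from .qus_metrics import (
    GroupSummary,
    MetricsResult,
    spectral_features,
    summaries_to_frame,
    summarize,
)
from .solver import PMLSpec
from .sweep import Spectrum, SweepConfig, run_sweep

__all__ = [
    "StudyConfig",
    "StudyResult",
    "preset",
    "run_study",
    "mesh_sensitivity_study",
]

MODES = ("pulse_echo", "pitch_catch")


@dataclass(frozen=True)
class StudyConfig:
    """Concrete parameters of one design-of-simulation run."""

    pathologies: tuple[Pathology, ...] = tuple(Pathology)
    offsets: tuple[tuple[float, float], ...] = tuple(standard_offsets())
    sweep: SweepConfig = field(default_factory=SweepConfig)
    mesh_divisor: int = 8
    pml: PMLSpec = field(default_factory=PMLSpec)
    pml_layers: int = 8
    output_dir: str | None = None
    make_plots: bool = False
    seed: int = 0  # fixtures only; the physics is deterministic

    def __post_init__(self):
        if not self.pathologies or not self.offsets:
            raise ValueError("pathology and offset lists must be nonempty")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "pathologies": [p.value for p in self.pathologies],
                "offsets": list(map(list, self.offsets)),
                "sweep": asdict(self.sweep),
                "mesh_divisor": self.mesh_divisor,
                "pml": asdict(self.pml),
                "pml_layers": self.pml_layers,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def preset(name: str, **overrides) -> StudyConfig:
    """Named fidelity presets: ``full``, ``reduced`` or ``desk``."""
    if name == "full":
        cfg = StudyConfig()
    elif name == "reduced":
        cfg = StudyConfig(
            offsets=tuple(standard_offsets()[:3]),
            sweep=SweepConfig(step=0.5e6),
            mesh_divisor=6,
        )
    elif name == "desk":
        cfg = StudyConfig(
            offsets=tuple(standard_offsets()[:3]),
            sweep=SweepConfig(
                f_start=5.5e6, f_stop=10.25e6, step=0.1e6, center=7.875e6
            ),
            mesh_divisor=6,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; use full, reduced or desk")
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class StudyResult:
    config: StudyConfig
    spectra: dict[tuple[str, int], Spectrum]          # (pathology, offset idx)
    metrics: pd.DataFrame                              # tidy per-case table
    summaries: list[GroupSummary]
    failures: list[dict]

    @property
    def summary_frame(self) -> pd.DataFrame:
        return summaries_to_frame(self.summaries)

    def summary(self, pathology: Pathology | str, mode: str) -> GroupSummary:
        name = pathology.value if isinstance(pathology, Pathology) else pathology
        for s in self.summaries:
            if s.pathology == name and s.mode == mode:
                return s
        raise KeyError((name, mode))


def run_study(config: StudyConfig, progress: bool = False) -> StudyResult:
    """Execute the study described by ``config``.

    Individual (pathology, offset) failures are recorded and skipped; the rest
    of the study continues.  Results are written to ``config.output_dir`` when
    set (spectra CSVs, metrics/summary tables, a manifest with the config hash,
    and plots when ``make_plots``).
    """
    db = builtin_db()
    spectra: dict[tuple[str, int], Spectrum] = {}
    failures: list[dict] = []
    rows = []
    per_group: dict[tuple[str, str], list[MetricsResult]] = {}

    for pathology in config.pathologies:
        for ioff, off in enumerate(config.offsets):
            try:
                model = build_margin_model(pathology, off)
                spec = run_sweep(
                    model,
                    db=db,
                    sweep=config.sweep,
                    wavelength_divisor=config.mesh_divisor,
                    pml=config.pml,
                    pml_layers=config.pml_layers,
                    progress=progress,
                )
            except Exception as exc:
                failures.append(
                    {
                        "pathology": pathology.value,
                        "offset": off,
                        "error": str(exc),
                        "traceback": traceback.format_exc(),
                    }
                )
                continue
            spectra[(pathology.value, ioff)] = spec
            for mode in MODES:
                r = spectral_features(spec, mode)
                per_group.setdefault((pathology.value, mode), []).append(r)
                row = {
                    "pathology": pathology.value,
                    "offset_x_m": off[0],
                    "offset_y_m": off[1],
                    "mode": mode,
                }
                row.update(
                    {k: getattr(r, k) for k in (
                        "peak_density", "mpvd", "peak_frequency",
                        "peak_magnitude", "overall_magnitude", "jaggedness",
                    )}
                )
                rows.append(row)

    summaries = [
        summarize(results, pathology=p, mode=m)
        for (p, m), results in per_group.items()
        if results
    ]
    result = StudyResult(
        config=config,
        spectra=spectra,
        metrics=pd.DataFrame(rows),
        summaries=summaries,
        failures=failures,
    )
    if config.output_dir is not None:
        _write_bundle(result)
    return result


def _write_bundle(result: StudyResult) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (pathology, ioff), spec in result.spectra.items():
        spec.to_csv(out / f"spectrum_{pathology}_pos{ioff}.csv")
    result.metrics.to_csv(out / "metrics.csv", index=False)
    result.summary_frame.to_csv(out / "summaries.csv", index=False)
    manifest = {
        "config_hash": result.config.config_hash(),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_spectra": len(result.spectra),
        "failures": [
            {k: v for k, v in f.items() if k != "traceback"}
            for f in result.failures
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if result.config.make_plots:
        _write_plots(result, out)


def _write_plots(result: StudyResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for mode, channel in (("pulse_echo", "front_abs"), ("pitch_catch", "back_abs")):
        fig, ax = plt.subplots(figsize=(7, 4))
        for (pathology, ioff), spec in result.spectra.items():
            if ioff != 0:
                continue
            ax.plot(
                np.asarray(spec.frequencies) / 1e6,
                getattr(spec, channel),
                label=pathology,
            )
        ax.set_xlabel("frequency [MHz]")
        ax.set_ylabel("|wall-averaged $p_s$| [Pa]")
        ax.set_title(f"{mode} spectra (centered duct)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"spectra_{mode}.png", dpi=130)
        plt.close(fig)

    frame = result.summary_frame
    for mode in MODES:
        sub = frame[frame["mode"] == mode]
        if sub.empty:
            continue
        for metric in ("peak_density", "mpvd"):
            fig, ax = plt.subplots(figsize=(6, 3.5))
            ax.bar(
                sub["pathology"],
                sub[f"{metric}_mean"],
                yerr=sub[f"{metric}_sd"],
                capsize=4,
            )
            ax.set_ylabel(metric)
            ax.set_title(f"{mode}: {metric} (mean +/- SD over positions)")
            fig.tight_layout()
            fig.savefig(out / f"{metric}_{mode}.png", dpi=130)
            plt.close(fig)


def mesh_sensitivity_study(
    model: MarginModel,
    frequencies: Sequence[float],
    divisors: Sequence[int] = (6, 7, 8, 9),
    db: MaterialDB | None = None,
    tolerance: float = 0.01,
    pml: PMLSpec | None = None,
) -> pd.DataFrame:
    """Wall-averaged response versus mesh divisor, with successive changes.

    For each divisor the model is meshed at ``max(frequencies)`` and solved at
    the given frequencies; the report lists the mean front/back responses and
    the relative change from the previous divisor.  The ``converged`` column
    flags the first divisor whose successive change drops below ``tolerance``.
    """
    from .materials import complex_wavenumber
    from .solver import FrequencySolver, IncidentWave, wall_average_pressure

    divisors = sorted(divisors)
    if len(divisors) < 2:
        raise ValueError("need at least two divisors to assess convergence")
    db = db or builtin_db()
    ambient = db.fluids[model.ambient_material]
    f_max = max(frequencies)
    rows = []
    prev = None
    for dv in divisors:
        # keep the physical PML thickness roughly constant across divisors so
        # the comparison isolates discretisation error
        layers = max(4, round(8 * dv / min(divisors)))
        mesh = generate_mesh(model, f_max, dv, db=db, pml_layers=layers)
        fs = FrequencySolver(mesh, db, pml)
        front, back = [], []
        for f in frequencies:
            inc = IncidentWave(1.0, complex_wavenumber(ambient, f))
            sol = fs.solve_frequency(f, inc)
            front.append(abs(wall_average_pressure(sol, "front")))
            back.append(abs(wall_average_pressure(sol, "back")))
        resp = (np.asarray(front), np.asarray(back))
        if prev is None:
            change = np.nan
        else:
            # per-channel relative L2 change: scale-invariant, so the weak
            # pulse-echo channel neither dominates nor vanishes
            change = float(max(
                np.linalg.norm(r - p) / np.linalg.norm(p)
                for r, p in zip(resp, prev)
            ))
        rows.append(
            {
                "divisor": dv,
                "front_mean": float(np.mean(front)),
                "back_mean": float(np.mean(back)),
                "rel_change_from_prev": change,
                "converged": bool(change < tolerance) if prev is not None else False,
            }
        )
        prev = resp
    return pd.DataFrame(rows)
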