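"""Run configuration schema, YAML loading, and the simulation pipeline.

Keys carry their units (``duration_months``, ``mu_gray_kpa``) to prevent
unit drift; unknown keys are rejected. A run produces per-increment VTU
files (on the output cadence), a metrics table (CSV + JSON), and a
reproducibility manifest (config echo, package version, mesh checksum,
per-increment convergence statistics).
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .mechanics import MaterialParams
from .mesh import SliceSpec, TriMesh, VentricleSpec, generate_slice
from .morphometry import Morphometer
from .scenarios import AtrophySchedule, focal_schedule, generalized_schedule
from .solver import SolverSettings, brainstem_fixation, run_schedule

__all__ = ["RunConfig", "load_config", "run_from_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VentricleConfig(_Model):
    center_mm: tuple[float, float]
    semi_axes_mm: tuple[float, float]
    angle_deg: float = 0.0


class MeshGenerateConfig(_Model):
    profile: Literal["coronal", "sagittal"] = "coronal"
    width_mm: Optional[float] = None
    height_mm: Optional[float] = None
    ribbon_thickness_mm: Optional[float] = None
    gyral_amplitude_mm: Optional[float] = None
    gyral_wavelength_mm: Optional[float] = None
    gyral_sharpness: Optional[float] = None
    deep_gray_margin_mm: Optional[float] = None
    target_edge_length_mm: Optional[float] = None
    ventricles: Optional[list[VentricleConfig]] = None
    seed: int = 0

    def to_spec(self) -> SliceSpec:
        over: dict = {"seed": self.seed}
        base = SliceSpec.coronal() if self.profile == "coronal" else SliceSpec.sagittal()
        if self.width_mm or self.height_mm:
            over["bounding_extent"] = (self.width_mm or base.bounding_extent[0],
                                       self.height_mm or base.bounding_extent[1])
        for attr, key in (("ribbon_thickness", "ribbon_thickness_mm"),
                          ("gyral_amplitude", "gyral_amplitude_mm"),
                          ("gyral_wavelength", "gyral_wavelength_mm"),
                          ("gyral_sharpness", "gyral_sharpness"),
                          ("deep_gray_margin", "deep_gray_margin_mm"),
                          ("target_edge_length", "target_edge_length_mm")):
            val = getattr(self, key)
            if val is not None:
                over[attr] = val
        if self.ventricles is not None:
            over["ventricles"] = tuple(
                VentricleSpec(v.center_mm, v.semi_axes_mm, v.angle_deg)
                for v in self.ventricles)
        factory = SliceSpec.coronal if self.profile == "coronal" else SliceSpec.sagittal
        return factory(**over)


class MeshConfig(_Model):
    generate: Optional[MeshGenerateConfig] = None
    file: Optional[str] = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.generate is None) == (self.file is None):
            raise ValueError("mesh config needs exactly one of 'generate' or 'file'")
        return self


class MaterialConfig(_Model):
    mu_gray_kpa: float = 2.07
    mu_white_kpa: float = 1.15
    kappa_ratio: float = 100.0

    def to_params(self) -> MaterialParams:
        return MaterialParams(mu_gray=self.mu_gray_kpa,
                              mu_white=self.mu_white_kpa,
                              kappa_ratio=self.kappa_ratio)


class ScheduleConfig(_Model):
    mode: Literal["generalized", "focal"] = "generalized"
    duration_months: float = 48.0
    n_increments: int = Field(default=48, ge=1)
    stepping: Literal["endpoint", "rate"] = "endpoint"
    # generalized
    delta_upsilon_gray: float = -0.20
    delta_upsilon_white: float = -0.10
    rate_gray_per_month: float = -0.004
    rate_white_per_month: float = -0.002
    # focal
    target_region: Optional[str] = None
    delta_upsilon: Optional[float] = None

    def to_schedule(self, mesh: TriMesh) -> AtrophySchedule:
        if self.mode == "generalized":
            return generalized_schedule(
                delta_gray=self.delta_upsilon_gray,
                delta_white=self.delta_upsilon_white,
                duration=self.duration_months,
                n_increments=self.n_increments,
                stepping=self.stepping,
                rate_gray=self.rate_gray_per_month,
                rate_white=self.rate_white_per_month)
        if self.target_region is None or self.delta_upsilon is None:
            raise ConfigError(
                "focal schedule needs 'target_region' and 'delta_upsilon'")
        available = tuple(np.unique(mesh.element_region)) + tuple(
            s for s in np.unique(mesh.element_subregion) if s)
        return focal_schedule(self.target_region, self.delta_upsilon,
                              duration=self.duration_months,
                              n_increments=self.n_increments,
                              available_regions=available)


class SolverConfig(_Model):
    newton_rel_tol: float = 1e-8
    newton_abs_tol: float = 1e-10
    max_newton_iters: int = 25
    max_increment_bisections: int = 3

    def to_settings(self) -> SolverSettings:
        return SolverSettings(newton_rel_tol=self.newton_rel_tol,
                              newton_abs_tol=self.newton_abs_tol,
                              max_newton_iters=self.max_newton_iters,
                              max_increment_bisections=self.max_increment_bisections)


class OutputConfig(_Model):
    directory: str = "atrophyfem-out"
    cadence: int = Field(default=1, ge=1)  # write fields every k increments
    write_vtu: bool = True


class RunConfig(_Model):
    mesh: MeshConfig
    schedule: ScheduleConfig  # required: a run without a schedule is meaningless
    material: MaterialConfig = MaterialConfig()
    solver: SolverConfig = SolverConfig()
    output: OutputConfig = OutputConfig()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (fail-fast on unknown keys)."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: invalid YAML: {e}") from e
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return RunConfig(**doc)
    except Exception as e:
        raise ConfigError(f"{path}: {e}") from e


def _mesh_checksum(mesh: TriMesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.node_coords).tobytes())
    h.update(np.ascontiguousarray(mesh.elements).tobytes())
    h.update("".join(mesh.element_region.tolist()).encode())
    return h.hexdigest()


def build_mesh(cfg: RunConfig) -> TriMesh:
    if cfg.mesh.generate is not None:
        return generate_slice(cfg.mesh.generate.to_spec())
    from .io import read_mesh
    return read_mesh(cfg.mesh.file)


def run_from_config(cfg: RunConfig, out_dir=None):
    """Execute a configured run; returns (mesh, states, reports, manifest)."""
    from .io import write_vtu

    mesh = build_mesh(cfg)
    params = cfg.material.to_params()
    schedule = cfg.schedule.to_schedule(mesh)
    settings = cfg.solver.to_settings()
    bcs = brainstem_fixation(mesh)
    morph = Morphometer(mesh)
    out = Path(out_dir or cfg.output.directory)
    out.mkdir(parents=True, exist_ok=True)

    states, reports = run_schedule(mesh, schedule, params, bcs, settings,
                                   report_fn=morph.report)
    rows = [r.as_row() for r in reports]
    df = pd.DataFrame(rows)
    df.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
    (out / "metrics.json").write_text(json.dumps(rows, indent=1))

    if cfg.output.write_vtu:
        for st in states:
            if st.increment % cfg.output.cadence and st.increment != len(states):
                continue
            write_vtu(out / f"increment_{st.increment:04d}.vtu", mesh,
                      point_data={"displacement_mm": st.u},
                      cell_data={"upsilon": st.upsilon, "J": st.J,
                                 "Je": st.Je, "von_mises_kpa": st.von_mises})

    manifest = {
        "artifact_version": __version__,
        "config": cfg.model_dump(),
        "mesh_checksum_sha256": _mesh_checksum(mesh),
        "n_nodes": mesh.n_nodes,
        "n_elements": mesh.n_elements,
        "increments": [
            {"increment": st.increment, "time_months": st.time,
             "newton_iters": st.newton_iters,
             "final_residual": st.residual_history[-1] if st.residual_history else None,
             "max_displacement_mm": float(np.linalg.norm(st.u, axis=1).max()),
             "max_von_mises_kpa": float(st.von_mises.max())}
            for st in states],
        "platform": {"python": platform.python_version(),
                     "machine": platform.machine()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return mesh, states, reports, manifest
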