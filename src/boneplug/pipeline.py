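"""Configuration and orchestration of the whole pipeline.

``RunConfig`` is a declarative, YAML-round-trippable description of one run
(assembly dimensions, materials, load case, thresholds, sweep moduli, slice
band, noise model, seed).  ``run_pipeline`` executes mesh build -> solve ->
SED -> remodelling classification for every stem modulus and writes VTK,
CSV and log artefacts; ``validate_against_fixtures`` recomputes the
published validation statistics from the packaged reference dataset.

Units: SI in files; microstrain and mm in human-readable reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fe, vtkio
from .geometry import AssemblySpec, SliceSpec, build_assembly_mesh
from .loads import (LoadCase, Orientation, bodyweight_load, lc1, lc2,
                    transform_axial_load, equivalent_face_loads,
                    DONOR_MASS_KG, STANDARD_GRAVITY, IN_VITRO_ORIENTATION)
from .materials import default_cards, STEM_MODULI_SWEEP
from .remodelling import Thresholds, stiffness_sweep, trend
from .synthetic import NoiseModel, reference_tables
from .validation import PairedSample, lins_ccc, percent_error

__all__ = ["RunConfig", "run_pipeline", "validate_against_fixtures",
           "default_gauge_sites"]

log = logging.getLogger(__name__)


def default_gauge_sites(mesh_spec: AssemblySpec,
                        gauge_length: float = 0.004) -> list[fe.GaugeSite]:
    """Four virtual gauge sites mirroring the in vitro layout: distal and
    proximal pairs on the medial (-X) and lateral (+X) outer bone surface.

    The averaging footprint defaults to 4 mm so it always contains surface
    nodes at desk-scale mesh resolution.
    """
    L = mesh_spec.residual_length
    y_distal, y_proximal = 0.25 * L, 0.75 * L
    return [
        fe.GaugeSite(y_distal, 180.0, gauge_length, "gauge1"),   # medial distal
        fe.GaugeSite(y_proximal, 180.0, gauge_length, "gauge2"),  # medial proximal
        fe.GaugeSite(y_distal, 0.0, gauge_length, "gauge3"),     # lateral distal
        fe.GaugeSite(y_proximal, 0.0, gauge_length, "gauge4"),   # lateral proximal
    ]


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run (SI units, degrees)."""

    assembly: AssemblySpec = field(default_factory=lambda: AssemblySpec(
        element_edge_length=0.003))
    slices: SliceSpec = field(default_factory=SliceSpec)
    thresholds: Thresholds = field(default_factory=Thresholds)
    load_case: str = "lc2"
    custom_load: tuple[float, float, float] | None = None
    sweep_moduli: tuple[float, ...] = STEM_MODULI_SWEEP
    noise: NoiseModel = field(default_factory=NoiseModel)
    output_dir: str = "boneplug_out"
    seed: int = 0
    verbosity: str = "INFO"

    def resolve_load_case(self) -> LoadCase:
        if self.load_case == "lc1":
            return lc1()
        if self.load_case == "lc2":
            return lc2()
        if self.load_case == "custom":
            if self.custom_load is None:
                raise ValueError("custom load case requires custom_load components")
            return LoadCase(*self.custom_load, name="custom")
        raise ValueError(f"unknown load case {self.load_case!r}")

    # ---- YAML round trip --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise"] = {"gauge_sd_ue": list(self.noise.gauge_sd_ue),
                      "dic_sd_m": self.noise.dic_sd_m, "seed": self.noise.seed}
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "assembly" in d:
            d["assembly"] = AssemblySpec(**{k: (tuple(v) if isinstance(v, list) else v)
                                            for k, v in d["assembly"].items()})
        if "slices" in d:
            d["slices"] = SliceSpec(**d["slices"])
        if "thresholds" in d:
            d["thresholds"] = Thresholds(**d["thresholds"])
        if "noise" in d:
            n = dict(d["noise"])
            n["gauge_sd_ue"] = tuple(n.get("gauge_sd_ue", (5.2, 8.5, 2.9, 12.7)))
            d["noise"] = NoiseModel(**n)
        if "sweep_moduli" in d:
            d["sweep_moduli"] = tuple(d["sweep_moduli"])
        if d.get("custom_load") is not None:
            d["custom_load"] = tuple(d["custom_load"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and write the artefact bundle.

    Outputs (under ``config.output_dir``): mesh + baseline SED field VTK,
    per-slice remodelling CSV per stem modulus, sweep summary CSV,
    validation CSV, and a plain-text log.  Identical config and seed yield
    an identical bundle.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("boneplug")
    root.addHandler(handler)
    root.setLevel(config.verbosity)
    artefacts: dict[str, Path] = {"log": out / "run.log"}
    try:
        log.info("building mesh (edge length %.4g m)",
                 config.assembly.element_edge_length)
        mesh = build_assembly_mesh(config.assembly, slices=config.slices)
        log.info("mesh: %d elements, %d nodes", mesh.n_elements, mesh.n_nodes)
        lc = config.resolve_load_case()
        log.info("load case %s: F = (%.2f, %.2f, %.2f) N", lc.name, *lc.force)

        materials = default_cards()
        sweep = stiffness_sweep(config.assembly, materials, lc,
                                list(config.sweep_moduli), slices=config.slices,
                                thresholds=config.thresholds, mesh=mesh)

        slice_rows = []
        for E, report in sweep.reports.items():
            t = report.table.copy()
            t.insert(0, "stem_modulus", E)
            slice_rows.append(t)
        slice_csv = out / "slice_report.csv"
        pd.concat(slice_rows, ignore_index=True).to_csv(slice_csv, index=False)
        artefacts["slice_report"] = slice_csv

        sweep_csv = out / "sweep_summary.csv"
        sweep.summary.to_csv(sweep_csv, index=False)
        artefacts["sweep_summary"] = sweep_csv
        peaks_csv = out / "peak_sed_changes.csv"
        sweep.peak_changes.to_csv(peaks_csv, index=False)
        artefacts["peak_sed_changes"] = peaks_csv

        # baseline field export (middle modulus = as-designed stem)
        baseline = sorted(config.sweep_moduli)[len(config.sweep_moduli) // 2]
        mats = dict(materials)
        mats["stem"] = materials["stem"].with_modulus(baseline)
        system = fe.assemble(mesh, mats)
        u = fe.solve(system, equivalent_face_loads(lc, mesh))
        tensors = fe.strain_stress(mesh, mats, u, elem_C=system.elem_C)
        sed_field = fe.sed(tensors)
        vtk_path = out / "assembly_fields.vtk"
        vtkio.write_vtk(vtk_path, mesh,
                        point_data={"displacement": u.u},
                        cell_data={"sed": sed_field.U,
                                   "strain_yy": tensors.strain[:, 1],
                                   "stress_yy": tensors.stress[:, 1]})
        artefacts["fields_vtk"] = vtk_path

        gauges = default_gauge_sites(config.assembly)
        gauge_rows = [{"gauge": g.label,
                       "axial_position_m": g.axial_position,
                       "angle_deg": g.angle_deg,
                       "strain_ue": fe.virtual_gauge(mesh, tensors, g)}
                      for g in gauges]
        gauge_csv = out / "virtual_gauges.csv"
        pd.DataFrame(gauge_rows).to_csv(gauge_csv, index=False)
        artefacts["virtual_gauges"] = gauge_csv

        validation = validate_against_fixtures()
        val_csv = out / "validation_report.csv"
        validation.to_csv(val_csv, index=False)
        artefacts["validation_report"] = val_csv

        config.to_yaml(out / "config.yaml")
        artefacts["config"] = out / "config.yaml"
        log.info("pipeline complete: %d artefacts", len(artefacts))
    except Exception:
        log.exception("pipeline stage failed")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return artefacts


def validate_against_fixtures(tol_2dp: float = 0.005) -> pd.DataFrame:
    """Recompute every published validation statistic from the packaged
    reference dataset and report computed vs printed values.

    Covers: the four gauge percentage errors, the three displacement-span
    percentage errors and their average, the span concordance coefficient,
    the load-case-1 force-component reconstruction, and the body-weight
    load scalings.
    """
    ref = reference_tables()
    rows = []

    def add(name, computed, printed, decimals):
        rows.append({"quantity": name, "computed": round(float(computed), 6),
                     "printed": printed,
                     "pass": abs(float(computed) - printed) < 0.5 * 10 ** (-decimals) + 1e-12})

    g = ref["gauges"]
    for lbl, vitro, silico, err in zip(g["labels"], g["strain_invitro_ue"],
                                       g["strain_insilico_ue"], g["error_pct"]):
        add(f"strain_error_pct_{lbl}", percent_error(vitro, silico), err, 2)
    d = ref["displacement_spans"]
    errs = []
    for ax, vitro, silico, err in zip(d["axes"], d["invitro_mm"],
                                      d["insilico_mm"], d["error_pct"]):
        e = percent_error(vitro, silico)
        errs.append(e)
        add(f"span_error_pct_{ax}", e, err, 2)
    add("span_error_avg_pct", np.mean(errs), 7.0, 0)
    ccc = lins_ccc(PairedSample(np.array(d["invitro_mm"]), np.array(d["insilico_mm"])))
    add("span_ccc", ccc, d["ccc"], 3)

    bw = ref["body_weight"]
    F1 = bodyweight_load(bw["mass_kg"], bw["g"])
    add("bw_load_1x_N", F1, bw["load_1bw_N"], 1)
    add("bw_load_3p5x_N", 3.5 * F1, bw["load_range_N"][1], 1)
    FX, FY, FZ = transform_axial_load(F1, IN_VITRO_ORIENTATION)
    for comp, val in zip(("FX", "FY", "FZ"), (FX, FY, FZ)):
        add(f"lc1_{comp}_N", val, ref["load_cases"]["lc1"][comp], 2)
    return pd.DataFrame(rows)
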