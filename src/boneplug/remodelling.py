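"""Adaptive bone-remodelling classification from strain energy density.

Under the mechanostat hypothesis the periprosthetic bone keeps the specific
strain energy SED/rho (J g^-1) inside a homeostatic band; cross-sectional
area below the band is scored as likely resorption, above as likely
apposition.  The classification is evaluated per slice of the bone layer
and compared across implant stem stiffnesses to quantify stress shielding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import fe
from .geometry import AssemblyMesh, AssemblySpec, SliceSpec, build_assembly_mesh
from .loads import LoadCase, equivalent_face_loads
from .materials import MaterialCard

__all__ = [
    "Thresholds",
    "SliceReport",
    "SweepResult",
    "sed_bounds",
    "classify",
    "stiffness_sweep",
    "trend",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Homeostatic SED/rho band (J g^-1) and the apparent density
    (g cm^-3) that converts it to volumetric SED bounds (J m^-3)."""

    lower: float = 0.0036
    upper: float = 0.0044
    density: float = 1.8

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError("need 0 < lower < upper")
        if self.density <= 0:
            raise ValueError("density must be positive")


def sed_bounds(t: Thresholds) -> tuple[float, float]:
    """Volumetric SED bounds (J m^-3): threshold (J g^-1) x density (g m^-3).

    1 g cm^-3 = 1e6 g m^-3, so the defaults give (6480, 7920) J m^-3.
    """
    rho_g_per_m3 = t.density * 1e6
    return (t.lower * rho_g_per_m3, t.upper * rho_g_per_m3)


@dataclass
class SliceReport:
    """Per-slice area fractions of the bone layer below / within / above the
    homeostatic SED band (below -> resorption, above -> apposition)."""

    table: pd.DataFrame  # columns: slice, area, fraction_below, fraction_within, fraction_above
    thresholds: Thresholds

    def fractions(self, which: str) -> np.ndarray:
        return self.table[f"fraction_{which}"].to_numpy()


def classify(sed_field: fe.SEDField, mesh: AssemblyMesh,
             t: Thresholds) -> SliceReport:
    """Classify each bone-layer slice by area-weighted SED against the band.

    Element area contributions are element volume / element axial extent
    (exact on the layer-aligned structured mesh).  Fractions sum to 1 in
    every slice.
    """
    if mesh.slice_spec is None or not np.any(mesh.slice_index > 0):
        raise ValueError("mesh has no slice indices; call assign_slices first")
    lo, hi = sed_bounds(t)
    n_slices = mesh.slice_spec.number_of_slices
    coords = mesh.element_coords()
    height = coords[:, :, 1].max(axis=1) - coords[:, :, 1].min(axis=1)
    area = mesh.element_volumes() / height

    rows = []
    for k in range(1, n_slices + 1):
        sel = mesh.slice_index == k
        if not np.any(sel):
            raise ValueError(f"slice {k} is empty")
        a = area[sel]
        U = sed_field.U[sel]
        total = a.sum()
        below = a[U < lo].sum() / total
        above = a[U > hi].sum() / total
        rows.append({
            "slice": k,
            "area": total,
            "fraction_below": below,
            "fraction_within": 1.0 - below - above,
            "fraction_above": above,
        })
    return SliceReport(table=pd.DataFrame(rows), thresholds=t)


@dataclass
class SweepResult:
    """Stem-stiffness sweep: one slice report per stem modulus plus peak and
    mean SED summaries, and pairwise peak-SED percentage differences."""

    reports: dict[float, SliceReport]
    summary: pd.DataFrame       # per modulus: peak/mean SED in bone_layer, peak on outer surface
    peak_changes: pd.DataFrame  # pairwise % difference of peak bone-layer SED


def stiffness_sweep(spec: AssemblySpec, materials: dict[str, MaterialCard],
                    lc: LoadCase, moduli: list[float],
                    slices: SliceSpec | None = None,
                    thresholds: Thresholds | None = None,
                    mesh: AssemblyMesh | None = None) -> SweepResult:
    """Re-solve the assembly for each stem Young's modulus (same mesh, all
    other properties unchanged) and classify remodelling per slice.

    ``moduli`` must be positive and distinct; a solver failure is re-raised
    naming the offending modulus.
    """
    moduli = [float(E) for E in moduli]
    if any(E <= 0 for E in moduli):
        raise ValueError("stem moduli must be positive")
    if len(set(moduli)) != len(moduli):
        raise ValueError("stem moduli must be distinct")
    slices = slices or SliceSpec()
    thresholds = thresholds or Thresholds()
    if mesh is None:
        mesh = build_assembly_mesh(spec, slices=slices)
    f = equivalent_face_loads(lc, mesh)

    bone_sel = mesh.part_elements("bone_layer")
    outer_sel = mesh.part_elements("outer_bone")
    vol = mesh.element_volumes()

    reports: dict[float, SliceReport] = {}
    summary_rows = []
    for E in moduli:
        mats = dict(materials)
        mats["stem"] = materials["stem"].with_modulus(E)
        try:
            system = fe.assemble(mesh, mats)
            u = fe.solve(system, f)
        except Exception as exc:
            raise RuntimeError(f"solve failed for stem modulus {E:.3g} Pa: {exc}") from exc
        tensors = fe.strain_stress(mesh, mats, u, elem_C=system.elem_C)
        sed_field = fe.sed(tensors)
        reports[E] = classify(sed_field, mesh, thresholds)
        summary_rows.append({
            "stem_modulus": E,
            "peak_sed_bone_layer": float(sed_field.U[bone_sel].max()),
            "mean_sed_bone_layer": float(np.average(sed_field.U[bone_sel],
                                                    weights=vol[bone_sel])),
            "peak_sed_outer_bone": float(sed_field.U[outer_sel].max()),
        })
    summary = pd.DataFrame(summary_rows)

    pairs = []
    for i, Ei in enumerate(moduli):
        for Ej in moduli[i + 1:]:
            pi = summary.loc[summary.stem_modulus == Ei, "peak_sed_bone_layer"].iloc[0]
            pj = summary.loc[summary.stem_modulus == Ej, "peak_sed_bone_layer"].iloc[0]
            pairs.append({"modulus_a": Ei, "modulus_b": Ej,
                          "peak_sed_change_pct": 100.0 * (pi - pj) / pj})
    return SweepResult(reports=reports, summary=summary,
                       peak_changes=pd.DataFrame(pairs))


def trend(report: SliceReport, slice_range: tuple[int, int] = (1, 10)) -> dict[str, float]:
    """Mean distal-to-proximal change (%) of the apposition and resorption
    fractions: mean of per-step relative changes over the slice range.

    Steps whose baseline fraction is zero are skipped (logged), mirroring
    the undefined relative change.
    """
    tab = report.table
    lo, hi = slice_range
    sel = tab[(tab["slice"] >= lo) & (tab["slice"] <= hi)]
    if len(sel) < 2:
        raise ValueError("need at least two slices for a trend")
    out = {}
    for which, key in (("above", "apposition_mean_change_pct"),
                       ("below", "resorption_mean_change_pct")):
        f = sel[f"fraction_{which}"].to_numpy()
        steps = []
        for a, b in zip(f[:-1], f[1:]):
            if a == 0.0:
                log.info("trend: skipping step with zero baseline fraction_%s", which)
                continue
            steps.append((b - a) / a)
        out[key] = float(100.0 * np.mean(steps)) if steps else float("nan")
    return out
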