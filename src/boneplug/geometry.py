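"""Parametric bone-plug assembly geometry and structured hexahedral meshing.

The modelled assembly is a set of concentric cylinders along the global Y
axis (X lateral+, Y proximal+, Z anterior+):

* ``stem``       -- solid tapered implant stem (distal diameter > proximal),
* ``cement``     -- PMMA mantle, 1 mm thick distally, thickening proximally,
* ``bone_layer`` -- 2 mm periprosthetic cortical bone layer,
* ``outer_bone`` -- parametric outer cortical wall standing in for the
  residual femur, which continues proximally past the stem tip as a tube up
  to the residual length.

The distal plane (y = 0) is the osteotomy plane; the stem spigot is fixed
there.  Cross-sections are meshed with a square-core ("butterfly") disk
quadrangulation for the stem plus concentric rings of quadrilaterals for
the annular parts, extruded axially into 8-node hexahedra.  All radii are
scaled by a single area-preserving factor so that every meshed part volume
equals the analytic frustum/shell volume to roundoff, at any resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _hex

__all__ = [
    "GeometryError",
    "AssemblySpec",
    "SliceSpec",
    "AssemblyMesh",
    "Discretisation",
    "default_discretisation",
    "build_assembly_mesh",
    "refine",
    "assign_slices",
    "analytic_part_volumes",
]

PART_NAMES = ("stem", "cement", "bone_layer", "outer_bone")
PART_ID = {name: i for i, name in enumerate(PART_NAMES)}


class GeometryError(ValueError):
    """Raised for inconsistent assembly dimensions or slice placement."""


@dataclass(frozen=True)
class AssemblySpec:
    """Dimensions and discretisation of the parametric assembly (SI metres)."""

    stem_length: float = 0.12
    stem_diameter_distal: float = 0.012
    stem_diameter_proximal: float = 0.009
    cement_thickness_distal: float = 0.001
    cement_taper_rule: str = "linear_increase_proximal"
    cement_thickness_proximal: float = 0.002
    bone_layer_thickness: float = 0.002
    outer_bone_wall_thickness: float = 0.005
    residual_length: float = 0.201
    collar_diameter: float = 0.018
    element_edge_length: float = 0.000625
    element_order: str = "linear"
    n_sectors: int | None = None  # override circumferential sector count

    def __post_init__(self) -> None:
        for attr in ("stem_length", "stem_diameter_distal", "stem_diameter_proximal",
                     "cement_thickness_distal", "cement_thickness_proximal",
                     "bone_layer_thickness", "outer_bone_wall_thickness",
                     "residual_length", "collar_diameter", "element_edge_length"):
            if getattr(self, attr) <= 0:
                raise GeometryError(f"{attr} must be positive")
        if self.stem_diameter_proximal > self.stem_diameter_distal:
            raise GeometryError("stem taper must narrow proximally "
                                "(proximal diameter <= distal diameter)")
        if self.stem_length > self.residual_length:
            raise GeometryError("stem_length must not exceed residual_length")
        if self.cement_taper_rule not in ("uniform", "linear_increase_proximal"):
            raise GeometryError(f"unknown cement_taper_rule {self.cement_taper_rule!r}")
        if (self.cement_taper_rule == "linear_increase_proximal"
                and self.cement_thickness_proximal < self.cement_thickness_distal):
            raise GeometryError("proximal cement thickness must be >= distal thickness")
        if self.element_order not in ("linear", "quadratic"):
            raise GeometryError(f"unknown element_order {self.element_order!r}")

    # ---- radii as functions of axial position -------------------------------
    def stem_radius(self, y):
        """Stem radius at axial position(s) y (linear distal->proximal taper)."""
        f = np.clip(np.asarray(y, dtype=float) / self.stem_length, 0.0, 1.0)
        r0 = 0.5 * self.stem_diameter_distal
        r1 = 0.5 * self.stem_diameter_proximal
        return r0 + (r1 - r0) * f

    def cement_thickness(self, y):
        f = np.clip(np.asarray(y, dtype=float) / self.stem_length, 0.0, 1.0)
        t0 = self.cement_thickness_distal
        if self.cement_taper_rule == "uniform":
            return np.broadcast_to(t0, f.shape).copy() if f.shape else np.float64(t0)
        return t0 + (self.cement_thickness_proximal - t0) * f

    def cement_outer_radius(self, y):
        return self.stem_radius(y) + self.cement_thickness(y)

    def bone_layer_outer_radius(self, y):
        return self.cement_outer_radius(y) + self.bone_layer_thickness

    def outer_radius(self, y):
        return self.bone_layer_outer_radius(y) + self.outer_bone_wall_thickness


@dataclass(frozen=True)
class SliceSpec:
    """Equidistant cross-section band in the periprosthetic bone layer.

    Slice 1 starts at ``origin`` (distal end of the bone layer, the plane
    adjacent to the osteotomy face); slice k covers
    [origin + (k-1) * spacing, origin + k * spacing).
    """

    number_of_slices: int = 11
    spacing: float = 0.00109
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.number_of_slices < 1:
            raise GeometryError("need at least one slice")
        if self.spacing <= 0:
            raise GeometryError("slice spacing must be positive")
        if self.origin < 0:
            raise GeometryError("slice origin must be >= 0")

    @property
    def band(self) -> tuple[float, float]:
        return (self.origin, self.origin + self.number_of_slices * self.spacing)


@dataclass
class AssemblyMesh:
    """Labelled structured hexahedral mesh of the assembly."""

    nodes: np.ndarray            # (nn, 3) coordinates, m
    elems: np.ndarray            # (ne, 8) connectivity, VTK hex order
    part: np.ndarray             # (ne,) part id into PART_NAMES
    layer: np.ndarray            # (ne,) axial layer index (0 = most distal)
    slice_index: np.ndarray      # (ne,) 1-based slice id, -1 outside band
    node_sets: dict[str, np.ndarray]
    spec: AssemblySpec
    disc: "Discretisation | None" = None
    slice_spec: SliceSpec | None = None
    _volumes: np.ndarray | None = field(default=None, repr=False)
    _centroids: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elems.shape[0]

    def element_coords(self) -> np.ndarray:
        return self.nodes[self.elems]

    def element_volumes(self) -> np.ndarray:
        if self._volumes is None:
            self._volumes = _hex.volumes(self.element_coords())
        return self._volumes

    def element_centroids(self) -> np.ndarray:
        if self._centroids is None:
            self._centroids = _hex.centroids(self.element_coords())
        return self._centroids

    def centroid_cylindrical(self) -> np.ndarray:
        """(ne, 3) array of (r, theta, y) at element centroids."""
        c = self.element_centroids()
        r = np.hypot(c[:, 0], c[:, 2])
        theta = np.arctan2(c[:, 2], c[:, 0])
        return np.column_stack([r, theta, c[:, 1]])

    def part_volumes(self) -> dict[str, float]:
        v = self.element_volumes()
        return {name: float(v[self.part == pid].sum()) for name, pid in PART_ID.items()}

    def part_elements(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.part == PART_ID[name])


# ---------------------------------------------------------------------------
# cross-section template: square-core disk + concentric rings
# ---------------------------------------------------------------------------

def _core_template(m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unit-disk core template with m divisions per square side.

    Returns (core_uv, core_quads, boundary_ids, boundary_theta): node
    positions of the mapped square on the closed unit disk, quad
    connectivity, the ids of boundary nodes in counter-clockwise order, and
    their azimuths.  The elliptical map (u, v) -> (u sqrt(1 - v^2/2),
    v sqrt(1 - u^2/2)) sends the square boundary exactly onto the unit
    circle.
    """
    lin = np.linspace(-1.0, 1.0, m + 1)
    u, v = np.meshgrid(lin, lin, indexing="ij")
    x = u * np.sqrt(1.0 - 0.5 * v ** 2)
    z = v * np.sqrt(1.0 - 0.5 * u ** 2)
    core_uv = np.column_stack([x.ravel(), z.ravel()])

    def gid(i, j):
        return i * (m + 1) + j

    quads = []
    for i in range(m):
        for j in range(m):
            quads.append([gid(i, j), gid(i + 1, j), gid(i + 1, j + 1), gid(i, j + 1)])
    quads = np.array(quads)

    # counter-clockwise boundary walk starting at corner (u, v) = (1, -1)
    boundary = []
    for j in range(m):                       # side u = +1, v: -1 -> +1
        boundary.append(gid(m, j))
    for i in range(m, 0, -1):                # side v = +1, u: +1 -> -1
        boundary.append(gid(i, m))
    for j in range(m, 0, -1):                # side u = -1, v: +1 -> -1
        boundary.append(gid(0, j))
    for i in range(m):                       # side v = -1, u: -1 -> +1
        boundary.append(gid(i, 0))
    boundary = np.array(boundary)
    theta = np.arctan2(core_uv[boundary, 1], core_uv[boundary, 0])
    # unwrap to a strictly increasing sequence starting near -45 degrees
    theta = np.unwrap(theta)
    return core_uv, quads, boundary, theta


@dataclass(frozen=True)
class Discretisation:
    """Structured element counts: circumferential sectors, radial divisions
    per part, and axial divisions per region (pre-slice-band, slice band,
    post-band, proximal tube).  ``refine`` scales these counts directly so
    successive meshes are exactly self-similar (nested), as Richardson
    extrapolation assumes."""

    n_sect: int
    n_r: tuple[int, int, int, int]          # per part in PART_NAMES order
    n_ax: tuple[int, int, int, int]         # pre-band, band, post-band, tube

    def scaled(self, factor: float) -> "Discretisation":
        s = lambda n: max(1, round(n / factor)) if n > 0 else 0
        return Discretisation(
            n_sect=max(8, 4 * max(1, round(self.n_sect / 4 / factor))),
            n_r=tuple(s(n) for n in self.n_r),
            # the slice band keeps one element layer per slice
            n_ax=(s(self.n_ax[0]), self.n_ax[1], s(self.n_ax[2]), s(self.n_ax[3])),
        )


def default_discretisation(spec: AssemblySpec,
                           slices: SliceSpec | None) -> Discretisation:
    """Counts targeting ``spec.element_edge_length``, with the worst
    circumferential arc length held within 3x the edge length (element
    aspect ratio <= 3) and at least one element through every layer."""
    h = spec.element_edge_length
    r_out_max = float(np.max(spec.outer_radius(np.linspace(0, spec.stem_length, 9))))
    if spec.n_sectors is not None:
        n_sect = int(spec.n_sectors)
        if n_sect < 8 or n_sect % 4:
            raise GeometryError("n_sectors must be a multiple of 4, >= 8")
    else:
        n_sect = max(16, int(np.ceil(2 * np.pi * r_out_max / (3 * h))))
        n_sect = int(4 * np.ceil(n_sect / 4))
    core_frac = 0.5
    r_s0 = float(spec.stem_radius(0.0))
    n_r = (max(1, round((1 - core_frac) * r_s0 / h)),
           max(1, round(spec.cement_thickness_distal / h)),
           max(1, round(spec.bone_layer_thickness / h)),
           max(1, round(spec.outer_bone_wall_thickness / h)))
    L, Lr = spec.stem_length, spec.residual_length
    nax = lambda a, b: 0 if b - a <= 1e-12 else max(1, round((b - a) / h))
    if slices is not None:
        b0, b1 = slices.band
        if b1 > L + 1e-12:
            raise GeometryError("slice band exceeds the bone layer extent")
        n_ax = (nax(0.0, b0), slices.number_of_slices, nax(b1, L), nax(L, Lr))
    else:
        n_ax = (0, 0, nax(0.0, L), nax(L, Lr))
    return Discretisation(n_sect=n_sect, n_r=n_r, n_ax=n_ax)


def _axial_stations(spec: AssemblySpec, slices: SliceSpec | None,
                    disc: Discretisation) -> tuple[np.ndarray, np.ndarray]:
    """Axial node stations for the plug region [0, L_stem] and the proximal
    tube region (L_stem, L_res].  Inside the slice band each slice is an
    integer number of element layers."""
    L, Lr = spec.stem_length, spec.residual_length

    def seg(a, b, n):
        if n == 0 or b - a <= 1e-12:
            return np.array([])
        return np.linspace(a, b, n + 1)[1:]

    pts = [np.array([0.0])]
    if slices is not None:
        b0, b1 = slices.band
        pts.append(seg(0.0, b0, disc.n_ax[0]))
        pts.append(seg(b0, b1, disc.n_ax[1]))
        pts.append(seg(b1, L, disc.n_ax[2]))
    else:
        pts.append(seg(0.0, L, disc.n_ax[2]))
    plug = np.concatenate(pts)
    tube = seg(L, Lr, disc.n_ax[3])
    return plug, tube


def build_assembly_mesh(spec: AssemblySpec,
                        slices: SliceSpec | None = None,
                        disc: Discretisation | None = None) -> AssemblyMesh:
    """Build the conforming structured hex mesh of the four-part assembly.

    All part interfaces share nodes (fully bonded).  If ``slices`` is given
    the axial stations are aligned with the slice planes and slice indices
    are assigned to the bone-layer elements.  ``disc`` overrides the
    structured counts derived from the spec's element edge length.
    """
    if spec.element_order == "quadratic":
        raise NotImplementedError(
            "quadratic (20-node) hexahedra are not implemented; use "
            "element_order='linear' (convergence is controlled by the "
            "Richardson criterion)")
    if disc is None:
        disc = default_discretisation(spec, slices)
    n_sect = disc.n_sect
    m = n_sect // 4

    core_uv, core_quads, boundary_ids, theta = _core_template(m)
    n_core = core_uv.shape[0]

    # area-preserving radius scale: polygon through the boundary azimuths has
    # exactly the area of the circle it approximates
    dtheta = np.diff(np.concatenate([theta, [theta[0] + 2 * np.pi]]))
    kappa = float(np.sqrt(2 * np.pi / np.sum(np.sin(dtheta))))

    core_frac = 0.5
    n_r = dict(zip(PART_NAMES, disc.n_r))
    n_circ_full = 1 + sum(n_r.values())          # circles incl. core boundary
    n_circ_tube = 1 + n_r["outer_bone"]

    plug_y, tube_y = _axial_stations(spec, slices, disc)
    n_plug, n_tube = len(plug_y), len(tube_y)

    def circle_radii(y: float) -> np.ndarray:
        r_s = float(spec.stem_radius(y))
        bounds = [core_frac * r_s, r_s,
                  float(spec.cement_outer_radius(y)),
                  float(spec.bone_layer_outer_radius(y)),
                  float(spec.outer_radius(y))]
        radii = [bounds[0]]
        for k, zone in enumerate(PART_NAMES):
            seg = np.linspace(bounds[k], bounds[k + 1], n_r[zone] + 1)[1:]
            radii.extend(seg.tolist())
        return kappa * np.array(radii)

    cos_t, sin_t = np.cos(theta), np.sin(theta)

    # ---- nodes ------------------------------------------------------------
    nodes = []
    full_core_base = np.empty(n_plug, dtype=int)    # node id offsets
    full_ring_base = np.empty(n_plug, dtype=int)
    tube_base = np.empty(n_tube, dtype=int)
    nid = 0
    for k, y in enumerate(plug_y):
        radii = circle_radii(y)
        r_core = radii[0]
        full_core_base[k] = nid
        core_xyz = np.column_stack([
            kappa * core_frac * float(spec.stem_radius(y)) * core_uv[:, 0],
            np.full(n_core, y),
            kappa * core_frac * float(spec.stem_radius(y)) * core_uv[:, 1]])
        nodes.append(core_xyz)
        nid += n_core
        full_ring_base[k] = nid
        for r in radii[1:]:
            nodes.append(np.column_stack([r * cos_t, np.full(n_sect, y), r * sin_t]))
            nid += n_sect
    for k, y in enumerate(tube_y):
        radii = circle_radii(spec.stem_length)[-n_circ_tube:]
        tube_base[k] = nid
        for r in radii:
            nodes.append(np.column_stack([r * cos_t, np.full(n_sect, y), r * sin_t]))
            nid += n_sect
    nodes = np.vstack(nodes)

    def full_circle(k: int, c: int) -> np.ndarray:
        """Node ids of circle c (0 = core boundary) at plug station k."""
        if c == 0:
            return full_core_base[k] + boundary_ids
        return full_ring_base[k] + (c - 1) * n_sect + np.arange(n_sect)

    def tube_circle(k: int, c: int) -> np.ndarray:
        """Node ids of tube circle c (0 = inner) at station k; station k = -1
        refers to the outermost circles of the last plug station."""
        if k < 0:
            return full_circle(n_plug - 1, n_circ_full - n_circ_tube + c)
        return tube_base[k] + c * n_sect + np.arange(n_sect)

    # ---- elements ---------------------------------------------------------
    jp = np.arange(n_sect)
    jp1 = (jp + 1) % n_sect
    elems, part, layer = [], [], []

    zone_of_circle = []                      # part id of annulus starting at circle c
    for k, zone in enumerate(PART_NAMES):
        zone_of_circle.extend([PART_ID[zone]] * n_r[zone])

    for k in range(n_plug - 1):
        # core cells (stem)
        b0, b1 = full_core_base[k], full_core_base[k + 1]
        q = core_quads
        hexes = np.column_stack([b0 + q[:, 0], b0 + q[:, 1], b0 + q[:, 2], b0 + q[:, 3],
                                 b1 + q[:, 0], b1 + q[:, 1], b1 + q[:, 2], b1 + q[:, 3]])
        elems.append(hexes)
        part.append(np.full(len(hexes), PART_ID["stem"]))
        layer.append(np.full(len(hexes), k))
        # ring cells
        for c in range(n_circ_full - 1):
            lo0, hi0 = full_circle(k, c), full_circle(k, c + 1)
            lo1, hi1 = full_circle(k + 1, c), full_circle(k + 1, c + 1)
            hexes = np.column_stack([lo0[jp], hi0[jp], hi0[jp1], lo0[jp1],
                                     lo1[jp], hi1[jp], hi1[jp1], lo1[jp1]])
            elems.append(hexes)
            part.append(np.full(n_sect, zone_of_circle[c]))
            layer.append(np.full(n_sect, k))
    for k in range(n_tube):
        for c in range(n_circ_tube - 1):
            lo0, hi0 = tube_circle(k - 1, c), tube_circle(k - 1, c + 1)
            lo1, hi1 = tube_circle(k, c), tube_circle(k, c + 1)
            hexes = np.column_stack([lo0[jp], hi0[jp], hi0[jp1], lo0[jp1],
                                     lo1[jp], hi1[jp], hi1[jp1], lo1[jp1]])
            elems.append(hexes)
            part.append(np.full(n_sect, PART_ID["outer_bone"]))
            layer.append(np.full(n_sect, n_plug - 1 + k))
    elems = np.vstack(elems)
    part = np.concatenate(part)
    layer = np.concatenate(layer)

    # orientation: ensure positive Jacobians everywhere
    dets = _hex.jacobian_dets(nodes[elems])
    if np.all(dets < 0):
        elems = elems[:, [0, 3, 2, 1, 4, 7, 6, 5]]
        dets = -dets
    if np.any(dets <= 0):
        raise GeometryError("mesh generation produced inverted elements")

    # ---- node sets --------------------------------------------------------
    y_all = nodes[:, 1]
    r_all = np.hypot(nodes[:, 0], nodes[:, 2])
    tol = 1e-9
    distal = np.flatnonzero((np.abs(y_all) < tol)
                            & (r_all <= 0.5 * spec.collar_diameter * kappa + 1e-9))
    y_max = float(y_all.max())
    proximal = np.flatnonzero(np.abs(y_all - y_max) < tol)
    outer_r = kappa * spec.outer_radius(np.clip(y_all, 0, spec.stem_length))
    outer_surface = np.flatnonzero(r_all >= outer_r - 1e-9)
    node_sets = {
        "distal_fixed_face": distal,
        "proximal_load_face": proximal,
        "outer_surface": outer_surface,
    }

    mesh = AssemblyMesh(nodes=nodes, elems=elems, part=part, layer=layer,
                        slice_index=np.full(len(elems), -1, dtype=int),
                        node_sets=node_sets, spec=spec, disc=disc)
    if slices is not None:
        assign_slices(mesh, slices)
    return mesh


def refine(mesh: AssemblyMesh, factor: float) -> AssemblyMesh:
    """Regenerate the mesh with every structured element count scaled by
    1/``factor`` (factor < 1 refines, > 1 coarsens; 1 reproduces the mesh
    exactly).  Count scaling makes successive refinements self-similar, the
    premise of Richardson extrapolation; geometry and part labels are
    preserved exactly."""
    if factor <= 0:
        raise GeometryError("refinement factor must be positive")
    if factor == 1.0:
        disc = mesh.disc
    else:
        disc = mesh.disc.scaled(factor)
    spec = replace(mesh.spec,
                   element_edge_length=mesh.spec.element_edge_length * factor)
    return build_assembly_mesh(spec, slices=mesh.slice_spec, disc=disc)


def assign_slices(mesh: AssemblyMesh, slices: SliceSpec) -> AssemblyMesh:
    """Assign a 1-based slice index to every bone-layer element in the slice
    band (by element centroid); elements outside the band get -1.

    Raises :class:`GeometryError` if the band leaves the bone layer's axial
    extent or any slice ends up empty (mesh too coarse for the spacing).
    """
    b0, b1 = slices.band
    if b0 < -1e-12 or b1 > mesh.spec.stem_length + 1e-12:
        raise GeometryError(
            f"slice band [{b0:.4g}, {b1:.4g}] m exceeds the bone layer extent "
            f"[0, {mesh.spec.stem_length:.4g}] m")
    cy = mesh.element_centroids()[:, 1]
    in_layer = mesh.part == PART_ID["bone_layer"]
    idx = np.floor((cy - slices.origin) / slices.spacing).astype(int) + 1
    in_band = in_layer & (cy >= b0) & (cy < b1)
    sl = np.full(mesh.n_elements, -1, dtype=int)
    sl[in_band] = np.clip(idx[in_band], 1, slices.number_of_slices)
    counts = np.bincount(sl[sl > 0], minlength=slices.number_of_slices + 1)[1:]
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0) + 1
        raise GeometryError(
            f"slices {empty.tolist()} contain no bone-layer elements; rebuild "
            "the mesh with the slice spec so slice planes align with element "
            "layers")
    mesh.slice_index = sl
    mesh.slice_spec = slices
    return mesh


def analytic_part_volumes(spec: AssemblySpec) -> dict[str, float]:
    """Closed-form part volumes of the parametric assembly.

    Radii are linear in y, so every cross-sectional area is quadratic in y
    and Simpson's rule integrates the plug region exactly.
    """
    L, Lr = spec.stem_length, spec.residual_length

    def shell(r_in, r_out):
        # Simpson over [0, L] of pi (r_out^2 - r_in^2)
        ys = np.array([0.0, 0.5 * L, L])
        a = np.pi * (np.asarray(r_out(ys)) ** 2 - np.asarray(r_in(ys)) ** 2)
        return L / 6.0 * (a[0] + 4 * a[1] + a[2])

    zero = lambda y: np.zeros_like(np.asarray(y, dtype=float))
    out = {
        "stem": float(shell(zero, spec.stem_radius)),
        "cement": float(shell(spec.stem_radius, spec.cement_outer_radius)),
        "bone_layer": float(shell(spec.cement_outer_radius, spec.bone_layer_outer_radius)),
        "outer_bone": float(shell(spec.bone_layer_outer_radius, spec.outer_radius)),
    }
    # proximal tube continues the outer bone past the stem tip
    r_in = float(spec.bone_layer_outer_radius(L))
    r_out = float(spec.outer_radius(L))
    out["outer_bone"] += float(np.pi * (r_out ** 2 - r_in ** 2) * (Lr - L))
    return out
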