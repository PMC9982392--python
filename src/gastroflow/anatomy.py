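"""Parametric upper-GI lumen geometry and the CGJ/SPGJ virtual surgery.

The tract is modelled as a union of signed-distance primitives in millimetre
coordinates (y up, z anterior, x toward the patient's left), routed in the
coronal plane:

* a straight esophagus entering the cardia from above,
* a J-shaped stomach swept along a vertical-corpus centreline with
  elliptical (anterior-posteriorly flattened) cross-sections; the antrum is
  the straight distal continuation of the corpus, as in the dependent
  obstructed stomach,
* a stapled side-to-side gastrojejunal anastomosis: a rounded-slot channel
  through the greater-curvature wall of the distal corpus into a jejunal
  conduit running alongside, whose efferent limb descends to the outflow
  plane,
* a duodenojejunal conduit from the pylorus around a C-loop, rejoining the
  jejunum just distal to the stoma, calibrated to a prescribed
  pylorus-to-anastomosis path length.

The SPGJ variant subtracts a partition wall across the corpus-antrum
junction immediately distal to the stoma, leaving a residual channel of
prescribed width along the lesser curvature.  All printed dimensions of the
reference reconstruction (esophagus 100 mm x 24 mm ID, anastomosis 45 mm,
pylorus-to-anastomosis path 350 mm, partition channel 20 mm) are defaults of
:class:`AnatomyParams`; the stomach body shape, which is patient-specific,
is a fixed template scaled by the greater-curvature length and maximum lumen
diameter.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AnatomyParams",
    "SurgicalVariant",
    "CrossSectionSpec",
    "LumenGeometry",
    "build_lumen",
    "export_surface",
    "load_surface",
    "GeometryError",
]

MM = 1e-3  # mm -> m conversion used at the solver boundary


class GeometryError(ValueError):
    """Raised for infeasible anatomical parameter combinations."""


class SurgicalVariant(str, enum.Enum):
    CGJ = "cgj"  # conventional gastrojejunostomy: bypass only
    SPGJ = "spgj"  # stomach-partitioning gastrojejunostomy: bypass + partition


@dataclass(frozen=True)
class AnatomyParams:
    """Dimensions of the reconstructed tract, all in millimetres."""

    esophagus_length: float = 100.0
    esophagus_inner_diameter: float = 24.0
    stomach_greater_curvature_length: float = 280.0
    stomach_max_lumen_diameter: float = 80.0
    pylorus_diameter: float = 15.0
    stenosis_factor: float = 1.0  # (0,1]; 1 = patent pyloroduodenal path
    duodenojejunal_path_length: float = 350.0
    bowel_inner_diameter: float = 25.0
    anastomosis_length: float = 45.0
    partition_channel_width: float = 20.0  # SPGJ residual lesser-curvature channel
    efferent_limb_length: float = 150.0

    def validate(self) -> None:
        positive = (
            "esophagus_length",
            "esophagus_inner_diameter",
            "stomach_greater_curvature_length",
            "stomach_max_lumen_diameter",
            "pylorus_diameter",
            "duodenojejunal_path_length",
            "bowel_inner_diameter",
            "anastomosis_length",
            "partition_channel_width",
            "efferent_limb_length",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise GeometryError(f"parameter {name!r} must be positive")
        if not 0 < self.stenosis_factor <= 1:
            raise GeometryError("parameter 'stenosis_factor' must lie in (0, 1]")
        if self.anastomosis_length >= self.duodenojejunal_path_length:
            raise GeometryError(
                "parameter 'anastomosis_length' must be smaller than "
                "'duodenojejunal_path_length'"
            )


@dataclass(frozen=True)
class CrossSectionSpec:
    """An axis-aligned diagnostic cut through one conduit of the lumen.

    ``axis`` is the face-normal axis (0=x, 1=y, 2=z), ``value`` the plane
    coordinate in mm, ``selector(points_mm, margin_mm)`` restricts the cut to
    the local conduit (True inside the conduit dilated by the margin), and
    ``positive`` gives the sign of the axis direction that counts as positive
    (stomach -> bowel) flow.
    """

    axis: int
    value: float
    selector: object
    positive: int = 1


# ---------------------------------------------------------------------------
# signed-distance primitives (vectorized over points of shape (N, 3))
# ---------------------------------------------------------------------------


def _capsule(p: np.ndarray, a, b, ra: float, rb: float, z_scale: float = 1.0) -> np.ndarray:
    """Distance to a tapered capsule from a to b with radii ra -> rb.

    ``z_scale`` < 1 flattens the cross-section into an ellipse with z
    semi-axis ``z_scale * r`` (approximate distance; exact sign).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    q = p.copy()
    q[:, 2] = q[:, 2] / z_scale
    a2, b2 = a.copy(), b.copy()
    a2[2] /= z_scale
    b2[2] /= z_scale
    ab = b2 - a2
    denom = float(ab @ ab)
    t = np.clip(((q - a2) @ ab) / max(denom, 1e-12), 0.0, 1.0)
    proj = a2 + t[:, None] * ab
    d = np.linalg.norm(q - proj, axis=1)
    return d - (ra + t * (rb - ra))


def _polyline(p: np.ndarray, pts: np.ndarray, radii: np.ndarray, z_scale: float = 1.0) -> np.ndarray:
    d = np.full(len(p), np.inf)
    for i in range(len(pts) - 1):
        d = np.minimum(d, _capsule(p, pts[i], pts[i + 1], radii[i], radii[i + 1], z_scale))
    return d


def _rounded_slot(p, center_x, center_y, hx, hv, rc, z_lo, z_hi):
    """Stoma channel through the posterior wall: rounded rectangle in (x, y)
    extruded along z."""
    dx = np.maximum(np.abs(p[:, 0] - center_x) - (hx - rc), 0.0)
    dy = np.maximum(np.abs(p[:, 1] - center_y) - (hv - rc), 0.0)
    d2 = np.hypot(dx, dy) - rc
    z_mid = 0.5 * (z_lo + z_hi)
    dz = np.abs(p[:, 2] - z_mid) - 0.5 * (z_hi - z_lo)
    return np.maximum(d2, dz)


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


# ---------------------------------------------------------------------------
# geometry container
# ---------------------------------------------------------------------------


@dataclass
class LumenGeometry:
    """Watertight upper-GI lumen with named landmarks and diagnostic cuts.

    The lumen is represented implicitly by :meth:`sdf` (negative inside, mm
    units); a triangulated surface is generated on demand.  ``clip_inlet_y``
    and ``clip_outlet_x`` are the open inflow/outflow planes.
    """

    params: AnatomyParams
    variant: SurgicalVariant
    landmarks: dict = field(default_factory=dict)
    sections: dict = field(default_factory=dict)
    # open ports: (axis, side, coordinate) of the planar inflow/outflow cuts
    inlet_port: tuple = (1, +1, 0.0)
    outlet_port: tuple = (0, +1, 0.0)
    bbox: tuple = ()
    min_channel_diameter: float = 0.0
    _primitives: dict = field(default_factory=dict, repr=False)

    # -- implicit representation ------------------------------------------

    def sdf(self, points: np.ndarray) -> np.ndarray:
        """Approximate signed distance (mm) to the lumen wall; negative inside."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        pr = self._primitives
        d = _polyline(p, *pr["esophagus"])
        d = np.minimum(d, _polyline(p, *pr["stomach"]))
        d = np.minimum(d, _rounded_slot(p, *pr["connector"]))
        d = np.minimum(d, _polyline(p, *pr["duodenum"]))
        d = np.minimum(d, _capsule(p, *pr["jejunum"]))
        if self.variant is SurgicalVariant.SPGJ:
            q, t, v1, half_th, s_keep, s_lo = pr["partition"]
            rel = p - q
            slab = np.abs(rel @ t) - half_th
            s = rel @ v1
            solid = np.maximum(slab, np.maximum(s - s_keep, s_lo - s))
            d = np.maximum(d, -solid)
        return d

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.sdf(points) < 0.0

    def capped_sdf(self, points: np.ndarray) -> np.ndarray:
        """Signed distance with the inlet/outlet openings closed (for surfacing)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.sdf(p)
        for axis, side, value in (self.inlet_port, self.outlet_port):
            d = np.maximum(d, side * (p[:, axis] - value))
        return d

    # -- surface ----------------------------------------------------------

    def surface(self, spacing: float = 2.0):
        """Closed triangulated surface via marching cubes (trimesh.Trimesh, mm)."""
        import trimesh
        from skimage import measure

        # the 0.317 offset keeps lattice points off the zero level set (exact
        # zeros produce degenerate marching-cubes facets)
        lo = np.array([b[0] for b in self.bbox]) - 3 * spacing - 0.317 * spacing
        hi = np.array([b[1] for b in self.bbox]) + 3 * spacing
        ns = np.maximum(((hi - lo) / spacing).astype(int) + 1, 2)
        xs = [np.linspace(lo[i], hi[i], ns[i]) for i in range(3)]
        grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
        vals = self.capped_sdf(grid.reshape(-1, 3)).reshape(grid.shape[:3])
        verts, faces, _, _ = measure.marching_cubes(vals, level=0.0)
        verts = lo + verts * (hi - lo) / (np.array(ns) - 1)
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
        trimesh.repair.fix_normals(mesh)
        return mesh

    def lumen_volume(self, spacing: float = 2.0) -> float:
        """Surface-integrated lumen volume in mm^3."""
        return float(abs(self.surface(spacing).volume))

    # -- measurements -----------------------------------------------------

    def measure_partition_channel_width(self, resolution: float = 0.25) -> float:
        """Open in-plane extent (mm) of the SPGJ channel on the partition plane."""
        if self.variant is not SurgicalVariant.SPGJ:
            raise GeometryError("partition channel exists only in the SPGJ variant")
        q, t, v1, _, s_keep, s_lo = self._primitives["partition"]
        v2 = np.cross(t, v1)
        # sample only the span the staple line covers (the extended plane also
        # crosses other conduits, which are not part of the stomach section)
        ss = np.arange(s_lo, s_keep + 80.0, resolution)
        zz = np.arange(-16.0, 16.0, 1.0)
        S, Z = np.meshgrid(ss, zz, indexing="ij")
        pts = q[None, None, :] + S[..., None] * v1 + Z[..., None] * v2
        inside = self.contains(pts.reshape(-1, 3)).reshape(S.shape)
        if not inside.any():
            raise GeometryError("partition plane carries no open lumen")
        open_s = S[inside]
        return float(open_s.max() - open_s.min() + resolution)

    def measure_anastomosis_opening(self, resolution: float = 0.25) -> float:
        """Length (mm) of the stomach-jejunum junction opening along its axis."""
        x_c, y_c, hx, hv, rc, z_lo, z_hi = self._primitives["connector"]
        z_st = self.sections["ANASTOMOSIS"].value  # clean throat station
        xs = np.arange(x_c - 2 * hx, x_c + 2 * hx, resolution)
        pts = np.column_stack([xs, np.full_like(xs, y_c), np.full_like(xs, z_st)])
        inside = self.contains(pts)
        if not inside.any():
            raise GeometryError("anastomotic throat is closed")
        # contiguous open run through the stoma centre (the station plane may
        # also graze other parts of the lumen)
        i0 = int(np.argmin(np.abs(xs - x_c)))
        if not inside[i0]:
            raise GeometryError("anastomotic throat is closed at its centre")
        lo = i0
        while lo > 0 and inside[lo - 1]:
            lo -= 1
        hi = i0
        while hi < len(xs) - 1 and inside[hi + 1]:
            hi += 1
        return float(xs[hi] - xs[lo] + resolution)


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------

# Stomach centreline template for a gastric-filling-phase J-shaped stomach
# (greater-curvature length 280 mm, max lumen diameter 80 mm); x/y offsets are
# relative to the cardia, radii are in-plane semi-axes.  The esophagus bends
# at the cardia so the entering stream is aimed along the gastric canal
# toward the corpus-antrum junction; the greater-curvature stoma lies in the
# floor, off that stream, which is the flow contrast the two operations are
# hypothesized to exploit.
_STOMACH_TEMPLATE = np.array(
    [
        # dx, dy, r
        [0.0, 0.0, 14.0],
        [-12.0, -35.0, 32.0],
        [0.0, -75.0, 40.0],
        [35.0, -105.0, 38.0],
        [75.0, -118.0, 33.0],
        [110.0, -110.0, 24.0],
        [140.0, -90.0, 16.0],
        [162.0, -72.0, 9.0],
        [170.0, -64.0, 7.5],  # pylorus; radius replaced from params
    ]
)
_Z_FLATTEN = 0.6  # anterior-posterior flattening of the gastric cross-section

_CARDIA = np.array([0.0, -10.0, 0.0])


def _probe_extreme(sdf_1d, origin, direction, lo: float, hi: float, find_max: bool) -> float:
    """Extent of the lumen along a probe line origin + s*direction, s in [lo, hi]."""
    ss = np.linspace(lo, hi, 800)
    pts = np.asarray(origin, dtype=float)[None, :] + ss[:, None] * np.asarray(direction, dtype=float)[None, :]
    inside = sdf_1d(pts) < 0
    if not inside.any():
        raise GeometryError(f"probe line through {tuple(origin)} misses the lumen")
    return float(ss[inside].max() if find_max else ss[inside].min())


def build_lumen(params: AnatomyParams, variant: SurgicalVariant | str) -> LumenGeometry:
    """Construct the reconstructed upper-GI lumen for one surgical variant.

    Raises :class:`GeometryError` when the parameters violate their
    invariants (named in the message) or when the partition cannot fit the
    local gastric lumen.
    """
    variant = SurgicalVariant(variant)
    params.validate()
    sL = params.stomach_greater_curvature_length / 280.0
    sD = params.stomach_max_lumen_diameter / 80.0

    # stomach centreline
    st = _STOMACH_TEMPLATE.copy()
    pts = np.zeros((len(st), 3))
    pts[:, 0] = _CARDIA[0] + st[:, 0] * sL
    pts[:, 1] = _CARDIA[1] + st[:, 1] * sL
    radii = st[:, 2] * sD
    radii[0] = max(radii[0], params.esophagus_inner_diameter / 2)
    r_pyl = 0.5 * params.pylorus_diameter * params.stenosis_factor
    radii[-1] = r_pyl
    stomach = (pts, radii, _Z_FLATTEN)

    # esophagus: vertical above, bending at the cardia so the entering
    # stream is launched along the gastric canal toward the antrum
    re = params.esophagus_inner_diameter / 2
    bend = np.array([[-30.0, 30.0, 0.0], [-16.0, 0.0, 0.0], [10.0, -13.0, 0.0]])
    l_curve = (
        np.linalg.norm(bend[1] - bend[0])
        + np.linalg.norm(np.array([0.0, -10.0, 0.0]) - bend[1])
    )
    y_in = bend[0][1] + (params.esophagus_length - l_curve)
    if y_in <= bend[0][1] + 5.0:
        raise GeometryError("parameter 'esophagus_length' too short for the cardia bend")
    e_pts = np.vstack([[bend[0][0], y_in + 10.0, 0.0], bend])
    esoph = (e_pts, np.full(len(e_pts), re), 1.0)

    stomach_only = lambda p: np.minimum(  # noqa: E731
        _polyline(np.atleast_2d(p), *stomach), _polyline(np.atleast_2d(p), *esoph)
    )

    # stoma: side-to-side anastomosis through the POSTERIOR gastric wall
    # near the greater-curvature low point; the jejunum runs behind the
    # stomach, so the stoma opens perpendicular to the coronal food stream
    x_c = 60.0 * sL
    hx = params.anastomosis_length / 2
    rb = params.bowel_inner_diameter / 2
    hv = min(10.0, 0.45 * params.bowel_inner_diameter)
    rc = min(6.0, hv - 1.0)
    y_floor = _probe_extreme(
        stomach_only, (x_c, 0.0, 0.0), (0.0, 1.0, 0.0), -400.0 * sL, 50.0, find_max=False
    )
    y_sl = y_floor + hv + 5.0  # stoma centre sits just above the floor
    z_wall = _probe_extreme(
        stomach_only, (x_c, y_sl, 0.0), (0.0, 0.0, 1.0), -80.0, 80.0, find_max=False
    )
    z_jej = z_wall - rb - 8.0  # jejunum axis behind the posterior wall
    connector = (x_c, y_sl, hx, hv, rc, z_jej, z_wall + 8.0)

    # jejunum behind the stomach: efferent limb toward -x, afferent side +x
    p0 = pts[-1]
    a_x = float(p0[0] + 60.0)
    x_out = x_c - hx - params.efferent_limb_length
    jejunum = (
        np.array([x_out - 10.0, y_sl, z_jej]),
        np.array([a_x, y_sl, z_jej]),
        rb,
        rb,
        1.0,
    )

    # duodenal conduit: pyloric canal along +x at the coronal plane, then a
    # loop descending into the retrogastric plane to rejoin the afferent limb
    a_pt = np.array([a_x, y_sl, z_jej])

    def duo_points(x_r: float) -> np.ndarray:
        return np.vstack(
            [
                p0,
                p0 + np.array([22.0, 0.0, 0.0]),
                [x_r, p0[1] - 10.0, 0.5 * z_jej],
                [x_r, y_sl - 4.0, z_jej],
                a_pt,
            ]
        )

    def path_length(x_r: float) -> float:
        # pylorus -> loop -> afferent limb -> near edge of the anastomosis
        return _polyline_length(duo_points(x_r)) + (a_x - (x_c + hx))

    target = params.duodenojejunal_path_length
    g_lo, g_hi = a_x + 2.2 * rb, a_x + 2.2 * rb + 500.0
    if not path_length(g_lo) <= target <= path_length(g_hi):
        raise GeometryError(
            "parameter 'duodenojejunal_path_length' outside the constructible "
            f"range [{path_length(g_lo):.0f}, {path_length(g_hi):.0f}] mm"
        )
    for _ in range(60):
        g_mid = 0.5 * (g_lo + g_hi)
        if path_length(g_mid) < target:
            g_lo = g_mid
        else:
            g_hi = g_mid
    x_r = 0.5 * (g_lo + g_hi)
    dpts = duo_points(x_r)
    r_duo_first = max(r_pyl, rb * params.stenosis_factor)
    dradii = np.array([r_pyl, r_duo_first] + [rb] * (len(dpts) - 2))
    duodenum = (dpts, dradii, 1.0)

    geom = LumenGeometry(params=params, variant=variant)
    geom._primitives = {
        "esophagus": esoph,
        "stomach": stomach,
        "connector": connector,
        "duodenum": duodenum,
        "jejunum": jejunum,
    }

    # SPGJ partition: wall across the stomach immediately distal to the
    # stoma, residual channel along the lesser curvature
    if variant is SurgicalVariant.SPGJ:
        q_x = x_c + hx + 12.5 * sL + 5.0
        seg = 5 if q_x > pts[5][0] else 4
        sa, sb = pts[seg], pts[seg + 1]
        t = sb - sa
        t = t / np.linalg.norm(t)
        frac = np.clip((q_x - sa[0]) / max(sb[0] - sa[0], 1e-9), 0.0, 1.0)
        q = sa + frac * (sb - sa)
        v1 = np.array([-t[1], t[0], 0.0])
        if v1[1] < 0:
            v1 = -v1  # toward the lesser curvature (upper wall)
        s_top = _probe_extreme(stomach_only, q, v1, -120.0 * sL, 120.0 * sL, find_max=True)
        s_bot = _probe_extreme(stomach_only, q, v1, -120.0 * sL, 120.0 * sL, find_max=False)
        lumen_span = s_top - s_bot
        if params.partition_channel_width >= lumen_span:
            raise GeometryError(
                "parameter 'partition_channel_width' "
                f"({params.partition_channel_width} mm) is not smaller than the "
                f"local stomach lumen span ({lumen_span:.1f} mm)"
            )
        s_keep = s_top - params.partition_channel_width
        geom._primitives["partition"] = (q, t, v1, 5.0, s_keep, s_bot - 10.0)
        geom.landmarks["partition plane"] = {
            "point": tuple(q),
            "normal": tuple(t),
            "channel_width": params.partition_channel_width,
        }

    # landmarks and diagnostic cuts
    pyl_plane_x = float(p0[0] + 0.5 * (dpts[1][0] - p0[0]))
    z_cut = 0.5 * (z_wall + (z_jej + rb))  # clean throat station
    geom.landmarks.update(
        {
            "inlet disc": {"point": (-30.0, float(y_in), 0.0), "normal": (0.0, 1.0, 0.0), "radius": re},
            "outlet disc": {"point": (float(x_out), float(y_sl), float(z_jej)), "normal": (-1.0, 0.0, 0.0), "radius": rb},
            "pyloric plane": {"point": (pyl_plane_x, float(p0[1]), 0.0), "normal": (1.0, 0.0, 0.0)},
            "anastomotic plane": {"point": (float(x_c), float(y_sl), float(z_cut)), "normal": (0.0, 0.0, -1.0)},
        }
    )
    _d1 = dpts[1]

    def _pylorus_sel(pts_mm, margin):
        return (
            _capsule(np.atleast_2d(pts_mm), p0, _d1, r_duo_first + margin, r_duo_first + margin)
            < 0
        )

    def _anastomosis_sel(pts_mm, margin):
        return (
            _rounded_slot(
                np.atleast_2d(pts_mm),
                x_c,
                y_sl,
                hx + margin,
                hv + margin,
                rc,
                z_jej - margin,
                z_wall + 8.0 + margin,
            )
            < 0
        )

    geom.sections = {
        "PYLORUS": CrossSectionSpec(
            axis=0, value=pyl_plane_x, selector=_pylorus_sel, positive=+1
        ),
        "ANASTOMOSIS": CrossSectionSpec(
            axis=2, value=float(z_cut), selector=_anastomosis_sel, positive=-1
        ),
    }
    geom.inlet_port = (1, +1, float(y_in))
    geom.outlet_port = (0, -1, float(x_out))
    geom.bbox = (
        (float(x_out), float(x_r + rb + 8.0)),
        (float(y_floor - 10.0), float(y_in)),
        (float(z_jej - rb - 6.0), float(_Z_FLATTEN * radii.max() + 6.0)),
    )
    geom.min_channel_diameter = float(
        min(2 * r_pyl, 2 * hv, params.partition_channel_width if variant is SurgicalVariant.SPGJ else np.inf)
    )
    return geom


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


def export_surface(geom: LumenGeometry, path: str | Path, spacing: float = 2.0) -> Path:
    """Write the closed lumen surface as an STL file; returns the path."""
    path = Path(path)
    mesh = geom.surface(spacing=spacing)
    if len(mesh.faces) == 0:
        raise GeometryError("surfacing produced no facets")
    mesh.export(path)
    return path


def load_surface(path: str | Path):
    """Read a watertight STL surface into a trimesh.Trimesh (mm coordinates)."""
    import trimesh

    mesh = trimesh.load_mesh(str(path))
    return mesh
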