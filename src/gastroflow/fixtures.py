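"""Validation geometries with closed-form flow solutions.

These minimal lumens (a straight circular tube, a rectangular box) share the
full :class:`~gastroflow.anatomy.LumenGeometry` interface, so every stage of
the pipeline — voxelization, the flow solver, particle tracking — can be
validated against Hagen-Poiseuille flow, plug transit times and exact voxel
volumes.
"""

from __future__ import annotations

import numpy as np

from gastroflow.anatomy import (
    AnatomyParams,
    CrossSectionSpec,
    LumenGeometry,
    SurgicalVariant,
    _capsule,
)

__all__ = ["straight_tube", "box_lumen"]


def straight_tube(radius: float, length: float) -> LumenGeometry:
    """Circular tube along +x: inlet disc at x=0, outlet at x=length (mm)."""
    a = np.array([-10.0, 0.0, 0.0])
    b = np.array([length + 10.0, 0.0, 0.0])

    geom = LumenGeometry(params=AnatomyParams(), variant=SurgicalVariant.CGJ)
    geom._primitives = {"tube": (a, b, radius, radius)}

    def sdf(points):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return _capsule(p, a, b, radius, radius)

    geom.sdf = sdf  # type: ignore[method-assign]
    geom.inlet_port = (0, -1, 0.0)
    geom.outlet_port = (0, +1, float(length))
    geom.landmarks = {
        "inlet disc": {"point": (0.0, 0.0, 0.0), "normal": (-1.0, 0.0, 0.0), "radius": radius},
        "outlet disc": {"point": (float(length), 0.0, 0.0), "normal": (1.0, 0.0, 0.0), "radius": radius},
    }

    def _mid_sel(pts_mm, margin):
        return (
            _capsule(np.atleast_2d(pts_mm), a, b, radius + margin, radius + margin) < 0
        )

    geom.sections = {
        "MID": CrossSectionSpec(axis=0, value=length / 2, selector=_mid_sel, positive=+1)
    }
    geom.bbox = ((0.0, float(length)), (-radius - 4, radius + 4), (-radius - 4, radius + 4))
    geom.min_channel_diameter = 2.0 * radius
    return geom


def box_lumen(lx: float, ly: float, lz: float) -> LumenGeometry:
    """Axis-aligned rectangular box with corners at the origin and (lx,ly,lz)."""
    half = np.array([lx, ly, lz]) / 2.0
    center = half.copy()

    geom = LumenGeometry(params=AnatomyParams(), variant=SurgicalVariant.CGJ)

    def sdf(points):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        q = np.abs(p - center) - half
        outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
        inside = np.minimum(q.max(axis=1), 0.0)
        return outside + inside

    geom.sdf = sdf  # type: ignore[method-assign]
    geom.inlet_port = (1, +1, float(ly))
    geom.outlet_port = (0, +1, float(lx))
    geom.landmarks = {
        "inlet disc": {
            "point": (lx / 2, float(ly), lz / 2),
            "normal": (0.0, 1.0, 0.0),
            "radius": min(lx, lz) / 2,
        },
        "outlet disc": {
            "point": (float(lx), ly / 2, lz / 2),
            "normal": (1.0, 0.0, 0.0),
            "radius": min(ly, lz) / 2,
        },
    }
    geom.bbox = ((0.0, float(lx)), (0.0, float(ly)), (0.0, float(lz)))
    geom.min_channel_diameter = float(min(lx, ly, lz))
    return geom
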