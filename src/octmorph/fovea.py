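"""Foveal morphometry: pit metrics and zoned retinal-layer thicknesses.

Pit width, depth and area are measured on the flattened scan: every
boundary is re-expressed as height above a straightened Bruch's-membrane
baseline, the pit rims are the most prominent ILM positions on either side
of the pit, the width is their lateral separation, the depth the axial
distance from the rim-to-rim chord to the deepest ILM point, and the area
the region enclosed between chord and ILM.

Layer thicknesses are reported per zone: at the single A-scan through the
pit centre (``central``), averaged from 1 deg nasally to 1 deg temporally
(``paracentral``), and averaged from 2 to 6 deg on each side (``nasal``,
``temporal``), for the grouped layers {RNFL, GCL+IPL, INL, OPL, ONL+IS,
OS+RPE}.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .scan import BoundarySet, LAYER_INTERFACES, LAYERS, ScanMeta
from .segment import ElmResult

ZONES = ("central", "paracentral", "nasal", "temporal")


@dataclass
class FoveaParams:
    """Foveal pit metrics plus zoned grouped-layer thicknesses."""

    pit_width_deg: float
    pit_depth_um: float
    pit_area_degum: float
    thickness_um: dict[str, dict[str, float]] = field(default_factory=dict)
    elm_detected: bool | None = None
    elm_score: float = float("nan")
    flat_pit: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def flatten(b: BoundarySet, baseline: str | None = None) -> BoundarySet:
    """Re-express all curves as depth relative to a straightened baseline.

    The baseline (Bruch's membrane, or the OS+RPE posterior boundary when
    no BM curve is present) becomes a constant at its own median depth;
    layer thicknesses are invariant under this transform.
    """
    if baseline is None:
        baseline = "BM" if "BM" in b else "OSRPE_post"
    if baseline not in b:
        raise ValueError(f"no {baseline!r} curve to flatten against")
    base = b[baseline]
    bad = ~np.isfinite(base)
    if bad.any():
        j0, j1 = np.flatnonzero(bad)[[0, -1]]
        raise ValueError(
            f"baseline {baseline!r} missing over {b.x_um[j0]:.0f}"
            f"-{b.x_um[j1]:.0f} um; cannot flatten")
    level = float(np.median(base))
    curves = {name: z - base + level for name, z in b.curves.items()}
    return BoundarySet(b.x_um.copy(), curves,
                       b.disc_edge_nasal_um, b.disc_edge_temporal_um)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample extremum position/value by a parabola through the three
    samples around index ``i`` (assumed equally spaced)."""
    if i <= 0 or i >= len(y) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    step = x[i + 1] - x[i]
    value = y1 - 0.25 * (y0 - y2) * delta
    return float(x[i] + delta * step), float(value)


def _pit_centre(x: np.ndarray, elev: np.ndarray) -> tuple[float, float]:
    """Sub-pixel lateral position and elevation of the pit minimum."""
    i = int(np.nanargmin(elev))
    return _parabolic_refine(x, elev, i)


def measure_pit(b: BoundarySet, meta: ScanMeta, *,
                min_prominence_um: float = 2.0):
    """Pit width (deg), depth (um) and area (deg*um) from a flattened scan.

    The rims are the global ILM elevation maxima on each side of the pit
    minimum (plateau ties broken toward the pit). Raises
    ``ValueError("no pit rims found")`` when the ILM carries no two
    flanking maxima of at least ``min_prominence_um``.
    """
    baseline = "BM" if "BM" in b else "OSRPE_post"
    elev = b[baseline] - b["ILM"]          # height of ILM above baseline
    x = b.x_um
    ok = np.isfinite(elev)
    if ok.sum() < 5:
        raise ValueError("too few finite ILM samples")
    x, elev = x[ok], elev[ok]

    # the pit is where the ILM is lowest, i.e. elevation is minimal
    xc, ec = _pit_centre(x, elev)

    def rim(mask: np.ndarray) -> tuple[float, float]:
        idx = np.flatnonzero(mask)
        if idx.size < 2:
            raise ValueError("no pit rims found")
        seg = elev[idx]
        best = float(seg.max())
        if best - ec < min_prominence_um:
            raise ValueError("no pit rims found")
        # plateau ties broken toward the pit (conservative, smaller width)
        cand = idx[np.flatnonzero(seg >= best - 1e-9)]
        j = int(cand[np.argmin(np.abs(x[cand] - xc))])
        # refine the apex with a quadratic fit over a small neighbourhood:
        # median-smoothed curves flatten the very top of the rim, so a
        # 3-point parabola alone under-resolves the apex position
        lo, hi = max(j - 4, 0), min(j + 5, len(x))
        if hi - lo >= 5:
            c2, c1, c0 = np.polyfit(x[lo:hi] - x[j], elev[lo:hi], 2)
            if c2 < 0:
                dx = float(np.clip(-c1 / (2.0 * c2), x[lo] - x[j],
                                   x[hi - 1] - x[j]))
                return float(x[j] + dx), float(c0 + c1 * dx + c2 * dx * dx)
        return _parabolic_refine(x, elev, j)

    x_l, e_l = rim(x < xc)
    x_r, e_r = rim(x > xc)

    width_deg = (x_r - x_l) / meta.um_per_degree

    # chord between the two rim tops; depth and area measured axially
    chord = e_l + (e_r - e_l) * (x - x_l) / (x_r - x_l)
    between = (x >= x_l) & (x <= x_r)
    drop = np.clip(chord - elev, 0.0, None)[between]
    xs = x[between]
    i_deep = int(np.argmax(drop))
    _, depth = _parabolic_refine(xs, drop, i_deep)
    area = float(np.trapezoid(drop, xs / meta.um_per_degree))
    return width_deg, float(depth), area


def zonal_thickness(b: BoundarySet, meta: ScanMeta, *,
                    inner_deg: float = 1.0,
                    outer_deg: tuple[float, float] = (2.0, 6.0)
                    ) -> dict[str, dict[str, float]]:
    """Grouped-layer thickness per zone.

    ``central`` is evaluated at the pit-centre A-scan (sub-pixel, linear
    interpolation of the boundary curves); ``paracentral`` averages
    [-1, +1] deg; ``nasal``/``temporal`` average [2, 6] deg on the
    respective side, resolved through ``meta.nasal_side``. Zones without
    full coverage are reported as NaN.
    """
    x = b.x_um
    upd = meta.um_per_degree
    baseline = "BM" if "BM" in b else "OSRPE_post"
    total = b[baseline] - b["ILM"]
    ok = np.isfinite(total)
    if ok.sum() < 5:
        raise ValueError("insufficient coverage to locate the pit")
    xc, _ = _pit_centre(x[ok], total[ok])

    ang = (x - xc) / upd
    nasal_mask = ang < 0 if meta.nasal_side == "left" else ang > 0
    lo, hi = outer_deg

    out: dict[str, dict[str, float]] = {}
    for layer in LAYERS:
        upper, lower = LAYER_INTERFACES[layer]
        if upper not in b or lower not in b:
            continue
        t = b[lower] - b[upper]
        vals: dict[str, float] = {}

        fin = np.isfinite(t)
        vals["central"] = (float(np.interp(xc, x[fin], t[fin]))
                           if fin.sum() >= 2 and x[fin][0] <= xc <= x[fin][-1]
                           else np.nan)

        para = np.abs(ang) <= inner_deg
        vals["paracentral"] = (float(np.nanmean(t[para]))
                               if para.any() and np.isfinite(t[para]).all()
                               else np.nan)

        for zone, side in (("nasal", nasal_mask), ("temporal", ~nasal_mask)):
            sel = side & (np.abs(ang) >= lo) & (np.abs(ang) <= hi)
            covered = (sel.any() and np.isfinite(t[sel]).all()
                       and np.abs(ang[sel]).max() >= hi - 0.25)
            vals[zone] = float(np.nanmean(t[sel])) if covered else np.nan
        out[layer] = vals
    return out


def measure_fovea(b: BoundarySet, meta: ScanMeta,
                  elm: ElmResult | None = None) -> FoveaParams:
    """Assemble the full foveal parameter set from a segmented scan.

    A flat ILM (no pit rims) yields the degenerate flat-pit result with
    zero depth and area rather than an error.
    """
    flat = flatten(b)
    thickness = zonal_thickness(flat, meta)
    try:
        width, depth, area = measure_pit(flat, meta)
        flat_pit = False
    except ValueError:
        width, depth, area = float("nan"), 0.0, 0.0
        flat_pit = True
    return FoveaParams(
        pit_width_deg=width, pit_depth_um=depth, pit_area_degum=area,
        thickness_um=thickness,
        elm_detected=None if elm is None else elm.detected,
        elm_score=float("nan") if elm is None else elm.score,
        flat_pit=flat_pit,
    )
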