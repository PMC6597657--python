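"""Optic-nerve-head morphometry on a horizontal B-scan.

The measurement scheme works entirely in micrometre boundary space:

* the **disc plane** joins Bruch's membrane at the two disc edges, and the
  **offset plane** is that line translated 150 um anteriorly (configurable);
* the **disc diameter** is the lateral distance between the disc edges;
* the **rim edges** are the outermost intersections of the ILM with the
  offset plane inside the disc; their lateral separation is the **cup
  diameter**, and cup diameter / disc diameter is the CDR;
* **cup depth** is the maximal perpendicular distance from the segment
  joining the rim edges down to the ILM; **cup area** is the area enclosed
  between that segment and the ILM below it;
* **rim width** is the summed nasal + temporal lateral distance from disc
  edge to rim edge; **rim area** the summed area anterior to the offset
  plane between the disc edges and the ILM;
* **RNFL thickness** is the ILM-to-posterior-RNFL distance sampled at a
  configurable eccentricity (default 6 deg from the disc centre; sampling
  from the disc margins is available as an alternative convention).

Lateral distances are converted to degrees of visual angle with the
small-angle model-eye factor; the mixed areas are in degree-micrometres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .scan import BoundarySet, ScanMeta


def um_to_deg(x_um: float | np.ndarray, meta: ScanMeta) -> float | np.ndarray:
    """Convert a lateral distance in um to degrees of visual angle
    (linear small-angle conversion; 292 um per degree by default)."""
    return x_um / meta.um_per_degree


@dataclass(frozen=True)
class OnhMeasureConfig:
    offset_um: float = 150.0
    rnfl_from: str = "centre"          # 'centre' or 'margin'
    rnfl_eccentricity_deg: float = 6.0

    def __post_init__(self) -> None:
        if self.rnfl_from not in ("centre", "margin"):
            raise ValueError("rnfl_from must be 'centre' or 'margin'")
        if self.offset_um < 0 or self.rnfl_eccentricity_deg <= 0:
            raise ValueError("offset and eccentricity must be non-negative")


@dataclass
class ONHParams:
    """The nine optic-nerve parameters measured on one horizontal B-scan."""

    disc_diameter_deg: float
    cup_disc_ratio: float
    cup_diameter_deg: float
    cup_area_degum: float
    cup_depth_um: float
    rim_width_deg: float
    rim_area_degum: float
    rnfl_nasal_um: float
    rnfl_temporal_um: float
    no_cup: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _interp_curve(x: np.ndarray, z: np.ndarray, xq: float,
                  max_gap_um: float = 60.0) -> float:
    valid = np.isfinite(z)
    if valid.sum() < 2:
        return np.nan
    xv, zv = x[valid], z[valid]
    if not (xv[0] - max_gap_um <= xq <= xv[-1] + max_gap_um):
        return np.nan
    j = np.searchsorted(xv, xq)
    lo, hi = max(j - 1, 0), min(j, len(xv) - 1)
    if xv[hi] - xv[lo] > max_gap_um and lo != hi:
        return np.nan
    return float(np.interp(xq, xv, zv))


def _bm_at_edge(b: BoundarySet, edge_um: float, window_um: float = 320.0) -> float:
    """Bruch's-membrane height at a disc edge, from a local linear fit of
    the valid BM samples just outside the edge."""
    x, bm = b.x_um, b["BM"]
    centre_side = np.sign(edge_um - 0.5 * (b.disc_edge_nasal_um
                                           + b.disc_edge_temporal_um))
    sel = (np.isfinite(bm)
           & ((x - edge_um) * centre_side >= 0)
           & (np.abs(x - edge_um) <= window_um))
    if sel.sum() >= 3:
        coef = np.polyfit(x[sel], bm[sel], 1)
        return float(np.polyval(coef, edge_um))
    val = _interp_curve(x, bm, edge_um, max_gap_um=120.0)
    if not np.isfinite(val):
        raise ValueError(f"no Bruch's membrane samples near disc edge at "
                         f"{edge_um:.0f} um")
    return val


def reference_planes(b: BoundarySet, offset_um: float = 150.0):
    """Disc plane (line joining BM at the disc edges) and the offset plane
    translated ``offset_um`` anteriorly. Each is ``(slope, intercept)`` with
    z = slope * x + intercept in um."""
    if b.disc_edge_nasal_um is None or b.disc_edge_temporal_um is None:
        raise ValueError("disc edges missing")
    x0, x1 = b.disc_edge_nasal_um, b.disc_edge_temporal_um
    z0, z1 = _bm_at_edge(b, x0), _bm_at_edge(b, x1)
    slope = (z1 - z0) / (x1 - x0)
    intercept = z0 - slope * x0
    return (slope, intercept), (slope, intercept - offset_um)


def _parabolic_max(y0: float, y1: float, y2: float) -> float:
    """Vertex value of the parabola through three equally spaced samples
    with y1 the discrete maximum."""
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return y1
    return y1 - (y0 - y2) ** 2 / (8.0 * denom)


def measure_onh(b: BoundarySet, meta: ScanMeta,
                config: OnhMeasureConfig | None = None) -> ONHParams:
    """Measure the nine optic-nerve parameters from boundary curves.

    If the ILM never crosses the offset plane inside the disc, the cup
    metrics are zero and the result is flagged ``no_cup``; the full disc
    then counts as rim.
    """
    config = config or OnhMeasureConfig()
    upd = meta.um_per_degree
    x = b.x_um
    ilm = b["ILM"]

    (m, c0), (_, c_off) = reference_planes(b, config.offset_um)
    z_off = m * x + c_off

    e_lo, e_hi = sorted((b.disc_edge_nasal_um, b.disc_edge_temporal_um))
    disc_d_um = e_hi - e_lo

    inside = (x > e_lo) & (x < e_hi) & np.isfinite(ilm)
    d = np.where(inside, ilm - z_off, np.nan)   # >0 means below the plane

    # rim edges: outermost sub-pixel crossings of the ILM with the plane
    idx = np.flatnonzero(inside)
    crossings = []

    def crossing_x(i: int, j: int) -> float:
        # sub-pixel zero of d between straddling samples i (one sign) and
        # j = i + 1. The ILM is kinked where the cup wall meets the rim,
        # so extrapolate the cup-side (d > 0) branch from its two nearest
        # samples when available rather than interpolating across the kink.
        lo, hi = x[i], x[j]
        pos, step = (i, -1) if d[i] > 0 else (j, +1)
        prev = pos + step
        if 0 <= prev < len(d) and inside[prev] and d[prev] > d[pos] > 0:
            xc = x[pos] + d[pos] * (x[pos] - x[prev]) / (d[prev] - d[pos])
            return float(np.clip(xc, lo, hi))
        return float(x[i] + d[i] / (d[i] - d[j]) * (x[j] - x[i]))

    for i, j in zip(idx[:-1], idx[1:]):
        if j != i + 1:
            continue
        di, dj = d[i], d[j]
        if di == 0.0:
            crossings.append(x[i])
        elif (di < 0 < dj) or (dj < 0 < di):
            crossings.append(crossing_x(i, j))
    if idx.size and d[idx[-1]] == 0.0:
        crossings.append(x[idx[-1]])

    has_cup = len(crossings) >= 2 and np.nanmax(d) > 0
    if has_cup:
        rim_lo, rim_hi = min(crossings), max(crossings)
        sel = inside & (x >= rim_lo) & (x <= rim_hi)
        dsel = d[sel]
        i_max = int(np.nanargmax(dsel))
        if 0 < i_max < len(dsel) - 1:
            depth_ax = _parabolic_max(dsel[i_max - 1], dsel[i_max], dsel[i_max + 1])
        else:
            depth_ax = float(dsel[i_max])
        cup_depth = depth_ax / np.sqrt(1.0 + m * m)

        xs = np.concatenate([[rim_lo], x[sel], [rim_hi]])
        ys = np.concatenate([[0.0], np.clip(dsel, 0.0, None), [0.0]])
        order = np.argsort(xs)
        cup_area = float(np.trapezoid(ys[order], xs[order] / upd))

        cup_d_um = rim_hi - rim_lo
        rim_width_um = (rim_lo - e_lo) + (e_hi - rim_hi)
    else:
        cup_depth = cup_area = 0.0
        cup_d_um = 0.0
        rim_width_um = disc_d_um

    # rim area: ILM anterior to the offset plane, between the disc edges
    above = np.where(inside, np.clip(-d, 0.0, None), np.nan)
    sel = np.isfinite(above)
    rim_area = float(np.trapezoid(above[sel], x[sel] / upd)) if sel.sum() >= 2 else np.nan

    # RNFL sampling
    rnfl_post = b.curves.get("RNFL_post")
    rnfl = {"nasal": np.nan, "temporal": np.nan}
    if rnfl_post is not None:
        centre = 0.5 * (e_lo + e_hi)
        ecc_um = config.rnfl_eccentricity_deg * upd
        for side, edge in (("nasal", b.disc_edge_nasal_um),
                           ("temporal", b.disc_edge_temporal_um)):
            direction = np.sign(edge - centre)
            xq = (centre + direction * ecc_um if config.rnfl_from == "centre"
                  else edge + direction * ecc_um)
            zi = _interp_curve(x, ilm, xq)
            zp = _interp_curve(x, rnfl_post, xq)
            rnfl[side] = zp - zi if np.isfinite(zi) and np.isfinite(zp) else np.nan

    disc_d_deg = um_to_deg(disc_d_um, meta)
    cup_d_deg = um_to_deg(cup_d_um, meta)
    return ONHParams(
        disc_diameter_deg=disc_d_deg,
        cup_disc_ratio=float(np.clip(cup_d_deg / disc_d_deg, 0.0, 1.0))
        if disc_d_deg > 0 else np.nan,
        cup_diameter_deg=cup_d_deg,
        cup_area_degum=cup_area,
        cup_depth_um=float(cup_depth),
        rim_width_deg=um_to_deg(rim_width_um, meta),
        rim_area_degum=rim_area,
        rnfl_nasal_um=float(rnfl["nasal"]),
        rnfl_temporal_um=float(rnfl["temporal"]),
        no_cup=not has_cup,
    )
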