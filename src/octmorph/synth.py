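"""Synthetic B-scan and cohort generation with known ground truth.

Two kinds of object are simulated:

* **B-scans** — layered-retina images matching the hand-held OCT protocol
  (12 mm wide scans of 600 A-scans; axial pitch 3.9 um/px, lateral
  20 um/px by default) with parametric optic-cup or foveal-pit geometry,
  piecewise-constant per-layer reflectivity, gamma multiplicative speckle,
  additive Gaussian noise and Gaussian point-spread blur. The noise-free
  limit is exactly segmentable, and every scan is returned together with
  its ground-truth boundary curves.
* **Cohorts** — per-eye parameter tables with the marginal distributions
  of published group summaries (means +/- SD), truncated-normal sampling
  within physical bounds, two eyes per participant with a configurable
  within-participant correlation (Gaussian copula, marginals preserved).

Rendering uses exact axial partial-volume integration: a pixel crossed by
a boundary receives the coverage-weighted mixture of the two layer
reflectivities, so sub-pixel boundary positions survive quantisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .scan import BScan, BoundarySet, ScanMeta

__all__ = [
    "OnhGeometry", "FoveaGeometry", "NoiseModel", "GroupStats",
    "generate_onh_bscan", "generate_fovea_bscan", "sample_cohort",
    "onh_geometry_from_row", "fovea_geometry_from_row",
    "DEFAULT_LAYER_THICKNESS",
]

#: zone order for per-layer thickness tuples
ZONES = ("central", "paracentral", "nasal", "temporal")

#: default per-layer thickness (um) by zone (central, paracentral, nasal,
#: temporal); values typical of a young child's macula
DEFAULT_LAYER_THICKNESS: dict[str, tuple[float, float, float, float]] = {
    "RNFL": (6.0, 10.0, 22.0, 18.0),
    "GCLIPL": (14.0, 30.0, 72.0, 68.0),
    "INL": (12.0, 22.0, 38.0, 36.0),
    "OPL": (18.0, 24.0, 30.0, 28.0),
    "ONLIS": (118.0, 108.0, 92.0, 94.0),
    "OSRPE": (62.0, 60.0, 58.0, 58.0),
}

# piecewise-constant reflectivity levels (arbitrary units)
_L_VITREOUS = 0.04
_L_RNFL = 0.85
_L_INNER = 0.45      # undifferentiated inner retina on ONH scans
_L_DISC_TISSUE = 0.40
_L_RPE_BAND = 0.95
_L_BELOW = 0.12
_FOVEA_LEVELS = {"RNFL": 0.80, "GCLIPL": 0.35, "INL": 0.55,
                 "OPL": 0.70, "ONLIS": 0.20, "OSRPE": 0.90}
_L_CHOROID = 0.15


@dataclass(frozen=True)
class NoiseModel:
    """Speckle / additive-noise / blur model applied after rendering.

    ``speckle_scale`` is the dispersion of mean-one gamma multiplicative
    speckle (0 disables it); ``additive_sigma`` the SD of additive
    Gaussian background noise; ``blur_sigma_px`` the Gaussian point-spread
    blur in pixels. Identical (configuration, seed) pairs give
    byte-identical images.
    """

    speckle_scale: float = 0.5
    additive_sigma: float = 0.02
    blur_sigma_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.speckle_scale, self.additive_sigma, self.blur_sigma_px) < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0)

    def apply(self, img: np.ndarray) -> np.ndarray:
        out = img.astype(np.float64, copy=True)
        rng = np.random.default_rng(self.seed)
        if self.speckle_scale > 0:
            s2 = self.speckle_scale ** 2
            out *= rng.gamma(1.0 / s2, s2, size=out.shape)
        if self.additive_sigma > 0:
            out += rng.normal(0.0, self.additive_sigma, size=out.shape)
        if self.blur_sigma_px > 0:
            out = gaussian_filter(out, self.blur_sigma_px)
        return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class OnhGeometry:
    """Parametric optic-nerve-head geometry for one horizontal B-scan.

    ``cup_depth_um`` is measured from the offset reference plane (150 um
    anterior to the Bruch's-membrane plane) to the deepest ILM point;
    ``rim_height_um`` is the ILM elevation above that plane at the rim.
    """

    disc_diameter_deg: float = 5.596
    cup_diameter_deg: float = 3.782
    cup_depth_um: float = 781.8
    rim_height_um: float = 120.0
    rnfl_nasal_um: float = 51.1
    rnfl_temporal_um: float = 59.6
    cup_profile: str = "parabolic"

    def __post_init__(self) -> None:
        if self.cup_diameter_deg > self.disc_diameter_deg:
            raise ValueError("cup_diameter_deg must not exceed disc_diameter_deg")
        if self.cup_depth_um < 0 or self.cup_diameter_deg < 0:
            raise ValueError("cup depth and diameter must be non-negative")
        if self.rim_height_um < 0 or min(self.rnfl_nasal_um, self.rnfl_temporal_um) < 0:
            raise ValueError("rim height and RNFL thicknesses must be non-negative")
        if self.cup_profile not in ("parabolic", "cosine"):
            raise ValueError("cup_profile must be 'parabolic' or 'cosine'")


@dataclass(frozen=True)
class FoveaGeometry:
    """Parametric foveal geometry: pit shape plus zoned layer thicknesses.

    ``layer_thicknesses_um`` maps each grouped layer to its (central,
    paracentral, nasal, temporal) thickness in um. The pit rim is placed at
    ``pit_width_deg / 2`` on each side with the rim elevated ``pit_depth_um``
    above the central inner-limiting-membrane point; the rim prominence is
    carried by the ganglion-cell complex with an in-zone compensation so
    zone-mean thicknesses equal their inputs exactly.
    """

    pit_width_deg: float = 9.62
    pit_depth_um: float = 120.0
    layer_thicknesses_um: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_THICKNESS))
    elm_present: bool = True
    elm_contrast: float = 2.0
    bm_tilt_um: float = 0.0
    bm_warp_amplitude_um: float = 0.0
    bm_warp_period_deg: float = 8.0

    def __post_init__(self) -> None:
        if self.pit_width_deg <= 0:
            raise ValueError("pit_width_deg must be positive")
        if self.pit_depth_um < 0:
            raise ValueError("pit_depth_um must be non-negative")
        for layer, zones in self.layer_thicknesses_um.items():
            if len(zones) != 4:
                raise ValueError(f"layer {layer!r} needs (central, paracentral, "
                                 "nasal, temporal) thicknesses")
            if min(zones) < 0:
                raise ValueError(f"negative thickness for layer {layer!r}")
        if self.elm_contrast < 0 or self.bm_warp_period_deg <= 0:
            raise ValueError("elm_contrast must be >= 0 and warp period positive")


@dataclass(frozen=True)
class GroupStats:
    """Per-parameter (mean, SD) summary of a named group, with truncation
    bounds used when sampling synthetic eyes."""

    name: str
    params: Mapping[str, tuple[float, float]]
    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for k, (m, s) in self.params.items():
            if s < 0:
                raise ValueError(f"negative SD for {k!r}")
            lo, hi = self.bounds.get(k, (-np.inf, np.inf))
            if not lo < hi:
                raise ValueError(f"empty truncation interval for {k!r}")


def _render(n_rows: int, axial_um_per_px: float, top_level,
            interfaces: list[np.ndarray], deltas: list[np.ndarray]) -> np.ndarray:
    """Exact axial partial-volume rendering of piecewise-constant columns.

    ``interfaces[k]`` gives per-column boundary depth (um); crossing it adds
    ``deltas[k]`` to the reflectivity below. A pixel spanning a boundary
    receives the coverage-weighted mixture.
    """
    n_cols = len(interfaces[0])
    row_bottom = (np.arange(n_rows, dtype=np.float64)[:, None] + 1.0) * axial_um_per_px
    img = np.full((n_rows, n_cols), top_level, dtype=np.float64)
    for z, d in zip(interfaces, deltas):
        frac_below = np.clip((row_bottom - z[None, :]) / axial_um_per_px, 0.0, 1.0)
        img += frac_below * (np.asarray(d, dtype=np.float64)[None, :]
                             if np.ndim(d) else float(d) * np.ones((1, n_cols)))
    return img


def generate_onh_bscan(
    geom: OnhGeometry,
    meta: ScanMeta | None = None,
    noise: NoiseModel | None = None,
    *,
    field_beyond_disc_deg: float = 7.0,
    offset_um: float = 150.0,
    top_margin_um: float = 150.0,
    bottom_margin_um: float = 150.0,
    rpe_band_um: float = 25.0,
    n_cols: int | None = None,
) -> tuple[BScan, BoundarySet]:
    """Render a horizontal B-scan through the optic-disc centre.

    Returns the image and its ground-truth boundaries: the ILM everywhere,
    Bruch's membrane (BM) and the posterior nerve-fibre-layer boundary
    outside the disc opening (BM carries no reflective band inside the
    opening), plus the two lateral disc-edge positions.
    """
    meta = meta or ScanMeta(scan_kind="onh")
    noise = noise or NoiseModel.zero()
    upd, lat, ax = meta.um_per_degree, meta.lateral_um_per_px, meta.axial_um_per_px

    disc_r = geom.disc_diameter_deg * upd / 2.0
    need_half = disc_r + field_beyond_disc_deg * upd
    if n_cols is None:
        n_cols = max(50, int(math.ceil(2.0 * need_half / lat)))
    elif n_cols * lat < 2.0 * need_half:
        raise ValueError(
            f"scan field {n_cols * lat:.0f} um narrower than required "
            f"{2 * need_half:.0f} um (disc plus {field_beyond_disc_deg} deg each side)")

    x = (np.arange(n_cols) + 0.5) * lat
    centre = n_cols * lat / 2.0
    dx = x - centre

    z_rim = top_margin_um
    z_offset = z_rim + geom.rim_height_um
    z_bm = z_offset + offset_um

    w = geom.cup_diameter_deg * upd / 2.0
    ilm = np.full(n_cols, z_rim)
    if w > 0 and geom.cup_depth_um > 0:
        adx = np.abs(dx)
        inside = adx <= w
        if geom.cup_profile == "parabolic":
            prof = 1.0 - (dx[inside] / w) ** 2
        else:
            prof = np.cos(np.pi * dx[inside] / (2.0 * w))
        ilm[inside] = z_offset + geom.cup_depth_um * prof
        # linear shoulder from the offset plane up to rim level
        ramp = min(150.0, 0.5 * (disc_r - w)) if disc_r > w else 2.0 * lat
        ramp = max(ramp, 1e-6)
        shoulder = (adx > w) & (adx <= w + ramp)
        ilm[shoulder] = z_offset - geom.rim_height_um * (adx[shoulder] - w) / ramp

    outside = np.abs(dx) >= disc_r
    # fractional lateral coverage of the extra-disc profile per column, so
    # the rendered band fades sub-pixel-accurately at the disc edges
    frac = np.clip((np.abs(dx) - disc_r) / lat + 0.5, 0.0, 1.0)
    rnfl_t = np.where(dx * (+1 if meta.nasal_side == "left" else -1) < 0,
                      geom.rnfl_nasal_um, geom.rnfl_temporal_um)
    rnfl_post = np.where(outside, ilm + rnfl_t, np.nan)
    bm = np.where(outside, z_bm, np.nan)

    bottom = max(z_bm + rpe_band_um, z_offset + geom.cup_depth_um) + bottom_margin_um
    n_rows = max(50, int(math.ceil(bottom / ax)))

    img = _render(
        n_rows, ax, _L_VITREOUS,
        interfaces=[ilm, ilm + rnfl_t, np.full(n_cols, z_bm),
                    np.full(n_cols, z_bm + rpe_band_um)],
        deltas=[frac * (_L_RNFL - _L_VITREOUS)
                + (1 - frac) * (_L_DISC_TISSUE - _L_VITREOUS),
                frac * (_L_INNER - _L_RNFL),
                frac * (_L_RPE_BAND - _L_INNER),
                frac * (_L_BELOW - _L_RPE_BAND)
                + (1 - frac) * (_L_BELOW - _L_DISC_TISSUE)],
    )
    img = noise.apply(img)

    nasal_left = meta.nasal_side == "left"
    truth = BoundarySet(
        x, {"ILM": ilm, "RNFL_post": rnfl_post, "BM": bm},
        disc_edge_nasal_um=centre - disc_r if nasal_left else centre + disc_r,
        disc_edge_temporal_um=centre + disc_r if nasal_left else centre - disc_r,
    )
    return BScan(img, meta), truth


def _zone_profile(abs_deg: np.ndarray,
                  zones: tuple[float, float, float, float],
                  side_value: float) -> np.ndarray:
    """Thickness profile vs eccentricity: piecewise linear through knots at
    0, 1 and 2 deg, constant beyond, with the paracentral [0,1] deg mean
    equal to the stated paracentral value."""
    central, para, _, _ = zones
    v1 = 2.0 * para - central
    knots = np.array([0.0, 1.0, 2.0, 1e9])
    vals = np.array([central, v1, side_value, side_value])
    return np.interp(abs_deg, knots, vals)


def generate_fovea_bscan(
    geom: FoveaGeometry,
    meta: ScanMeta | None = None,
    noise: NoiseModel | None = None,
    *,
    half_extent_deg: float = 7.0,
    top_margin_um: float = 100.0,
    below_margin_um: float = 90.0,
    elm_thickness_um: float = 8.0,
    rim_halfwidth_deg: float = 1.2,
) -> tuple[BScan, BoundarySet]:
    """Render a horizontal B-scan through the foveal centre.

    The ground truth contains the ILM, the six grouped-layer posterior
    interfaces, Bruch's membrane, and an ELM curve iff ``elm_present``.
    Layer reflectivities alternate so that every interface is a distinct
    intensity edge and noise-free segmentation is exact.
    """
    from .scan import LAYERS

    meta = meta or ScanMeta(scan_kind="fovea")
    noise = noise or NoiseModel.zero()
    upd, lat, ax = meta.um_per_degree, meta.lateral_um_per_px, meta.axial_um_per_px
    if half_extent_deg < 6.0:
        raise ValueError("scan must span at least 6 deg each side of the pit")
    # widen the field if a broad pit's rim would run off the scan
    half_extent_deg = max(half_extent_deg,
                          geom.pit_width_deg / 2.0 + rim_halfwidth_deg + 0.4)

    n_cols = max(50, int(math.ceil(2.0 * half_extent_deg * upd / lat)))
    x = (np.arange(n_cols) + 0.5) * lat
    centre = n_cols * lat / 2.0
    ang = (x - centre) / upd                      # signed eccentricity, deg
    nasal_mask = ang < 0 if meta.nasal_side == "left" else ang > 0
    abs_ang = np.abs(ang)

    # per-layer thickness profiles (um per column)
    thick: dict[str, np.ndarray] = {}
    for layer in LAYERS:
        zones = tuple(geom.layer_thicknesses_um[layer])
        prof = np.where(nasal_mask,
                        _zone_profile(abs_ang, zones, zones[2]),
                        _zone_profile(abs_ang, zones, zones[3]))
        thick[layer] = prof

    # rim prominence on the ganglion-cell complex so the ILM peaks at
    # +/- pit_width/2 exactly pit_depth above the central ILM point
    r = geom.pit_width_deg / 2.0
    hw = rim_halfwidth_deg
    if r - hw < 1.0:
        raise ValueError("pit_width_deg too small: rim would enter the "
                         "paracentral zone")
    if r + hw > half_extent_deg - 0.3:
        raise ValueError("pit_width_deg too large for the scan field")
    t_central = sum(float(v[0]) for v in geom.layer_thicknesses_um.values())
    rim_target = t_central + geom.pit_depth_um
    bump = np.zeros(n_cols)
    for side_idx, side_mask in ((2, nasal_mask), (3, ~nasal_mask)):
        if not np.any(side_mask):
            continue
        side_total = sum(float(v[side_idx])
                         for v in geom.layer_thicknesses_um.values())
        base_at_r = sum(
            float(_zone_profile(np.array([r]),
                                tuple(geom.layer_thicknesses_um[l]),
                                float(geom.layer_thicknesses_um[l][side_idx]))[0])
            for l in LAYERS)
        if rim_target < base_at_r - 1e-9:
            raise ValueError(
                "pit_depth_um too shallow for these layer thicknesses: rim "
                f"needs at least {base_at_r - t_central:.1f} um of depth")
        if geom.pit_depth_um > 0 and rim_target < side_total + 2.0:
            raise ValueError(
                "pit rim would not be prominent: central thickness plus "
                "pit_depth_um must exceed the 2-6 deg thickness")
        # smooth (parabolic-cap) rim bump; the whole 2-6 deg plateau is
        # lowered by the bump's in-zone mean so the zone-mean thickness
        # equals its input without any step edge in the profile
        bump_u = np.clip(1.0 - ((abs_ang - r) / hw) ** 2, 0.0, None)
        bump_u[~side_mask] = 0.0
        zone = side_mask & (abs_ang >= 2.0) & (abs_ang <= 6.0)
        s_mean = float(bump_u[zone].mean()) if np.any(zone) else 0.0
        # lam: interpolation weight of the plateau value at each column
        lam = np.clip(abs_ang - 1.0, 0.0, 1.0)
        peak_col = int(np.argmax(np.where(side_mask, bump_u, -np.inf)))
        denom = float(bump_u[peak_col]) - float(lam[peak_col]) * s_mean
        if denom <= 1e-9:
            raise ValueError("degenerate rim bump; widen the scan or the pit")
        # rim peak sits exactly pit_depth above the central ILM point
        amp = (rim_target - base_at_r) / denom
        bump += np.where(side_mask, amp * (bump_u - lam * s_mean), 0.0)
    thick["GCLIPL"] = thick["GCLIPL"] + bump
    if np.any(thick["GCLIPL"] < 0):
        raise ValueError("rim compensation drove GCL+IPL thickness negative")

    total = sum(thick[l] for l in LAYERS)

    rel = (geom.bm_tilt_um * (x - x[0]) / (x[-1] - x[0])
           + geom.bm_warp_amplitude_um
           * np.sin(2.0 * np.pi * ang / geom.bm_warp_period_deg))
    z0 = top_margin_um + np.max(total - rel)
    bm = z0 + rel

    post_name = {"RNFL": "RNFL_post", "GCLIPL": "GCLIPL_post", "INL": "INL_post",
                 "OPL": "OPL_post", "ONLIS": "ONLIS_post", "OSRPE": "OSRPE_post"}
    curves: dict[str, np.ndarray] = {}
    z = bm.copy()
    for layer in reversed(LAYERS):
        curves[post_name[layer]] = z.copy()
        z = z - thick[layer]
    curves["ILM"] = z.copy()
    curves["BM"] = bm.copy()

    if geom.elm_present:
        curves["ELM"] = curves["OPL_post"] + 0.55 * thick["ONLIS"]

    # rendering: interfaces anterior to posterior with level deltas
    interfaces = [curves["ILM"]]
    deltas: list[np.ndarray | float] = [_FOVEA_LEVELS["RNFL"] - _L_VITREOUS]
    seq = [("RNFL_post", "GCLIPL"), ("GCLIPL_post", "INL"), ("INL_post", "OPL"),
           ("OPL_post", "ONLIS")]
    prev = "RNFL"
    for iface, nxt in seq:
        interfaces.append(curves[iface])
        deltas.append(_FOVEA_LEVELS[nxt] - _FOVEA_LEVELS[prev])
        prev = nxt
    if geom.elm_present and geom.elm_contrast > 0:
        elm_level = _FOVEA_LEVELS["ONLIS"] * geom.elm_contrast
        interfaces.append(curves["ELM"] - elm_thickness_um / 2.0)
        deltas.append(elm_level - _FOVEA_LEVELS["ONLIS"])
        interfaces.append(curves["ELM"] + elm_thickness_um / 2.0)
        deltas.append(_FOVEA_LEVELS["ONLIS"] - elm_level)
    interfaces.append(curves["ONLIS_post"])
    deltas.append(_FOVEA_LEVELS["OSRPE"] - _FOVEA_LEVELS["ONLIS"])
    interfaces.append(curves["OSRPE_post"])
    deltas.append(_L_CHOROID - _FOVEA_LEVELS["OSRPE"])

    n_rows = max(50, int(math.ceil((np.max(bm) + below_margin_um) / ax)))
    img = _render(n_rows, ax, _L_VITREOUS, interfaces,
                  [np.broadcast_to(np.asarray(d, float), (n_cols,)).copy()
                   for d in deltas])
    img = noise.apply(img)

    return BScan(img, meta), BoundarySet(x, curves)


# ---------------------------------------------------------------------------
# cohort sampling


def _sample_correlated_truncated(rng, mu, sd, lo, hi, rho, max_iter=10000):
    """Draw one correlated pair per participant with per-eye truncated-normal
    marginals (Gaussian copula; joint rejection within bounds).

    ``mu``/``sd``/``lo``/``hi`` have shape (n, 2).
    """
    n = mu.shape[0]
    out = np.empty((n, 2))
    todo = np.ones(n, dtype=bool)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    for _ in range(max_iter):
        k = int(todo.sum())
        if k == 0:
            break
        z = rng.standard_normal((k, 2)) @ chol.T
        vals = mu[todo] + sd[todo] * z
        ok = np.all((vals >= lo[todo]) & (vals <= hi[todo]), axis=1)
        idx = np.flatnonzero(todo)
        out[idx[ok]] = vals[ok]
        todo[idx[ok]] = False
    else:
        raise RuntimeError("truncated sampling failed to converge; check bounds")
    return out


def sample_cohort(
    stats_case: GroupStats,
    stats_control: GroupStats,
    n_case: int,
    n_control: int,
    unilateral_fraction: float = 0.65,
    seed: int = 0,
    eye_correlation: float = 0.6,
) -> pd.DataFrame:
    """Sample a two-eyes-per-participant cohort of parameter rows.

    Case participants have either both eyes affected or, for a
    ``unilateral_fraction`` of them, one affected eye (drawn from
    ``stats_case``) and one fellow eye drawn from ``stats_control``.
    Control participants contribute two unaffected eyes. A participant's
    two eyes share age and are correlated (``eye_correlation``) through a
    Gaussian copula, which leaves the per-eye marginals untouched.
    """
    if n_case < 1 or n_control < 0:
        raise ValueError("need at least one case participant")
    if not 0.0 <= unilateral_fraction <= 1.0:
        raise ValueError("unilateral_fraction must be in [0, 1]")
    if not 0.0 <= eye_correlation < 1.0:
        raise ValueError("eye_correlation must be in [0, 1)")

    rng = np.random.default_rng(seed)
    n_uni = int(round(unilateral_fraction * n_case))

    participants = []   # (pid, group, affected_od, affected_os, age_stats_key)
    for i in range(n_case):
        if i < n_uni:
            affected_eye = rng.choice(["OD", "OS"])
            participants.append((f"case{i + 1:03d}", "case",
                                 affected_eye == "OD", affected_eye == "OS"))
        else:
            participants.append((f"case{i + 1:03d}", "case", True, True))
    for i in range(n_control):
        participants.append((f"ctrl{i + 1:03d}", "control", False, False))

    n_part = len(participants)
    groups = np.array([p[1] for p in participants])
    affected = np.array([[p[2], p[3]] for p in participants], dtype=bool)

    def stat_arrays(key):
        mu = np.empty((n_part, 2))
        sd = np.empty((n_part, 2))
        lo = np.full((n_part, 2), -np.inf)
        hi = np.full((n_part, 2), np.inf)
        for j, src_mask in ((0, affected[:, 0]), (1, affected[:, 1])):
            for use_case in (True, False):
                st = stats_case if use_case else stats_control
                if key not in st.params:
                    raise KeyError(f"parameter {key!r} missing from {st.name}")
                sel = src_mask == use_case
                m, s = st.params[key]
                l, h = st.bounds.get(key, (-np.inf, np.inf))
                mu[sel, j], sd[sel, j] = m, s
                lo[sel, j], hi[sel, j] = l, h
        return mu, sd, lo, hi

    shared = sorted(set(stats_case.params) & set(stats_control.params))
    param_keys = [k for k in shared if k != "age_years"]

    rows: dict[str, np.ndarray] = {}
    for key in param_keys:
        mu, sd, lo, hi = stat_arrays(key)
        rows[key] = _sample_correlated_truncated(rng, mu, sd, lo, hi, eye_correlation)

    # participant-level age from the participant's own group
    if "age_years" in shared:
        age = np.empty(n_part)
        for use_case in (True, False):
            st = stats_case if use_case else stats_control
            m, s = st.params["age_years"]
            l, h = st.bounds.get("age_years", (0.0, np.inf))
            sel = np.flatnonzero((groups == "case") == use_case)
            vals = rng.normal(m, s, size=len(sel))
            for _ in range(10000):
                bad = (vals < l) | (vals > h)
                if not bad.any():
                    break
                vals[bad] = rng.normal(m, s, size=int(bad.sum()))
            age[sel] = vals
    else:
        age = np.full(n_part, np.nan)

    records = []
    for i, (pid, group, aff_od, aff_os) in enumerate(participants):
        for j, (eye, aff) in enumerate((("OD", aff_od), ("OS", aff_os))):
            rec = {"participant_id": pid, "group": group, "eye": eye,
                   "age_years": age[i], "affected": bool(aff)}
            for key in param_keys:
                rec[key] = rows[key][i, j]
            records.append(rec)
    return pd.DataFrame.from_records(records)


def onh_geometry_from_row(row: Mapping, rim_height_bounds=(30.0, 400.0)) -> OnhGeometry:
    """Build a renderable disc geometry from one cohort row.

    The sampled parameters are marginal draws, so the geometric constraint
    cup <= disc is enforced here by clamping the cup, and the rim height is
    back-derived from the sampled rim area and width.
    """
    disc = float(row["disc_diameter_deg"])
    cup = min(float(row["cup_diameter_deg"]), 0.97 * disc)
    width = max(float(row.get("rim_width_deg", disc - cup)), 0.3)
    h = float(np.clip(float(row.get("rim_area_degum", 120.0 * width)) / width,
                      *rim_height_bounds))
    return OnhGeometry(
        disc_diameter_deg=disc,
        cup_diameter_deg=max(cup, 0.0),
        cup_depth_um=max(float(row["cup_depth_um"]), 0.0),
        rim_height_um=h,
        rnfl_nasal_um=max(float(row["rnfl_nasal_um"]), 0.0),
        rnfl_temporal_um=max(float(row["rnfl_temporal_um"]), 0.0),
    )


def fovea_geometry_from_row(row: Mapping, **kwargs) -> FoveaGeometry:
    """Build a foveal geometry from one cohort row (pit width from the row,
    remaining shape parameters at their defaults unless overridden)."""
    return FoveaGeometry(pit_width_deg=float(row["foveal_pit_width_deg"]), **kwargs)
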