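"""B-scan containers, calibration metadata and boundary curves.

Coordinate conventions used throughout the package:

* rows are axial, columns are lateral A-scans;
* "anterior" is the smaller row index; axial positions are expressed in
  micrometres measured downward (posterior) from the top of the image;
* lateral positions are micrometres from the left image edge, with the
  A-scan at column ``j`` centred at ``(j + 0.5) * lateral_um_per_px``;
* lateral distances convert to degrees of visual angle with the small-angle
  model-eye factor (default 292 um per degree).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

#: canonical boundary-curve names, anterior to posterior
CURVE_NAMES = (
    "ILM",
    "RNFL_post",
    "GCLIPL_post",
    "INL_post",
    "OPL_post",
    "ONLIS_post",
    "OSRPE_post",
    "BM",
    "ELM",
)

#: grouped retinal layers analysed on fovea scans, inner to outer
LAYERS = ("RNFL", "GCLIPL", "INL", "OPL", "ONLIS", "OSRPE")

#: anterior interface of each grouped layer (posterior one is the layer's own)
LAYER_INTERFACES = {
    "RNFL": ("ILM", "RNFL_post"),
    "GCLIPL": ("RNFL_post", "GCLIPL_post"),
    "INL": ("GCLIPL_post", "INL_post"),
    "OPL": ("INL_post", "OPL_post"),
    "ONLIS": ("OPL_post", "ONLIS_post"),
    "OSRPE": ("ONLIS_post", "OSRPE_post"),
}


@dataclass(frozen=True)
class ScanMeta:
    """Calibration and orientation metadata for one B-scan.

    Parameters
    ----------
    axial_um_per_px
        Axial pixel pitch in micrometres per pixel (anterior = smaller row).
    lateral_um_per_px
        Lateral pixel pitch in micrometres per pixel.
    um_per_degree
        Micrometres of retina per degree of visual angle (small angles).
    nasal_side
        Which image side ('left' or 'right') corresponds to nasal retina.
    scan_kind
        'onh' for an optic-nerve-head scan, 'fovea' for a macular scan.
    """

    axial_um_per_px: float = 3.9
    lateral_um_per_px: float = 20.0
    um_per_degree: float = 292.0
    nasal_side: str = "left"
    scan_kind: str = "onh"

    def __post_init__(self) -> None:
        if self.axial_um_per_px <= 0 or self.lateral_um_per_px <= 0:
            raise ValueError("pixel pitches must be positive")
        if self.um_per_degree <= 0:
            raise ValueError("um_per_degree must be positive")
        if self.nasal_side not in ("left", "right"):
            raise ValueError(f"nasal_side must be 'left' or 'right', got {self.nasal_side!r}")
        if self.scan_kind not in ("onh", "fovea"):
            raise ValueError(f"scan_kind must be 'onh' or 'fovea', got {self.scan_kind!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScanMeta":
        return cls(**{k: d[k] for k in ("axial_um_per_px", "lateral_um_per_px",
                                        "um_per_degree", "nasal_side", "scan_kind")})


@dataclass
class BScan:
    """A single grayscale OCT B-scan plus its calibration metadata."""

    intensity: np.ndarray
    meta: ScanMeta

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D array")
        if self.intensity.shape[0] < 50 or self.intensity.shape[1] < 50:
            raise ValueError("B-scan must be at least 50 x 50 pixels")
        if np.any(self.intensity < 0):
            raise ValueError("intensity values must be non-negative")

    @property
    def n_rows(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intensity.shape[1]

    @property
    def x_um(self) -> np.ndarray:
        """Lateral position (um) of each A-scan centre."""
        return (np.arange(self.n_cols) + 0.5) * self.meta.lateral_um_per_px

    def save(self, path: str | Path) -> None:
        """Write a 16-bit grayscale TIFF plus a JSON metadata sidecar."""
        path = Path(path)
        lo, hi = float(self.intensity.min()), float(self.intensity.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        img16 = np.round((self.intensity - lo) * scale).astype(np.uint16)
        tifffile.imwrite(path, img16)
        sidecar = dict(self.meta.to_dict(), intensity_offset=lo, intensity_scale=scale)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "BScan":
        path = Path(path)
        img = tifffile.imread(path).astype(np.float64)
        side = json.loads(path.with_suffix(".json").read_text())
        img = img / side.pop("intensity_scale", 1.0) + side.pop("intensity_offset", 0.0)
        return cls(np.clip(img, 0.0, None), ScanMeta.from_dict(side))


@dataclass
class BoundarySet:
    """Named per-A-scan axial boundary curves in micrometres.

    ``curves`` maps a name in :data:`CURVE_NAMES` to an array of axial
    positions (um from image top) with NaN where the boundary is missing
    (e.g. Bruch's membrane inside the disc opening). ``disc_edge_nasal_um``
    / ``disc_edge_temporal_um`` are the lateral positions where Bruch's
    membrane terminates, for ONH scans only.
    """

    x_um: np.ndarray
    curves: dict[str, np.ndarray] = field(default_factory=dict)
    disc_edge_nasal_um: float | None = None
    disc_edge_temporal_um: float | None = None

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=np.float64)
        for name, z in list(self.curves.items()):
            z = np.asarray(z, dtype=np.float64)
            if z.shape != self.x_um.shape:
                raise ValueError(f"curve {name!r} length does not match x_um")
            self.curves[name] = z
        if (self.disc_edge_nasal_um is not None
                and self.disc_edge_temporal_um is not None
                and self.disc_edge_nasal_um == self.disc_edge_temporal_um):
            raise ValueError("disc edges must be distinct")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.curves[name]

    def __contains__(self, name: str) -> bool:
        return name in self.curves

    def check_ordering(self, atol_um: float = 1e-6) -> None:
        """Assert anterior-to-posterior ordering of all co-defined curves."""
        order = [n for n in CURVE_NAMES if n in self.curves and n != "ELM"]
        for upper, lower in zip(order, order[1:]):
            a, b = self.curves[upper], self.curves[lower]
            both = np.isfinite(a) & np.isfinite(b)
            bad = both & (a > b + atol_um)
            if np.any(bad):
                j = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"ordering violated: {upper} posterior to {lower} at A-scan {j}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "x_um": self.x_um.tolist(),
            "curves": {n: [None if not np.isfinite(v) else float(v) for v in z]
                       for n, z in self.curves.items()},
            "disc_edge_nasal_um": self.disc_edge_nasal_um,
            "disc_edge_temporal_um": self.disc_edge_temporal_um,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "BoundarySet":
        d = json.loads(Path(path).read_text())
        curves = {n: np.array([np.nan if v is None else v for v in z], dtype=float)
                  for n, z in d["curves"].items()}
        return cls(np.asarray(d["x_um"], dtype=float), curves,
                   d.get("disc_edge_nasal_um"), d.get("disc_edge_temporal_um"))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"x_um": self.x_um})
        for n, z in self.curves.items():
            df[n + "_um"] = z
        df.attrs = {}
        df.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path,
                 disc_edge_nasal_um: float | None = None,
                 disc_edge_temporal_um: float | None = None) -> "BoundarySet":
        df = pd.read_csv(path)
        curves = {c[:-3]: df[c].to_numpy(float) for c in df.columns if c.endswith("_um")
                  and c != "x_um"}
        return cls(df["x_um"].to_numpy(float), curves,
                   disc_edge_nasal_um, disc_edge_temporal_um)


def mirror_boundaries(b: BoundarySet) -> BoundarySet:
    """Mirror a boundary set laterally (nasal and temporal sides swap).

    The lateral coordinate is reflected about the scan midline; disc edges
    swap roles. Pair with flipping ``ScanMeta.nasal_side`` so measurements
    keep their anatomical labels.
    """
    if len(b.x_um) < 2:
        raise ValueError("need at least two A-scans to mirror")
    total = b.x_um[0] + b.x_um[-1]  # reflection keeps the same sample grid
    curves = {n: z[::-1].copy() for n, z in b.curves.items()}
    en = None if b.disc_edge_nasal_um is None else total - b.disc_edge_nasal_um
    et = None if b.disc_edge_temporal_um is None else total - b.disc_edge_temporal_um
    return BoundarySet(b.x_um.copy(), curves, en, et)


def flip_nasal_side(meta: ScanMeta) -> ScanMeta:
    return dataclasses.replace(
        meta, nasal_side="right" if meta.nasal_side == "left" else "left")
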