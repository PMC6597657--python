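"""Published group statistics and diagnostic thresholds used as study inputs.

The per-group means and standard deviations below summarise the hand-held
OCT morphometry of primary congenital glaucoma (PCG) in children, adult
primary open-angle glaucoma (POAG), and their age-matched control groups.
They parameterise the synthetic cohort generator: no per-eye raw data are
available, so cohorts are drawn from these marginal distributions.

Units: degrees of visual angle for lateral extents, micrometres for axial
extents, degree-micrometres for the mixed cup/rim areas (lateral degrees x
axial micrometres), years for age.
"""

from __future__ import annotations

from .synth import GroupStats

#: cohort-table column names for the optic-nerve and foveal parameters
ONH_PARAMS = (
    "disc_diameter_deg",
    "cup_disc_ratio",
    "cup_diameter_deg",
    "cup_area_degum",
    "cup_depth_um",
    "rim_width_deg",
    "rim_area_degum",
    "rnfl_nasal_um",
    "rnfl_temporal_um",
)

FOVEA_PARAMS = ("foveal_pit_width_deg",)

_BOUNDS = {
    "disc_diameter_deg": (1.0, 12.0),
    "cup_disc_ratio": (0.0, 1.0),
    "cup_diameter_deg": (0.0, 12.0),
    "cup_area_degum": (0.0, float("inf")),
    "cup_depth_um": (0.0, float("inf")),
    "rim_width_deg": (0.0, 12.0),
    "rim_area_degum": (0.0, float("inf")),
    "rnfl_nasal_um": (0.0, 300.0),
    "rnfl_temporal_um": (0.0, 300.0),
    "foveal_pit_width_deg": (5.0, 13.0),
    "age_years": (0.1, 110.0),
}


def _stats(name, rows):
    return GroupStats(
        name=name,
        params={k: (m, s) for k, m, s in rows},
        bounds={k: _BOUNDS[k] for k, _, _ in rows},
    )


#: children with primary congenital glaucoma (affected eyes)
PCG = _stats("pcg", [
    ("disc_diameter_deg", 5.596, 0.851),
    ("cup_disc_ratio", 0.668, 0.173),
    ("cup_diameter_deg", 3.782, 1.288),
    ("cup_area_degum", 1491.3, 778.2),
    ("cup_depth_um", 781.8, 196.1),
    ("rim_width_deg", 1.814, 0.947),
    ("rim_area_degum", 215.0, 212.4),
    ("rnfl_nasal_um", 51.1, 20.0),
    ("rnfl_temporal_um", 59.6, 17.6),
    ("foveal_pit_width_deg", 8.38, 1.00),
    ("age_years", 4.45, 2.82),
])

#: healthy children matched to the PCG group
PCG_CONTROL = _stats("pcg_control", [
    ("disc_diameter_deg", 6.014, 0.578),
    ("cup_disc_ratio", 0.398, 0.178),
    ("cup_diameter_deg", 2.381, 1.061),
    ("cup_area_degum", 503.6, 451.7),
    ("cup_depth_um", 473.5, 144.0),
    ("rim_width_deg", 3.633, 1.198),
    ("rim_area_degum", 590.3, 309.5),
    ("rnfl_nasal_um", 66.1, 21.1),
    ("rnfl_temporal_um", 60.4, 13.0),
    ("foveal_pit_width_deg", 9.62, 0.65),
    ("age_years", 4.73, 2.81),
])

#: adults with primary open-angle glaucoma
POAG = _stats("poag", [
    ("disc_diameter_deg", 5.536, 0.612),
    ("cup_disc_ratio", 0.804, 0.109),
    ("cup_diameter_deg", 4.470, 0.876),
    ("cup_area_degum", 1636.0, 633.4),
    ("cup_depth_um", 668.0, 148.8),
    ("rim_width_deg", 1.066, 0.531),
    ("rim_area_degum", 79.03, 85.6),
    ("rnfl_nasal_um", 46.0, 9.08),
    ("rnfl_temporal_um", 47.9, 8.95),
    ("age_years", 67.0, 6.96),
])

#: healthy adults matched to the POAG group
POAG_CONTROL = _stats("poag_control", [
    ("disc_diameter_deg", 5.180, 0.513),
    ("cup_disc_ratio", 0.551, 0.087),
    ("cup_diameter_deg", 2.866, 0.612),
    ("cup_area_degum", 695.0, 175.6),
    ("cup_depth_um", 572.5, 90.7),
    ("rim_width_deg", 2.314, 0.449),
    ("rim_area_degum", 294.8, 128.4),
    ("rnfl_nasal_um", 57.8, 18.19),
    ("rnfl_temporal_um", 50.4, 5.1),
    ("age_years", 66.8, 7.50),
])

#: published fixed diagnostic thresholds (parameter, threshold, direction)
FIXED_RULES = (
    ("cup_disc_ratio", 0.5, "ge_is_case"),
    ("cup_diameter_deg", 2.8, "ge_is_case"),
    ("cup_depth_um", 600.0, "ge_is_case"),
    ("rim_width_deg", 2.8, "le_is_case"),
    ("rim_area_degum", 400.0, "le_is_case"),
)

#: published diagnostic accuracy (percent) for the rules above, same order
PUBLISHED_SENSITIVITY = (81.5, 74.1, 81.5, 88.9, 88.9)
PUBLISHED_SPECIFICITY = (80.0, 70.0, 85.0, 80.0, 75.0)
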