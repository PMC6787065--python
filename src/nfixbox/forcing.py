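"""Synthetic forcing climatologies: aeolian iron, nitrogen deposition,
surface temperature and sea-ice cover.

The iron deposition emulates the structure of the modern dust climatology
(high in the northwest Pacific and Atlantic dust plumes, low in the eastern
equatorial Pacific) and of the glacial climatology, in which the global
integral rises five-fold while the tropical Pacific receives roughly
two-fold more iron than under modern conditions.

Everything here is deterministic: identical inputs give bit-identical
fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BoxGeometry
from .units import MOL_PER_TG_N

MODERN_SCALES = (25, 50, 75, 80, 90, 100, 125, 150, 200, 300, 400)
GLACIAL_SCALES = (500, 2500)

#: modern soluble-Fe deposition (umol Fe m-2 yr-1) per surface region
MODERN_FE_FLUX = {
    "trop_pac_east_surface": 8.0,
    "trop_pac_west_surface": 8.0,
    "trop_atl_surface": 10.0,
    "subtrop_surface": 6.0,
    "subtrop_s_surface": 2.5,
    "npac_surface": 25.0,
    "natl_surface": 35.0,
    "so_surface": 1.5,
}

#: regions treated as the tropical Pacific for the glacial 2-fold rule
TROPICAL_PACIFIC = ("trop_pac_east_surface", "trop_pac_west_surface")

N_DEP_RELATIVE = {            # relative per-area N deposition weights
    "trop_pac_east_surface": 0.5,
    "trop_pac_west_surface": 1.5,
    "trop_atl_surface": 1.2,
    "subtrop_surface": 2.0,
    "subtrop_s_surface": 0.8,
    "npac_surface": 1.5,
    "natl_surface": 1.8,
    "so_surface": 0.2,
}
N_DEP_TOTAL_TG = 11.3

MEAN_TEMP = {"warm": 5.3, "mild": 3.9, "cool": 3.5, "cold": 1.4}
SALINITY = {"warm": 34.72, "mild": 34.50, "cool": 34.38, "cold": 35.49}
SURFACE_DT = {"warm": 1.5, "mild": 0.0, "cool": -0.5, "cold": -2.0}

#: annual-mean base temperature (deg C) of the mild state, by tag
BASE_TEMP = {
    "trop_pac_east_surface": 24.0, "trop_pac_west_surface": 29.0,
    "trop_atl_surface": 26.0, "subtrop_surface": 22.0,
    "subtrop_s_surface": 21.0, "npac_surface": 8.0, "natl_surface": 7.0,
    "so_surface": 2.0, "thermocline_east": 11.0, "thermocline_west": 14.0,
    "thermocline_atl": 13.0, "thermocline_sub": 15.0,
    "intermediate_s": 4.0, "intermediate_n": 4.0, "deep": 2.2,
    "abyssal": 1.2,
}
SEASONAL_AMP = {
    "trop_pac_east_surface": 1.0, "trop_pac_west_surface": 1.0,
    "trop_atl_surface": 1.0, "subtrop_surface": 3.0,
    "subtrop_s_surface": 3.0, "npac_surface": 4.0, "natl_surface": 4.0,
    "so_surface": 2.0,
}
ICE_ANNUAL = {   # annual-mean ice fraction: (so, npac, natl)
    "warm": (0.12, 0.00, 0.00),
    "mild": (0.35, 0.05, 0.05),
    "cool": (0.45, 0.10, 0.10),
    "cold": (0.65, 0.25, 0.30),
}
FREEZING_T = -1.9


@dataclass
class FeDepositionField:
    """Per-surface-box aeolian Fe flux (umol Fe m-2 yr-1)."""

    pattern: str
    scale_percent: float
    flux: np.ndarray                 # aligned with geometry surface boxes
    surface_indices: np.ndarray

    def global_integral(self, geom: BoxGeometry) -> float:
        """Global deposition in mol Fe yr-1."""
        return float((self.flux * geom.area[self.surface_indices]).sum() * 1e-6)


def make_fe_deposition(geom: BoxGeometry, pattern: str,
                       scale_percent: float) -> FeDepositionField:
    """Build an iron-deposition field.

    ``pattern='modern'`` scales the modern climatology by a constant factor
    (valid scales 25-400%).  ``pattern='glacial'`` uses the glacial dust
    climatology: at 500% the global integral is five times the modern one
    while the tropical Pacific receives only about twice its modern flux;
    2500% is five times the 500% field (higher assumed Fe solubility of the
    same dust field).
    """
    surf = geom.surface_indices
    modern = np.array([MODERN_FE_FLUX[geom.tags[i]] for i in surf])
    areas = geom.area[surf]

    if pattern == "modern":
        if not (25 <= scale_percent <= 400):
            raise ValueError(
                f"modern pattern supports scales 25-400%, got {scale_percent}")
        flux = modern * (scale_percent / 100.0)
    elif pattern == "glacial":
        if scale_percent not in GLACIAL_SCALES:
            raise ValueError(
                f"glacial pattern supports scales {GLACIAL_SCALES}, "
                f"got {scale_percent}")
        trop = np.array([geom.tags[i] in TROPICAL_PACIFIC for i in surf])
        total = float((modern * areas).sum())
        total_trop = float((modern * areas)[trop].sum())
        # tropical Pacific doubles; the rest absorbs the remaining supply so
        # that the global integral is exactly 5x modern
        other_factor = (5.0 * total - 2.0 * total_trop) / (total - total_trop)
        flux_500 = np.where(trop, 2.0 * modern, other_factor * modern)
        flux = flux_500 * (scale_percent / 500.0)
    else:
        raise ValueError(f"unknown deposition pattern {pattern!r}")

    return FeDepositionField(pattern=pattern, scale_percent=scale_percent,
                             flux=flux, surface_indices=surf)


@dataclass
class NDepositionField:
    """Monthly N deposition (mol N m-2 yr-1 rate per month) on surface boxes."""

    flux_monthly: np.ndarray         # (12, n_surface)
    surface_indices: np.ndarray

    def annual_integral_tg(self, geom: BoxGeometry) -> float:
        area = geom.area[self.surface_indices]
        mol = float((self.flux_monthly.mean(axis=0) * area).sum())
        return mol / MOL_PER_TG_N


def make_n_deposition(geom: BoxGeometry,
                      total_tg: float = N_DEP_TOTAL_TG) -> NDepositionField:
    """Monthly N-deposition climatology, normalised so that the annual
    global integral is exactly ``total_tg`` Tg N yr-1 (renormalised for any
    geometry)."""
    surf = geom.surface_indices
    if len(surf) == 0:
        raise ValueError("geometry has no surface boxes")
    rel = np.array([N_DEP_RELATIVE[geom.tags[i]] for i in surf])
    months = np.arange(12)
    # mild seasonality: northern-hemisphere spring maximum for the
    # NH-weighted boxes, antiphase in the south
    nh = np.array([geom.tags[i] in ("subtrop_surface", "npac_surface",
                                    "natl_surface", "trop_pac_west_surface")
                   for i in surf])
    season = 1.0 + 0.3 * np.cos(2 * np.pi * (months[:, None] - 4) / 12.0)
    season_s = 1.0 + 0.3 * np.cos(2 * np.pi * (months[:, None] - 10) / 12.0)
    flux = rel[None, :] * np.where(nh[None, :], season, season_s)

    area = geom.area[surf]
    integral_mol = float((flux.mean(axis=0) * area).sum())
    flux *= (total_tg * MOL_PER_TG_N) / integral_mol
    return NDepositionField(flux_monthly=flux, surface_indices=surf)


@dataclass
class Climatology:
    """Monthly surface climatology plus annual-mean interior temperatures."""

    state_name: str
    temp_monthly: np.ndarray         # (12, n_box) deg C
    ico_monthly: np.ndarray          # (12, n_box), 0 for ice-free boxes
    salinity: float                  # psu, uniform per state

    @property
    def temp_annual(self) -> np.ndarray:
        return self.temp_monthly.mean(axis=0)

    def volume_mean_temp(self, geom: BoxGeometry) -> float:
        return float((self.temp_annual * geom.volume).sum() / geom.volume.sum())


def make_climatology(geom: BoxGeometry, state_name: str) -> Climatology:
    """Temperature/ice/salinity climatology for one physical state.

    Surface temperatures are the mild-state pattern shifted by a per-state
    offset; interior temperatures are shifted by a solved constant so that
    the volume-weighted annual mean matches the state's global mean
    temperature exactly (subject to the freezing point).
    """
    if state_name not in MEAN_TEMP:
        raise ValueError(f"unknown state {state_name!r}")
    n = geom.n_box
    surf_mask = geom.surface_mask
    base = np.array([BASE_TEMP[t] for t in geom.tags])
    temp = base.copy()
    temp[surf_mask] += SURFACE_DT[state_name]
    temp[surf_mask] = np.maximum(temp[surf_mask], FREEZING_T)

    # solve the interior offset so the volume mean hits the target
    target = MEAN_TEMP[state_name]
    vol = geom.volume
    interior = ~surf_mask
    free = interior.copy()
    for _ in range(8):
        fixed_sum = float((temp[~free] * vol[~free]).sum())
        delta = (target * vol.sum() - fixed_sum
                 - float((base[free] * vol[free]).sum())) / float(vol[free].sum())
        temp[free] = base[free] + delta
        clipped = free & (temp < FREEZING_T)
        if not clipped.any():
            break
        temp[clipped] = FREEZING_T
        free = free & ~clipped
        if not free.any():
            break

    months = np.arange(12)
    amp = np.array([SEASONAL_AMP.get(t, 0.0) for t in geom.tags])
    cycle = np.cos(2 * np.pi * (months[:, None] - 7) / 12.0)  # NH late-summer max
    temp_monthly = temp[None, :] + amp[None, :] * cycle
    temp_monthly = np.maximum(temp_monthly, FREEZING_T)

    ico = np.zeros((12, n))
    so_mean, npac_mean, natl_mean = ICE_ANNUAL[state_name]
    # Southern-hemisphere ice peaks in austral winter (opposite phase)
    ico[:, geom.index("so_surface")] = so_mean - 0.25 * cycle[:, 0]
    ico[:, geom.index("npac_surface")] = npac_mean + 0.10 * cycle[:, 0]
    ico[:, geom.index("natl_surface")] = natl_mean + 0.10 * cycle[:, 0]
    ico = np.clip(ico, 0.0, 1.0)

    return Climatology(state_name=state_name, temp_monthly=temp_monthly,
                       ico_monthly=ico, salinity=SALINITY[state_name])
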