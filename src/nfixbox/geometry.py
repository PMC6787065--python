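"""Box geometry for the desk-scale ocean.

Sixteen boxes: eight surface regions (two tropical Pacific boxes separating
the eastern upwelling zone from the western warm pool, a tropical
Atlantic/Indian box, two subtropical gyre boxes, and the three high-latitude
source regions), four thermocline boxes, two intermediate-water boxes and
two deep boxes.  This is the smallest arrangement that separates the
regions the low-latitude iron/nitrogen mechanism distinguishes.

Sub-grid bathymetry is emulated by a per-box ``sediment_contact_fraction``:
the fraction of sinking organic matter entering a depth level that is
intercepted by sediments at that level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# canonical region tags that any geometry must cover (by prefix match)
REQUIRED_TAGS = (
    "trop_pac_east_surface", "trop_pac_west_surface", "subtrop_surface",
    "so_surface", "natl_surface", "npac_surface",
    "thermocline_east", "thermocline_west", "intermediate", "deep",
)

#: default box table: tag, volume (1e16 m3), surface area (1e12 m2),
#: mid depth (m), sediment contact fraction, seafloor depth (km, surface
#: boxes only; used by the d15N_org depth correction)
DEFAULT_BOXES = [
    # tag                     vol    area  z_mid  f_sed  seafloor_km
    ("trop_pac_east_surface", 0.12, 12.0, 50.0, 0.00, 3.5),
    ("trop_pac_west_surface", 0.40, 40.0, 50.0, 0.00, 4.3),
    ("trop_atl_surface",      0.25, 25.0, 50.0, 0.00, 4.0),
    ("subtrop_surface",       0.70, 70.0, 50.0, 0.00, 4.8),
    ("subtrop_s_surface",     0.70, 70.0, 50.0, 0.00, 4.6),
    ("npac_surface",          0.20, 20.0, 50.0, 0.00, 5.0),
    ("natl_surface",          0.25, 25.0, 50.0, 0.00, 4.2),
    ("so_surface",            0.78, 78.0, 50.0, 0.00, 4.0),
    ("thermocline_east",      2.50,  0.0, 550.0, 0.10, np.nan),
    ("thermocline_west",      5.00,  0.0, 550.0, 0.02, np.nan),
    ("thermocline_atl",       1.20,  0.0, 550.0, 0.04, np.nan),
    ("thermocline_sub",      13.80,  0.0, 550.0, 0.01, np.nan),
    ("intermediate_s",       15.00,  0.0, 1500.0, 0.03, np.nan),
    ("intermediate_n",       10.00,  0.0, 1500.0, 0.03, np.nan),
    ("deep",                 40.00,  0.0, 2750.0, 0.03, np.nan),
    ("abyssal",              42.10,  0.0, 4300.0, 1.00, np.nan),
]

#: sinking columns: surface tag -> ordered subsurface tags, with the depth
#: interval (top, bottom in metres) each box spans in that column
DEFAULT_COLUMNS = {
    "trop_pac_east_surface": [("thermocline_east", 100, 1000),
                              ("intermediate_s", 1000, 2000),
                              ("deep", 2000, 3500), ("abyssal", 3500, 5000)],
    "trop_pac_west_surface": [("thermocline_west", 100, 1000),
                              ("intermediate_s", 1000, 2000),
                              ("deep", 2000, 3500), ("abyssal", 3500, 5000)],
    "trop_atl_surface": [("thermocline_atl", 100, 1000),
                         ("intermediate_n", 1000, 2000),
                         ("deep", 2000, 3500), ("abyssal", 3500, 5000)],
    "subtrop_surface": [("thermocline_sub", 100, 1000),
                        ("intermediate_n", 1000, 2000),
                        ("deep", 2000, 3500), ("abyssal", 3500, 5000)],
    "subtrop_s_surface": [("thermocline_sub", 100, 1000),
                          ("intermediate_s", 1000, 2000),
                          ("deep", 2000, 3500), ("abyssal", 3500, 5000)],
    "npac_surface": [("intermediate_n", 100, 2000),
                     ("deep", 2000, 3500), ("abyssal", 3500, 5000)],
    "natl_surface": [("intermediate_n", 100, 2000),
                     ("deep", 2000, 3500), ("abyssal", 3500, 5000)],
    "so_surface": [("intermediate_s", 100, 2000),
                   ("deep", 2000, 3500), ("abyssal", 3500, 5000)],
}

#: boxes whose Fe is relaxed toward the subsurface target: every
#: subsurface box plus the three high-latitude surface boxes, whose strong
#: vertical exchange with Fe-replete deep water renders them structurally
#: insensitive to aeolian supply.  Only the five low-latitude surface
#: boxes carry freely evolving iron.
DEFAULT_FE_RELAX = [
    "npac_surface", "natl_surface", "so_surface",
    "thermocline_east", "thermocline_west", "thermocline_atl",
    "thermocline_sub",
    "intermediate_s", "intermediate_n", "deep", "abyssal",
]

DEFAULT_TOTAL_VOLUME = 1.33e18  # m3


def default_config() -> dict:
    return {
        "total_volume": DEFAULT_TOTAL_VOLUME,
        "boxes": [list(row) for row in DEFAULT_BOXES],
        "columns": {k: [list(r) for r in v] for k, v in DEFAULT_COLUMNS.items()},
        "fe_relax_boxes": list(DEFAULT_FE_RELAX),
    }


@dataclass
class BoxGeometry:
    tags: list[str]
    volume: np.ndarray                # m3
    area: np.ndarray                  # m2, 0 for subsurface boxes
    mid_depth: np.ndarray             # m
    sediment_contact_fraction: np.ndarray
    seafloor_km: np.ndarray           # NaN for subsurface boxes
    columns: dict = field(default_factory=dict)   # surface idx -> [(idx, ztop, zbot)]
    fe_relax_mask: np.ndarray | None = None

    @property
    def n_box(self) -> int:
        return len(self.tags)

    @property
    def surface_mask(self) -> np.ndarray:
        return self.area > 0

    @property
    def surface_indices(self) -> np.ndarray:
        return np.flatnonzero(self.surface_mask)

    @property
    def thickness(self) -> np.ndarray:
        """Effective thickness (m) of surface boxes (volume / area)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.area > 0, self.volume / np.maximum(self.area, 1.0), np.nan)

    @property
    def total_volume(self) -> float:
        return float(self.volume.sum())

    def index(self, tag: str) -> int:
        return self.tags.index(tag)

    def volume_fraction(self, mask: np.ndarray) -> float:
        return float(self.volume[mask].sum() / self.volume.sum())


def make_geometry(config: dict | None = None) -> BoxGeometry:
    """Build a :class:`BoxGeometry` from a configuration dictionary.

    Deterministic: identical config gives a bit-identical geometry.
    """
    cfg = config if config is not None else default_config()
    rows = cfg["boxes"]
    if len(rows) < 12:
        raise ValueError("geometry config must define at least 12 boxes")

    tags = [r[0] for r in rows]
    for required in REQUIRED_TAGS:
        stem = required.replace("_surface", "")
        if not any(t.startswith(stem) for t in tags):
            raise ValueError(f"geometry config missing region tag {required!r}")

    volume = np.array([r[1] for r in rows], dtype=float) * 1e16
    area = np.array([r[2] for r in rows], dtype=float) * 1e12
    mid_depth = np.array([r[3] for r in rows], dtype=float)
    f_sed = np.array([r[4] for r in rows], dtype=float)
    seafloor = np.array([r[5] for r in rows], dtype=float)

    if np.any((f_sed < 0) | (f_sed > 1)):
        raise ValueError("sediment_contact_fraction must lie in [0, 1]")

    total = cfg.get("total_volume", DEFAULT_TOTAL_VOLUME)
    if abs(volume.sum() - total) > 1e-3 * total:
        raise ValueError(
            f"box volumes sum to {volume.sum():.4g}, expected {total:.4g}")

    index = {t: i for i, t in enumerate(tags)}
    columns = {}
    for surf_tag, path in cfg["columns"].items():
        columns[index[surf_tag]] = [(index[t], float(zt), float(zb))
                                    for t, zt, zb in path]

    relax = np.zeros(len(tags), dtype=bool)
    for t in cfg.get("fe_relax_boxes", []):
        relax[index[t]] = True

    return BoxGeometry(tags=tags, volume=volume, area=area,
                       mid_depth=mid_depth,
                       sediment_contact_fraction=f_sed,
                       seafloor_km=seafloor, columns=columns,
                       fe_relax_mask=relax)
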