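"""Volume-conserving circulation for the four named physical states.

The circulation is a set of closed advective loops (volume conservation is
then exact by construction) plus bidirectional mixing edges.  The lower
overturning cell is tagged AABW-like, the upper cell NADW-like, and the
subtropical cells feed equatorial upwelling into the eastern tropical
Pacific surface box.  Loop magnitudes follow the overturning strengths of
the four states:

=========  =====  =====  =====  =====
state       warm   mild   cool   cold
=========  =====  =====  =====  =====
Psi_AABW     7.2   11.5   11.4   39.0
Psi_NADW    20.3   18.4   13.0   13.0
upwelling   strongest in the warm state, weakest in the cold state
=========  =====  =====  =====  =====
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BoxGeometry
from .units import SV_TO_M3_PER_YEAR

STATE_NAMES = ("warm", "mild", "cool", "cold")

PSI_AABW = {"warm": 7.2, "mild": 11.5, "cool": 11.4, "cold": 39.0}
PSI_NADW = {"warm": 20.3, "mild": 18.4, "cool": 13.0, "cold": 13.0}

# subtropical-cell / upwelling magnitudes (Sv) ranked warm > mild >= cool > cold
UPWELL_PAC = {"warm": 40.0, "mild": 30.0, "cool": 28.0, "cold": 18.0}
UPWELL_PAC_S = {"warm": 20.0, "mild": 15.0, "cool": 14.0, "cold": 9.0}
UPWELL_ATL = {"warm": 12.0, "mild": 10.0, "cool": 9.0, "cold": 6.0}
NPIW = {"warm": 4.5, "mild": 4.0, "cool": 3.5, "cold": 2.5}
SAMW = {"warm": 14.0, "mild": 12.0, "cool": 11.0, "cold": 6.0}

# vertical-mixing scale factor: the cold state is strongly stratified
MIX_FACTOR = {"warm": 1.2, "mild": 1.0, "cool": 0.9, "cold": 0.45}

# renewal of the tropical OMZ thermoclines relative to the mild state: a
# property of each emulated climate (shadow-zone ventilation differs
# between the underlying circulation fields)
OMZ_VENT = {"warm": 1.5, "mild": 1.5, "cool": 1.55, "cold": 2.2}


@dataclass
class Circulation:
    name: str
    edges: list          # (tag_from, tag_to, Sv) advective, one-way
    mixing: list         # (tag_a, tag_b, Sv) bidirectional
    psi_aabw_sv: float
    psi_nadw_sv: float
    upwelling_sv: float  # total upwelling into the eastern tropical surface
    _matrix: np.ndarray | None = field(default=None, repr=False)

    def transport_matrix(self, geom: BoxGeometry) -> np.ndarray:
        """Linear operator M (yr-1): dC/dt = M @ C, volume conserving.

        Upwind advection: an edge u->v carrying q m3/yr contributes
        q (C_u - C_v) / V_v to box v.  A uniform tracer field therefore has
        an exactly null tendency.
        """
        if self._matrix is not None:
            return self._matrix
        n = geom.n_box
        m = np.zeros((n, n))
        vol = geom.volume

        def add_flow(u: int, v: int, q: float) -> None:
            m[v, u] += q / vol[v]
            m[v, v] -= q / vol[v]

        for tag_u, tag_v, sv in self.edges:
            q = sv * SV_TO_M3_PER_YEAR
            add_flow(geom.index(tag_u), geom.index(tag_v), q)
        for tag_a, tag_b, sv in self.mixing:
            q = sv * SV_TO_M3_PER_YEAR
            a, b = geom.index(tag_a), geom.index(tag_b)
            add_flow(a, b, q)
            add_flow(b, a, q)
        self._matrix = m
        return m

    def box_inflow_outflow(self, geom: BoxGeometry) -> tuple[np.ndarray, np.ndarray]:
        """Advective inflow and outflow (m3/yr) per box; equal when closed."""
        n = geom.n_box
        inflow = np.zeros(n)
        outflow = np.zeros(n)
        for tag_u, tag_v, sv in self.edges:
            q = sv * SV_TO_M3_PER_YEAR
            outflow[geom.index(tag_u)] += q
            inflow[geom.index(tag_v)] += q
        return inflow, outflow


def _loop(tags: list[str], sv: float) -> list:
    return [(tags[i], tags[(i + 1) % len(tags)], sv) for i in range(len(tags))]


def make_circulation(state_name: str) -> Circulation:
    """Construct one of the four named circulation states."""
    if state_name not in STATE_NAMES:
        raise ValueError(
            f"unknown circulation state {state_name!r}; "
            f"expected one of {STATE_NAMES}")

    a = PSI_AABW[state_name]
    nadw = PSI_NADW[state_name]
    u_pac = UPWELL_PAC[state_name]
    u_pac_s = UPWELL_PAC_S[state_name]
    u_atl = UPWELL_ATL[state_name]
    npiw = NPIW[state_name]
    samw = SAMW[state_name]
    mf = MIX_FACTOR[state_name]
    ov = OMZ_VENT[state_name]

    edges: list = []
    # lower cell (AABW-like); in the cold state most of the greatly
    # expanded cell recirculates at depth without surface contact, which
    # keeps the glacial abyss old despite the large formation rate
    a_surface = min(a, 12.0)
    edges += _loop(["so_surface", "abyssal", "deep", "intermediate_s"],
                   a_surface)
    if a > a_surface:
        edges += _loop(["intermediate_s", "abyssal", "deep"], a - a_surface)
    # upper cell (NADW-like), returning through both intermediate boxes
    edges += _loop(["natl_surface", "deep", "intermediate_s",
                    "thermocline_sub", "subtrop_surface"], 0.6 * nadw)
    edges += _loop(["natl_surface", "deep", "intermediate_n",
                    "thermocline_sub", "subtrop_surface"], 0.4 * nadw)
    # Pacific subtropical cells -> equatorial upwelling in the east
    edges += _loop(["subtrop_surface", "thermocline_sub", "thermocline_west",
                    "thermocline_east", "trop_pac_east_surface",
                    "trop_pac_west_surface"], u_pac)
    edges += _loop(["subtrop_s_surface", "thermocline_sub",
                    "thermocline_west", "thermocline_east",
                    "trop_pac_east_surface", "trop_pac_west_surface"],
                   u_pac_s)
    # Atlantic/Indian tropical cell
    edges += _loop(["subtrop_s_surface", "thermocline_atl",
                    "trop_atl_surface"], u_atl)
    # North Pacific intermediate water
    edges += _loop(["npac_surface", "intermediate_n", "thermocline_west",
                    "trop_pac_west_surface"], npiw)
    # Subantarctic mode / intermediate water
    edges += _loop(["so_surface", "intermediate_s", "thermocline_sub",
                    "subtrop_s_surface"], samw)

    mixing = [
        # high-latitude vertical exchange (stratification dependent)
        ("so_surface", "deep", 20.0 * mf),
        ("so_surface", "intermediate_s", 10.0 * mf),
        ("npac_surface", "intermediate_n", 5.0 * mf),
        ("natl_surface", "deep", 8.0 * mf),
        # surface <-> thermocline
        ("trop_pac_east_surface", "thermocline_east", 0.5 * mf),
        ("trop_pac_west_surface", "thermocline_west", 3.0 * mf),
        ("trop_atl_surface", "thermocline_atl", 2.0 * mf),
        ("subtrop_surface", "thermocline_sub", 5.0 * mf),
        ("subtrop_s_surface", "thermocline_sub", 5.0 * mf),
        # thermocline <-> intermediate
        ("thermocline_east", "intermediate_s", 0.5 * mf),
        ("thermocline_west", "intermediate_s", 3.0 * mf * ov),
        ("thermocline_atl", "intermediate_n", 2.0 * mf * ov),
        ("thermocline_sub", "intermediate_n", 5.0 * mf),
        ("thermocline_sub", "intermediate_s", 4.0 * mf),
        # intermediate <-> deep <-> abyssal
        ("intermediate_s", "deep", 6.0 * mf),
        ("intermediate_n", "deep", 4.0 * mf),
        ("deep", "abyssal", 6.0 * mf),
        # lateral surface exchange (not stratification dependent)
        ("trop_pac_west_surface", "subtrop_surface", 5.0),
        ("trop_pac_west_surface", "subtrop_s_surface", 5.0),
        ("trop_atl_surface", "subtrop_s_surface", 3.0),
        ("subtrop_surface", "npac_surface", 3.0),
        ("subtrop_surface", "natl_surface", 3.0),
        ("subtrop_s_surface", "so_surface", 4.0),
        ("thermocline_west", "thermocline_east", 1.5),
    ]

    return Circulation(name=state_name, edges=edges, mixing=mixing,
                       psi_aabw_sv=a, psi_nadw_sv=nadw,
                       upwelling_sv=u_pac + u_pac_s)


def ideal_age_steady(circ: Circulation, geom: BoxGeometry,
                     surface_restore_yr: float = 0.05) -> np.ndarray:
    """Steady-state ideal age (years) under a circulation.

    Solves 0 = M a + 1 - (restore at the surface), a linear system; the
    surface boxes are restored to zero age on a fast timescale.  Used to
    rank the ventilation of the four states without time stepping.
    """
    m = circ.transport_matrix(geom).copy()
    n = geom.n_box
    src = np.ones(n)
    restore = np.where(geom.surface_mask, 1.0 / surface_restore_yr, 0.0)
    m[np.diag_indices(n)] -= restore
    return np.linalg.solve(-m, src)
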