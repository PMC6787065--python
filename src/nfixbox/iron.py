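"""Iron cycle: aeolian deposition, biological uptake/release and the deep
relaxation control.

Iron is not globally conserved: deposition is an external source and the
relaxation of floor-contacting (and high-latitude) boxes toward the target
concentration acts as either source or sink.  The budget diagnostic
closes: d(total Fe)/dt = deposition + net relaxation.
"""

from __future__ import annotations

import numpy as np

from .forcing import FeDepositionField
from .geometry import BoxGeometry
from .params import FeParams


def deposition_tendency(field: FeDepositionField, geom: BoxGeometry):
    """Surface Fe tendency (umol m-3 yr-1) from aeolian deposition."""
    tend = np.zeros(geom.n_box)
    surf = field.surface_indices
    thickness = geom.volume[surf] / geom.area[surf]
    tend[surf] = field.flux / thickness
    return tend


def relaxation_update(fe, geom: BoxGeometry, params: FeParams, dt: float):
    """Exact exponential relaxation of flagged boxes toward the target.

    Returns (new_fe, delta): Fe(t+dt) = target + (Fe - target) exp(-dt/tau)
    on relaxed boxes, unchanged elsewhere.  Unconditionally stable and
    matches the closed-form solution of dFe/dt = (target - Fe)/tau.
    """
    fe = np.asarray(fe, dtype=float)
    mask = geom.fe_relax_mask
    decay = np.exp(-dt / params.relax_timescale_yr)
    new = np.where(mask, params.relax_target + (fe - params.relax_target) * decay,
                   fe)
    return new, new - fe


def bio_uptake(p_exp, fe_to_p):
    """Fe uptake (umol m-3 day-1) implied by P export at a Fe:P ratio.

    Fe:P is mol:mol; with P in mmol m-3 and Fe carried in umol m-3 the
    conversion factor is 1000.
    """
    return np.asarray(p_exp) * np.asarray(fe_to_p) * 1e3
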