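"""Nitrogen-isotope bookkeeping.

The model carries total NO3 and its 15N content (NO3_15 <= NO3) per box.
delta-15N is defined against the atmospheric N2 standard:

    delta = (R / R_std - 1) * 1000,  R = NO3_15 / (NO3 - NO3_15)

Process fractionation uses a linear open-system rule per (sub)step: a flux
removing a fraction f of a pool with fractionation factor eps carries
delta_removed = delta_pool - eps * (1 - f), so the residual pool delta
rises by eps * f and total 15N is conserved exactly by construction.
Sub-stepping keeps per-step utilisation small so the linearisation error
stays small.
"""

from __future__ import annotations

import numpy as np

MISSING = np.nan


def delta15n(no3_15, no3, r_std: float = 0.0036765):
    """per-mil delta of a (15N, total N) pool; NaN where the pool is empty."""
    no3 = np.asarray(no3, dtype=float)
    no3_15 = np.asarray(no3_15, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = no3_15 / (no3 - no3_15)
        delta = (r / r_std - 1.0) * 1e3
    return np.where(no3 > 0, delta, MISSING)


def pool_15n(delta, no3, r_std: float = 0.0036765):
    """15N content of a pool with a given delta (inverse of delta15n)."""
    r = r_std * (1.0 + np.asarray(delta, dtype=float) / 1e3)
    return np.asarray(no3, dtype=float) * r / (1.0 + r)


def atom_fraction(delta, r_std: float = 0.0036765):
    r = r_std * (1.0 + np.asarray(delta, dtype=float) / 1e3)
    return r / (1.0 + r)


def fractionating_flux(no3, no3_15, flux, eps, r_std: float = 0.0036765):
    """15N carried by a fractionating removal flux.

    ``flux`` (total N) leaves a pool (no3, no3_15) with fractionation
    ``eps`` (per mil).  Returns the 15N flux, capped so the residual pool
    stays physical.  With eps = 0 the flux carries the pool composition
    unchanged.
    """
    no3 = np.asarray(no3, dtype=float)
    no3_15 = np.asarray(no3_15, dtype=float)
    flux = np.asarray(flux, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(no3 > 0, flux / no3, 0.0)
        d_pool = delta15n(no3_15, no3, r_std)
    d_removed = np.where(np.isfinite(d_pool), d_pool - eps * (1.0 - f), 0.0)
    x = atom_fraction(d_removed, r_std)
    flux15 = flux * x
    # keep the residual pool physical: 0 <= no3_15' <= no3'
    lower = np.maximum(0.0, no3_15 - (no3 - flux))
    upper = np.minimum(no3_15, flux)
    flux15 = np.clip(flux15, lower, upper)
    return np.where(flux > 0, flux15, 0.0)


def depth_correction(seafloor_km, per_km: float = 0.9):
    """Diagenetic delta-15N_org offset: +0.9 per mil per km of water depth."""
    return per_km * np.asarray(seafloor_km, dtype=float)


def d15n_org(assimilated_n, assimilated_15n, fixed_n, delta_fix,
             seafloor_km, per_km: float = 0.9, r_std: float = 0.0036765):
    """Export-weighted delta-15N of organic matter with depth correction.

    Organic N leaving a surface region is the sum of assimilated NO3 (with
    its 15N content) and newly fixed N at ``delta_fix``.  The diagenetic
    correction adds ``per_km`` per km of seafloor depth.
    """
    assimilated_n = np.asarray(assimilated_n, dtype=float)
    fixed_n = np.asarray(fixed_n, dtype=float)
    total = assimilated_n + fixed_n
    x_fix = atom_fraction(delta_fix, r_std)
    n15 = np.asarray(assimilated_15n, dtype=float) + fixed_n * x_fix
    with np.errstate(divide="ignore", invalid="ignore"):
        d_org = delta15n(n15, total, r_std)
    return np.where(total > 0, d_org + depth_correction(seafloor_km, per_km),
                    MISSING)
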