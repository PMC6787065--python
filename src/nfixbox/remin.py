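"""Redox partitioning of sinking organic matter.

Delivered organic matter is remineralised through a cascade:

* water column: aerobic remineralisation, switching to denitrification as
  O2 falls below a threshold (``f_den``), with a NO3 floor (``r_WCden``);
  matter that cannot be remineralised is passed to deeper boxes;
* sediments (the sub-grid bathymetry fraction of the sinking flux):
  denitrification at a rate set by the organic-carbon rain and the
  bottom-water O2 - NO3 contrast, then aerobic remineralisation limited to
  two-thirds of the overlying O2 and scaled down under hypoxia, and
  finally sulfate reduction for whatever remains.

All functions are pure and vectorised; the engine wires them into the
column-resolved budget.
"""

from __future__ import annotations

import numpy as np

from .params import RedoxParams


def wc_denit_fraction(o2, params: RedoxParams | None = None):
    """Fraction of water-column remineralisation carried by denitrification.

    f_den = (1 - exp(-0.5 R) + exp(O2 - 0.5 R))^-1 with R the O2 threshold;
    equal to 1 at O2 = 0 and strictly decreasing in O2.
    """
    p = params or RedoxParams()
    o2 = np.asarray(o2, dtype=float)
    half = 0.5 * p.r_lim_o2
    return 1.0 / (1.0 - np.exp(-half) + np.exp(o2 - half))


def wc_denit_no3_limiter(no3, params: RedoxParams | None = None):
    """NO3-availability cap on the water-column denitrification fraction."""
    p = params or RedoxParams()
    no3 = np.asarray(no3, dtype=float)
    return 0.5 + 0.5 * np.tanh(0.25 * no3 - 0.25 * p.r_lim_no3 - 2.5)


def effective_wc_denit_fraction(o2, no3, params: RedoxParams | None = None):
    """f_den capped by the NO3 limiter (applied as a hard minimum)."""
    f = wc_denit_fraction(o2, params)
    r = wc_denit_no3_limiter(no3, params)
    return np.minimum(f, r)


def wc_denit_no3_removal(f_den, p_org, n_rem_to_p):
    """NO3 consumed by water-column denitrification (Delta NO3 = f * P * N_rem:P)."""
    return np.asarray(f_den) * np.asarray(p_org) * np.asarray(n_rem_to_p)


def sed_denit_factor(o2_bottom, no3_bottom, params: RedoxParams | None = None):
    """NO3 removed per unit organic C delivered to the sediments.

    (alpha + beta * 0.98^(O2 - NO3)) * r_Sden, with
    r_Sden = 0.5 + 0.5 tanh(10 NO3 - 5) relaxing the rate toward zero as
    NO3 becomes scarce.  O2 here is the bottom-water value (the two-thirds
    rule applies only to sediment aerobic remineralisation).
    """
    p = params or RedoxParams()
    o2 = np.asarray(o2_bottom, dtype=float)
    no3 = np.asarray(no3_bottom, dtype=float)
    base = p.sed_alpha + p.sed_beta * 0.98 ** (o2 - no3)
    return base * sed_denit_no3_scaling(no3)


def sed_denit_no3_scaling(no3):
    return 0.5 + 0.5 * np.tanh(10.0 * np.asarray(no3, dtype=float) - 5.0)


def sed_aerobic_scaling(o2_bottom, params: RedoxParams | None = None):
    """Hypoxic throttle on sediment aerobic remineralisation.

    r_Srem = 0.5 + 0.5 tanh(0.2 O2 - 5): near 1 above the hypoxia
    threshold (O2 = 40 -> ~0.9975) and near 0 in anoxia.
    """
    o2 = np.asarray(o2_bottom, dtype=float)
    return 0.5 + 0.5 * np.tanh(0.2 * o2 - 5.0)


def sinking_attenuation(z_top, z_bottom, b):
    """Fraction of a Martin-curve flux passing from z_top to z_bottom.

    F(z) ~ z^-b, so the pass-through fraction across a layer is
    (z_bottom / z_top)^-b.
    """
    return (np.asarray(z_bottom, dtype=float) / np.asarray(z_top, dtype=float)) ** (
        -np.asarray(b, dtype=float))


def sinking_flux_partition(export: float, contact_fractions,
                           attenuation=None):
    """Split an export flux down a column into sediment deliveries.

    At each level, ``contact_fractions[i]`` of the flux entering the level
    is routed to the sediment pathway; the remainder is attenuated by the
    water-column factor (default 1: no water-column remineralisation) and
    passed on.  Returns (sediment_deliveries, watercolumn_remin,
    flux_leaving_bottom); the three always sum back to the export.
    """
    fr = np.asarray(contact_fractions, dtype=float)
    att = np.ones_like(fr) if attenuation is None else np.asarray(attenuation,
                                                                  dtype=float)
    sed = np.zeros_like(fr)
    wc = np.zeros_like(fr)
    flux = float(export)
    for i in range(len(fr)):
        sed[i] = fr[i] * flux
        passing = flux - sed[i]
        wc[i] = passing * (1.0 - att[i])
        flux = passing * att[i]
    return sed, wc, flux


def suboxic_fraction(o2, volume, threshold: float = 10.0) -> float:
    """Volume percentage of the ocean with O2 below ``threshold``."""
    o2 = np.asarray(o2, dtype=float)
    volume = np.asarray(volume, dtype=float)
    return float(volume[o2 < threshold].sum() / volume.sum() * 100.0)


def hypoxic_fraction(o2, volume, threshold: float = 40.0) -> float:
    o2 = np.asarray(o2, dtype=float)
    volume = np.asarray(volume, dtype=float)
    return float(volume[o2 < threshold].sum() / volume.sum() * 100.0)
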