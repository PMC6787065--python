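"""Surface carbonate chemistry, oxygen solubility and the atmosphere box.

The carbonate system is solved as a full DIC/ALK equilibrium over the
carbonate, borate and water self-ionisation balances, with dissociation
constants evaluated at box temperature and salinity (Weiss solubility;
Lueker carbonic-acid constants; Dickson borate; Millero water).  A Newton
iteration on pH converges in a handful of steps when warm-started from the
previous time step.

The atmosphere is a single well-mixed reservoir of fixed molar content
(5.1e21 g of air at 28.97 g mol-1); CO2 mole changes convert to ppm
through that constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import ATM_TOTAL_MOL, SEAWATER_DENSITY, mol_co2_to_ppm

BORON_TO_SAL = 0.0004157 / 35.0      # total boron (mol/kg) per psu


def carbonate_constants(temp_c, sal):
    """(K0, K1, K2, KB, KW, BT) at temperature (deg C) and salinity (psu).

    K0 in mol kg-1 atm-1; dissociation constants on the total pH scale.
    """
    t = np.asarray(temp_c, dtype=float) + 273.15
    s = np.asarray(sal, dtype=float)
    tk100 = t / 100.0

    ln_k0 = (-60.2409 + 93.4517 / tk100 + 23.3585 * np.log(tk100)
             + s * (0.023517 - 0.023656 * tk100 + 0.0047036 * tk100**2))
    k0 = np.exp(ln_k0)

    pk1 = (3633.86 / t - 61.2172 + 9.6777 * np.log(t)
           - 0.011555 * s + 0.0001152 * s**2)
    pk2 = (471.78 / t + 25.929 - 3.16967 * np.log(t)
           - 0.01781 * s + 0.0001122 * s**2)
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)

    sqs = np.sqrt(s)
    ln_kb = ((-8966.90 - 2890.53 * sqs - 77.942 * s + 1.728 * s * sqs
              - 0.0996 * s**2) / t
             + 148.0248 + 137.1942 * sqs + 1.62142 * s
             + (-24.4344 - 25.085 * sqs - 0.2474 * s) * np.log(t)
             + 0.053105 * sqs * t)
    kb = np.exp(ln_kb)

    ln_kw = (148.9652 - 13847.26 / t - 23.6521 * np.log(t)
             + (118.67 / t - 5.977 + 1.0495 * np.log(t)) * sqs - 0.01615 * s)
    kw = np.exp(ln_kw)

    bt = BORON_TO_SAL * s
    return k0, k1, k2, kb, kw, bt


def solve_carbonate(dic, alk, temp_c, sal, ph_init=None,
                    n_iter: int = 50, tol: float = 1e-10, constants=None):
    """Solve the carbonate system; returns (pCO2 in uatm, pH).

    ``dic`` in mmol C m-3 and ``alk`` in meq m-3 are converted to mol/kg
    with a fixed reference density.  pCO2 increases with DIC at fixed ALK
    and decreases with ALK at fixed DIC.  ``constants`` may carry a
    precomputed :func:`carbonate_constants` tuple.
    """
    dic_kg = np.asarray(dic, dtype=float) / 1e3 / SEAWATER_DENSITY
    alk_kg = np.asarray(alk, dtype=float) / 1e3 / SEAWATER_DENSITY
    k0, k1, k2, kb, kw, bt = (constants if constants is not None
                              else carbonate_constants(temp_c, sal))

    ph = np.full_like(dic_kg, 8.0) if ph_init is None else np.asarray(
        ph_init, dtype=float).copy()
    h = 10.0 ** (-ph)

    for _ in range(n_iter):
        denom = h * h + k1 * h + k1 * k2
        ca = dic_kg * (k1 * h + 2.0 * k1 * k2) / denom
        borate = bt * kb / (kb + h)
        f = ca + borate + kw / h - h - alk_kg
        # df/dh
        dca = dic_kg * k1 * (
            (denom - (h + 2.0 * k2) * (2.0 * h + k1))) / denom**2
        dborate = -bt * kb / (kb + h) ** 2
        df = dca + dborate - kw / h**2 - 1.0
        step = f / df
        h_new = h - step
        h_new = np.where(h_new <= 0, h * 0.5, h_new)
        converged = np.all(np.abs(h_new - h) <= tol * h)
        h = h_new
        if converged:
            break

    denom = h * h + k1 * h + k1 * k2
    co2_star = dic_kg * h * h / denom
    pco2 = co2_star / k0 * 1e6
    return pco2, -np.log10(h)


def co2_solubility(temp_c, sal):
    """K0 in mol m-3 atm-1 (volumetric)."""
    k0 = carbonate_constants(temp_c, sal)[0]
    return k0 * SEAWATER_DENSITY


def o2_saturation(temp_c, sal):
    """O2 saturation concentration (mmol m-3), Garcia-Gordon fit."""
    t = np.asarray(temp_c, dtype=float)
    s = np.asarray(sal, dtype=float)
    ts = np.log((298.15 - t) / (273.15 + t))
    a = (5.80871 + 3.20291 * ts + 4.17887 * ts**2 + 5.10006 * ts**3
         - 0.0986643 * ts**4 + 3.80369 * ts**5)
    b = s * (-0.00701577 - 0.00770028 * ts - 0.0113864 * ts**2
             - 0.00951519 * ts**3)
    c = -2.75915e-7 * s**2
    umol_kg = np.exp(a + b + c)
    return umol_kg * SEAWATER_DENSITY / 1e3


@dataclass
class AtmosphereBox:
    """Single well-mixed atmospheric CO2 reservoir."""

    pco2: float = 280.0                   # ppm
    mode: str = "fixed"                   # 'fixed' or 'free'
    total_moles_air: float = ATM_TOTAL_MOL

    def __post_init__(self):
        if self.mode not in ("fixed", "free"):
            raise ValueError(f"unknown atmosphere mode {self.mode!r}")
        if self.pco2 <= 0:
            raise ValueError("pCO2 must be positive")

    @property
    def co2_moles(self) -> float:
        return self.pco2 * 1e-6 * self.total_moles_air

    def updated(self, net_ocean_uptake_mol: float) -> "AtmosphereBox":
        """Atmosphere after the ocean takes up ``net_ocean_uptake_mol`` CO2."""
        if self.mode == "fixed":
            return self
        dppm = -mol_co2_to_ppm(net_ocean_uptake_mol)
        return AtmosphereBox(pco2=self.pco2 + dppm, mode=self.mode,
                             total_moles_air=self.total_moles_air)


def air_sea_co2_flux(pco2_ocean, pco2_atm, temp_c, sal, area, ico,
                     piston_velocity_m_per_day: float = 3.0, k0_vol=None):
    """CO2 flux into the ocean (mol yr-1 per box).

    flux = kw * K0 * (pCO2_atm - pCO2_ocean) * area * (1 - ico); positive
    into the ocean when the atmosphere is supersaturated relative to it,
    zero under full ice cover.
    """
    kw = piston_velocity_m_per_day * 365.0      # m yr-1
    if k0_vol is None:
        k0_vol = co2_solubility(temp_c, sal)    # mol m-3 atm-1
    dp = (np.asarray(pco2_atm, dtype=float)
          - np.asarray(pco2_ocean, dtype=float)) * 1e-6
    return kw * k0_vol * dp * np.asarray(area, dtype=float) * (
        1.0 - np.asarray(ico, dtype=float))


def respired_carbon_pg(o2, temp_c, sal, volume, c_to_o2: float = 106.0 / 138.0,
                       mask=None) -> float:
    """AOU-based respired (regenerated) carbon inventory in Pg C.

    AOU = O2_sat(T, S) - O2, converted to carbon with the remineralisation
    C:O2 ratio of the exported mix.
    """
    o2 = np.asarray(o2, dtype=float)
    aou = o2_saturation(temp_c, sal) - o2
    contrib = aou * np.asarray(volume, dtype=float) * c_to_o2    # mmol C
    if mask is not None:
        contrib = contrib[np.asarray(mask)]
    mol = contrib.sum() / 1e3
    from .units import mol_to_pg_c
    return float(mol_to_pg_c(mol))
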