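"""Unit conventions and conversion constants.

Internal conventions used everywhere in the package:

* concentrations        mmol m-3  (iron in umol m-3)
* volumes               m3
* time                  years
* transports            m3 yr-1 (built from Sverdrups)
* global fluxes         mol yr-1 unless a diagnostic name says otherwise
* nitrogen diagnostics  Tg N yr-1
* carbon diagnostics    Pg C
"""

SEC_PER_YEAR = 3.1536e7          # 365-day year
DAYS_PER_YEAR = 365.0
SV_TO_M3_PER_YEAR = 1.0e6 * SEC_PER_YEAR

MOLAR_MASS_C = 12.011            # g mol-1
MOLAR_MASS_N = 14.007            # g mol-1

# 1 Tg N expressed in mol N
MOL_PER_TG_N = 1.0e12 / MOLAR_MASS_N

# atmosphere: fixed dry mass and mean molecular weight of air
ATM_MASS_G = 5.1e21              # g
ATM_MOL_WEIGHT = 28.97           # g mol-1
ATM_TOTAL_MOL = ATM_MASS_G / ATM_MOL_WEIGHT   # ~1.76044e20 mol air

SEAWATER_DENSITY = 1025.0        # kg m-3, fixed reference density


def mol_to_pg_c(mol: float) -> float:
    """mol C -> Pg C."""
    return mol * MOLAR_MASS_C * 1e-15


def mol_to_tg_n(mol: float) -> float:
    """mol N -> Tg N."""
    return mol * MOLAR_MASS_N * 1e-12


def tg_n_to_mol(tg: float) -> float:
    return tg * MOL_PER_TG_N


def mol_co2_to_ppm(mol: float) -> float:
    """mol CO2 in the atmosphere -> ppm (mole fraction * 1e6)."""
    return mol / ATM_TOTAL_MOL * 1e6


def ppm_to_mol_co2(ppm: float) -> float:
    return ppm * ATM_TOTAL_MOL * 1e-6
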