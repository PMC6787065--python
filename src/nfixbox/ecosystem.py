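"""Export production of the three producer groups.

Diazotrophs (N2 fixers) follow the static parameterisation

    P_exp_D = S_EP * mu_D(T) * max(0.01, min(PO4_lim, NO3_lim, Fe_lim)) * (1 - ico)

with a temperature-dependent maximum growth rate

    mu_D(T) = max(0.01, -0.0042 T^2 + 0.2253 T - 2.7819)

and limitation terms

    PO4_lim = PO4 / (PO4 + K_PO4)     (K_PO4 = 1e-10: superior P affinity)
    NO3_lim = exp(-NO3)               (the low-NO3:PO4 niche)
    Fe_lim  = max(0, tanh(2 Fe - K_Fe))

The general phytoplankton group uses Michaelis-Menten limitation in NO3,
PO4 and Fe with a phosphate-dependent C:P ratio (frugality under P
scarcity).  Calcifiers produce particulate inorganic carbon at 8% of the
general group's organic carbon production.  No light limitation anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import DiazotrophParams, GeneralPhytoParams, paulmier_closure


@dataclass
class SurfaceEnvironment:
    """Environment of one (or a vector of) surface box(es)."""

    temperature: np.ndarray | float       # deg C
    po4: np.ndarray | float               # mmol P m-3
    no3: np.ndarray | float               # mmol N m-3
    fe: np.ndarray | float                # umol Fe m-3
    ico: np.ndarray | float = 0.0         # ice fraction, 0..1


@dataclass
class ExportFluxes:
    """Export production (mmol P m-3 day-1) and derived carbon terms."""

    p_exp_general: np.ndarray
    p_exp_diazotroph: np.ndarray
    c_to_p_general: np.ndarray
    pic_production: np.ndarray            # mmol C m-3 day-1


def diazotroph_growth_rate(temperature):
    """mu_D(T): floored quadratic in temperature (day-1 scale factor)."""
    t = np.asarray(temperature, dtype=float)
    quad = -0.0042 * t**2 + 0.2253 * t - 2.7819
    return np.maximum(0.01, quad)


def diazotroph_limitations(env: SurfaceEnvironment, params: DiazotrophParams):
    """(PO4_lim, NO3_lim, Fe_lim), each in [0, 1] for non-negative inputs."""
    po4 = np.asarray(env.po4, dtype=float)
    no3 = np.asarray(env.no3, dtype=float)
    fe = np.asarray(env.fe, dtype=float)
    po4_lim = po4 / (po4 + params.k_po4)
    no3_lim = np.exp(-no3)
    fe_lim = np.maximum(0.0, np.tanh(2.0 * fe - params.k_fe))
    return po4_lim, no3_lim, fe_lim


def diazotroph_export(env: SurfaceEnvironment, params: DiazotrophParams):
    """Diazotroph P export (mmol P m-3 day-1)."""
    mu = diazotroph_growth_rate(env.temperature)
    po4_lim, no3_lim, fe_lim = diazotroph_limitations(env, params)
    limitation = np.maximum(0.01, np.minimum(np.minimum(po4_lim, no3_lim),
                                             fe_lim))
    ico = np.asarray(env.ico, dtype=float)
    return params.s_etop * mu * limitation * (1.0 - ico)


def general_export(env: SurfaceEnvironment, params: GeneralPhytoParams):
    """General-group P export and its dynamic C:P ratio.

    Returns ``(p_exp, c_to_p)``; export is the minimum of Michaelis-Menten
    terms in NO3, PO4 and Fe (half-saturations 0.75, 0.1, 0.1; the iron
    constant is one third of the diazotrophs'), scaled by the export rate
    constant.  C:P falls as PO4 rises (frugality under scarcity).
    """
    po4 = np.asarray(env.po4, dtype=float)
    no3 = np.asarray(env.no3, dtype=float)
    fe = np.asarray(env.fe, dtype=float)
    no3_lim = no3 / (no3 + params.k_no3)
    po4_lim = po4 / (po4 + params.k_po4)
    fe_lim = fe / (fe + params.k_fe)
    limitation = np.minimum(np.minimum(no3_lim, po4_lim), fe_lim)
    ico = np.asarray(env.ico, dtype=float)
    p_exp = params.s_etop * limitation * (1.0 - ico)
    return p_exp, params.c_to_p(po4)


def general_remin_demands(c_to_p, n_to_p: float = 16.0):
    """O2 and NO3 remineralisation demands for general organic matter."""
    return paulmier_closure(np.asarray(c_to_p, dtype=float), n_to_p)


def calcifier_production(p_exp_general, c_to_p_general,
                         pic_fraction: float = 0.08):
    """PIC production at ``pic_fraction`` of general organic C production."""
    return pic_fraction * np.asarray(p_exp_general) * np.asarray(c_to_p_general)


def compute_exports(env: SurfaceEnvironment, dz_params: DiazotrophParams,
                    g_params: GeneralPhytoParams,
                    pic_fraction: float = 0.08) -> ExportFluxes:
    p_g, ctop = general_export(env, g_params)
    p_d = diazotroph_export(env, dz_params)
    pic = calcifier_production(p_g, ctop, pic_fraction)
    return ExportFluxes(p_exp_general=p_g, p_exp_diazotroph=p_d,
                        c_to_p_general=ctop, pic_production=pic)
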