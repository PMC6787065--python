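"""Time-stepping engine composing transport, biology, redox, iron, carbon
and isotope tendencies.

Explicit Euler with a default coupling step of 0.1 yr; pure relaxation
terms (iron nudging, surface O2 and ideal-age restoring) use their exact
exponential update and are unconditionally stable.  A process may consume
at most the pool available in a step: demand beyond availability is
rescaled proportionally, and organic matter that cannot be remineralised
in a box is passed to the next deeper box, closing every budget exactly.

Tendencies are tagged by process; their sum equals the applied state
change exactly, which is the conservation contract the tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import remin as rx
from .carbonate import (AtmosphereBox, air_sea_co2_flux, o2_saturation,
                        solve_carbonate)
from .circulation import Circulation, make_circulation
from .ecosystem import (SurfaceEnvironment, diazotroph_export,
                        diazotroph_growth_rate, general_export)
from .forcing import (Climatology, FeDepositionField, NDepositionField,
                      make_climatology, make_fe_deposition, make_n_deposition)
from .geometry import BoxGeometry, make_geometry
from .iron import deposition_tendency
from .isotopes import atom_fraction, fractionating_flux
from .params import DiazotrophParams, ModelParams, paulmier_closure
from .state import CONCENTRATION_TRACERS, TRACERS, TracerState

PROCESSES = ("transport", "general_bio", "diazotroph", "calcifier",
             "remin_O2", "wc_denit", "sed_denit", "sulfate", "fe_relax",
             "deposition", "gas_exchange")

DIAZOTROPH_MODES = ("default", "off", "CtoP_0", "CtoP_165", "KPO4_0.1")

_FE_UMOL_PER_MMOL_P = 1e3     # Fe:P (mol/mol) -> umol Fe per mmol P
_TINY = 1e-300
_EPS = 1e-30


def _frac_flux(pool, pool15, flux, eps, r_std):
    """Fast linear open-system fractionation (same rule as
    :func:`nfixbox.isotopes.fractionating_flux`, avoiding the per-mil
    round trip): r_removed = r_pool - r_std * eps * (1 - f) / 1000."""
    f = flux / (pool + _EPS)
    r_pool = pool15 / (pool - pool15 + _EPS)
    r_rem = r_pool - r_std * eps * (1.0 - f) * 1e-3
    x_rem = r_rem / (1.0 + r_rem)
    flux15 = flux * x_rem
    lower = np.maximum(0.0, pool15 - (pool - flux))
    upper = np.minimum(pool15, flux)
    return np.maximum(lower, np.minimum(flux15, upper))


@dataclass
class StepTendency:
    """Per-process, per-tracer state change (state units) for one step."""

    deltas: dict = field(default_factory=dict)

    def add(self, process: str, tracer: str, delta: np.ndarray) -> None:
        self.deltas.setdefault(process, {})[tracer] = delta

    def total(self, tracer: str, n_box: int) -> np.ndarray:
        out = np.zeros(n_box)
        for proc in self.deltas.values():
            if tracer in proc:
                out = out + proc[tracer]
        return out


def _dz_params_for_mode(base: DiazotrophParams, mode: str,
                        k_fe_override: float | None) -> DiazotrophParams:
    if mode == "CtoP_0":
        p = DiazotrophParams.with_stoichiometry(
            0.0, base.n_to_p, fe_to_p=base.fe_to_p, k_fe=base.k_fe,
            k_po4=base.k_po4, s_etop=base.s_etop)
    elif mode == "CtoP_165":
        p = DiazotrophParams.with_stoichiometry(
            165.0, base.n_to_p, fe_to_p=base.fe_to_p, k_fe=base.k_fe,
            k_po4=base.k_po4, s_etop=base.s_etop)
    elif mode == "KPO4_0.1":
        p = replace(base, k_po4=0.1)
    else:
        p = base
    if k_fe_override is not None:
        p = replace(p, k_fe=k_fe_override)
    return p


class Model:
    """One configured box-model experiment.

    Composes the synthetic physical state (geometry, circulation,
    climatology), the deposition forcings and the biogeochemical process
    parameters, and advances a :class:`TracerState` in time.
    """

    def __init__(self, geometry: BoxGeometry | None = None,
                 state_name: str = "mild",
                 circulation: Circulation | None = None,
                 climatology: Climatology | None = None,
                 fe_pattern: str = "modern", fe_scale: float = 100.0,
                 fe_field: FeDepositionField | None = None,
                 n_deposition: NDepositionField | None = None,
                 params: ModelParams | None = None,
                 diazotroph_mode: str = "default",
                 k_fe_override: float | None = None,
                 atmosphere: AtmosphereBox | None = None,
                 dt: float = 0.1):
        if diazotroph_mode not in DIAZOTROPH_MODES:
            raise ValueError(f"unknown diazotroph_mode {diazotroph_mode!r}")
        self.geometry = geometry if geometry is not None else make_geometry()
        self.state_name = state_name
        self.circulation = circulation or make_circulation(state_name)
        self.climatology = climatology or make_climatology(self.geometry,
                                                           state_name)
        self.fe_field = fe_field or make_fe_deposition(self.geometry,
                                                       fe_pattern, fe_scale)
        self.n_deposition = n_deposition or make_n_deposition(self.geometry)
        self.params = params or ModelParams()
        self.diazotroph_mode = diazotroph_mode
        self.dz_params = _dz_params_for_mode(self.params.diazotroph,
                                             diazotroph_mode, k_fe_override)
        # 'off' removes the fixers AND the active N cycle: denitrification
        # and external N deposition are disabled so the NO3 inventory is a
        # closed, internally recycled pool
        self.n_cycle_active = diazotroph_mode != "off"
        self.atmosphere = atmosphere or AtmosphereBox(pco2=280.0, mode="fixed")
        self.dt = dt
        self.bio_substep_yr = 0.05    # surface-production sub-step (~18 d)
        self.clip_log: list = []

        g = self.geometry
        self._matrix = self.circulation.transport_matrix(g)
        self._vol = g.volume
        self._surf = g.surface_indices
        self._thickness = g.volume[self._surf] / g.area[self._surf]
        self._ph = np.full(len(self._surf), 8.05)
        self._fe_dep = deposition_tendency(self.fe_field, g)

        # column structures for the sinking-flux cascade, padded to the
        # deepest column; padded levels carry no flux by construction
        cols = [g.columns[i] for i in self._surf]
        self._ncol = len(cols)
        self._nlev = max(len(c) for c in cols)
        self._col_box = np.full((self._ncol, self._nlev), g.n_box - 1, int)
        self._col_zt = np.ones((self._ncol, self._nlev))
        self._col_zb = np.ones((self._ncol, self._nlev))
        self._col_fsc = np.zeros((self._ncol, self._nlev))
        for i, path in enumerate(cols):
            for l, (b, zt, zb) in enumerate(path):
                self._col_box[i, l] = b
                self._col_zt[i, l] = zt
                self._col_zb[i, l] = zb
                self._col_fsc[i, l] = g.sediment_contact_fraction[b]
        # PIC pass-through fraction per level (e-folding dissolution)
        efold = self.params.redox.pic_efold_m
        self._pic_pass = np.exp(-(self._col_zb - self._col_zt) / efold)
        self._pic_pass[:, -1] = 0.0          # remainder dissolves at the bottom

        # monthly forcing cache: everything that depends only on the month
        from .carbonate import carbonate_constants
        clim = self.climatology
        kw_yr = self.params.gas.piston_velocity_m_per_day * 365.0
        self._months = []
        for mo in range(12):
            t_mo = clim.temp_monthly[mo]
            ico_mo = clim.ico_monthly[mo]
            ndep = self.n_deposition.flux_monthly[mo]
            self._months.append({
                "temp": t_mo,
                "ico": ico_mo,
                "mu_d": diazotroph_growth_rate(t_mo[self._surf]),
                "o2_sat": o2_saturation(t_mo[self._surf], clim.salinity),
                "gas_rate": kw_yr * (1.0 - ico_mo[self._surf]) / self._thickness,
                "carb": carbonate_constants(t_mo[self._surf], clim.salinity),
                "k0_vol": carbonate_constants(
                    t_mo[self._surf], clim.salinity)[0] * 1025.0,
                "ndep_conc_yr": ndep * g.area[self._surf] * 1e3
                / g.volume[self._surf],
                "ndep_mol_yr": float((ndep * g.area[self._surf]).sum()),
            })

    # ------------------------------------------------------------------
    def initial_state(self, warm_start: bool = True, **kwargs) -> TracerState:
        if warm_start:
            return TracerState.warm_start(self.geometry,
                                          state_name=self.state_name,
                                          **kwargs)
        return TracerState.initial(self.geometry.n_box, **kwargs)

    def month_of(self, t: float) -> int:
        return int((t % 1.0) * 12.0) % 12

    # ------------------------------------------------------------------
    def step(self, state: TracerState, t: float,
             dt: float | None = None) -> tuple[TracerState, StepTendency, dict]:
        """Advance one coupling step; returns (state, tendencies, diagnostics)."""
        dt = self.dt if dt is None else dt
        if dt <= 0:
            raise ValueError("dt must be positive")
        g = self.geometry
        n = g.n_box
        vol = self._vol
        surf = self._surf
        month = self.month_of(t)
        clim = self.climatology
        mo = self._months[month]
        temp = mo["temp"]
        ico = mo["ico"]
        sal = clim.salinity
        iso = self.params.isotopes
        tend = StepTendency()
        diag: dict = {}

        # ---- transport (+ ideal-age source and surface reset) ----------
        x = np.stack([getattr(state, name) for name in TRACERS], axis=1)
        dx = (self._matrix @ x) * dt
        for k, name in enumerate(TRACERS):
            tend.add("transport", name, dx[:, k])
        d_age = dx[:, TRACERS.index("age")] + dt
        d_age[surf] = -state.age[surf]       # surface water is age zero
        tend.deltas["transport"]["age"] = d_age

        # working pools for availability capping (concentration units)
        avail_no3 = state.no3.copy()
        avail_no3_15 = state.no3_15.copy()
        avail_o2 = state.o2.copy()

        # ---- surface production ---------------------------------------
        # Surface nutrient pools are small relative to one coupling step of
        # uptake, so production is sub-stepped: limitation terms then act
        # on smoothly declining concentrations instead of a once-per-step
        # sawtooth, which matters most for the e^-NO3 niche term.
        dzp = self.dz_params
        gp = self.params.general
        nsub = max(1, int(round(dt / self.bio_substep_yr)))
        dts = dt / nsub
        po4_w = state.po4[surf].copy()
        no3_w = state.no3[surf].copy()
        no3_15_w = state.no3_15[surf].copy()
        fe_w = state.fe[surf].copy()
        nsurf = len(surf)
        up_g = np.zeros(nsurf)
        up_d = np.zeros(nsurf)
        assim15 = np.zeros(nsurf)
        c_exp_g = np.zeros(nsurf)       # accumulated C export (C:P varies)
        clipped = False

        # inlined export laws (see ecosystem.general_export /
        # diazotroph_export; parity is covered by the engine tests)
        one_minus_ico = 1.0 - ico[surf]
        mu_d = mo["mu_d"]
        rate_g = gp.s_etop * 365.0 * dts * one_minus_ico
        rate_d = dzp.s_etop * 365.0 * dts * mu_d * one_minus_ico
        fe2p_g = gp.fe_to_p * _FE_UMOL_PER_MMOL_P
        fe2p_d = dzp.fe_to_p * _FE_UMOL_PER_MMOL_P
        for _ in range(nsub):
            # work on clamped pools: round-off can leave tiny negative
            # residuals whose sign would otherwise corrupt the ratios
            po4_p = np.maximum(po4_w, 0.0)
            no3_p = np.maximum(no3_w, 0.0)
            fe_p = np.maximum(fe_w, 0.0)
            fe_lim_g = fe_p / (fe_p + gp.k_fe)
            lim_g = np.minimum(np.minimum(no3_p / (no3_p + gp.k_no3),
                                          po4_p / (po4_p + gp.k_po4)),
                               fe_lim_g)
            dug = rate_g * lim_g
            ctop_k = np.maximum(gp.ctop_min,
                                np.minimum(1.0 / (gp.ctop_a * po4_p
                                                  + gp.ctop_b), gp.ctop_max))
            if self.n_cycle_active:
                fe_lim_d = np.maximum(0.0, np.tanh(2.0 * fe_p - dzp.k_fe))
                lim_d = np.minimum(np.minimum(po4_p / (po4_p + dzp.k_po4),
                                              np.exp(-no3_p)), fe_lim_d)
                dud = rate_d * np.maximum(0.01, lim_d)
            else:
                dud = np.zeros(nsurf)
            r_po4 = np.minimum(1.0, po4_p / (dug + dud + _EPS))
            r_no3 = np.minimum(1.0, no3_p / (gp.n_to_p * dug + _EPS))
            fe_dem = fe2p_g * dug + fe2p_d * dud
            r_fe = np.minimum(1.0, fe_p / (fe_dem + _EPS))
            sg = np.minimum(np.minimum(r_po4, r_no3), r_fe)
            sd = np.minimum(r_po4, r_fe)
            if sg.min() < 1.0 or sd.min() < 1.0:
                clipped = True
            dug = dug * sg
            dud = dud * sd
            da = gp.n_to_p * dug
            da15 = _frac_flux(no3_p, np.maximum(no3_15_w, 0.0), da,
                              iso.eps_assimilation, iso.r_std)
            po4_w = po4_w - dug - dud
            no3_w = no3_w - da
            no3_15_w = no3_15_w - da15
            fe_w = fe_w - fe2p_g * dug - fe2p_d * dud
            up_g += dug
            up_d += dud
            assim15 += da15
            c_exp_g += ctop_k * dug
        if clipped:
            self.clip_log.append((t, "surface_uptake"))
        # step-mean C:P of the general export (per box)
        ctop_g = c_exp_g / np.maximum(up_g, _EPS)
        ctop_g = np.where(up_g > 0, ctop_g, gp.c_to_p(state.po4[surf]))

        o_rem_g, n_rem_g = paulmier_closure(ctop_g, gp.n_to_p)

        assim = gp.n_to_p * up_g
        avail_no3[surf] -= assim
        avail_no3_15[surf] -= assim15

        d = {k: np.zeros(n) for k in ("po4", "no3", "no3_15", "fe", "dic",
                                      "alk", "o2")}
        d["po4"][surf] = -up_g
        d["no3"][surf] = -assim
        d["no3_15"][surf] = -assim15
        d["fe"][surf] = -gp.fe_to_p * up_g * _FE_UMOL_PER_MMOL_P
        d["dic"][surf] = -ctop_g * up_g
        d["alk"][surf] = assim
        d["o2"][surf] = o_rem_g * up_g
        for k, v in d.items():
            tend.add("general_bio", k, v)

        d = {k: np.zeros(n) for k in ("po4", "fe", "dic", "o2")}
        d["po4"][surf] = -up_d
        d["fe"][surf] = -dzp.fe_to_p * up_d * _FE_UMOL_PER_MMOL_P
        d["dic"][surf] = -dzp.c_to_p * up_d
        d["o2"][surf] = dzp.o_rem_to_p * up_d
        for k, v in d.items():
            tend.add("diazotroph", k, v)

        pic = self.params.pic_fraction * ctop_g * up_g     # mmol C m-3
        d_dic = np.zeros(n)
        d_alk = np.zeros(n)
        d_dic[surf] = -pic
        d_alk[surf] = -2.0 * pic

        # ---- sinking organic matter: column cascade --------------------
        vs = vol[surf]
        fixed_n = dzp.n_to_p * up_d * vs
        fixed_15 = fixed_n * atom_fraction(iso.delta_fixation, iso.r_std)
        flux = np.stack([
            (up_g + up_d) * vs,                              # P
            (ctop_g * up_g + dzp.c_to_p * up_d) * vs,        # C
            (gp.n_to_p * up_g + dzp.n_to_p * up_d) * vs,     # N
            assim15 * vs + fixed_15,                         # 15N
            (gp.fe_to_p * up_g + dzp.fe_to_p * up_d)
            * _FE_UMOL_PER_MMOL_P * vs,                      # Fe (umol m3)
        ], axis=1)
        diag["fixation_mol_yr"] = float(fixed_n.sum()) / 1e3 / dt
        diag["c_export_mol_yr"] = float(flux[:, 1].sum()) / 1e3 / dt
        diag["p_export_general"] = up_g / dt
        diag["p_export_diazotroph"] = up_d / dt
        diag["assimilated_n"] = assim * vs
        diag["assimilated_15n"] = assim15 * vs
        diag["fixed_n"] = fixed_n

        rem = self._remineralise(flux, pic * vs, state, avail_no3,
                                 avail_no3_15, avail_o2, tend, d_dic, d_alk,
                                 dt, t)
        diag.update(rem)

        # ---- calcifiers (production + dissolution assembled above) -----
        tend.add("calcifier", "dic", d_dic)
        tend.add("calcifier", "alk", d_alk)

        # ---- external nitrogen deposition ------------------------------
        if self.n_cycle_active:
            amt = mo["ndep_conc_yr"] * dt                    # mmol m-3
            d_no3 = np.zeros(n)
            d_n15 = np.zeros(n)
            d_alk_dep = np.zeros(n)
            d_no3[surf] = amt
            d_n15[surf] = amt * atom_fraction(iso.delta_deposition, iso.r_std)
            d_alk_dep[surf] = -amt
            tend.add("deposition", "no3", d_no3)
            tend.add("deposition", "no3_15", d_n15)
            tend.add("deposition", "alk", d_alk_dep)
            diag["n_dep_mol_yr"] = mo["ndep_mol_yr"]
        else:
            diag["n_dep_mol_yr"] = 0.0

        # ---- iron deposition and deep relaxation -----------------------
        d_fe = self._fe_dep * dt
        tend.add("deposition", "fe", d_fe)
        fep = self.params.iron
        decay = np.exp(-dt / fep.relax_timescale_yr)
        relax = np.where(self.geometry.fe_relax_mask,
                         (fep.relax_target - state.fe) * (1.0 - decay), 0.0)
        tend.add("fe_relax", "fe", relax)
        diag["fe_dep_mol_yr"] = self.fe_field.global_integral(g)
        diag["fe_relax_mol_yr"] = float((relax * vol).sum()) / 1e6 / dt

        # ---- gas exchange ----------------------------------------------
        sat = mo["o2_sat"]
        d_o2 = np.zeros(n)
        d_o2[surf] = (sat - state.o2[surf]) * (1.0 - np.exp(-dt * mo["gas_rate"]))
        tend.add("gas_exchange", "o2", d_o2)

        pco2_oc, self._ph = solve_carbonate(state.dic[surf], state.alk[surf],
                                            temp[surf], sal, self._ph,
                                            constants=mo["carb"])
        co2_flux = air_sea_co2_flux(
            pco2_oc, self.atmosphere.pco2, temp[surf], sal, g.area[surf],
            ico[surf], self.params.gas.piston_velocity_m_per_day,
            k0_vol=mo["k0_vol"])  # mol/yr
        d_dic_gas = np.zeros(n)
        d_dic_gas[surf] = co2_flux * dt * 1e3 / vol[surf]
        tend.add("gas_exchange", "dic", d_dic_gas)
        uptake_mol = float(co2_flux.sum()) * dt
        self.atmosphere = self.atmosphere.updated(uptake_mol)
        diag["pco2_ocean"] = pco2_oc
        diag["pco2_atm"] = self.atmosphere.pco2
        diag["co2_flux_mol_yr"] = uptake_mol / dt

        # ---- apply ------------------------------------------------------
        new = {}
        for name in TRACERS:
            new[name] = getattr(state, name) + tend.total(name, n)
        for name in CONCENTRATION_TRACERS:
            arr = new[name]
            neg = arr < 0
            if np.any(neg):
                worst = float(arr[neg].min())
                if worst < -1e-6:
                    self.clip_log.append((t, name, worst))
                arr[neg] = 0.0
        new["no3_15"] = np.minimum(new["no3_15"], new["no3"])
        new_state = TracerState(**new)

        bad = [name for name in TRACERS
               if not np.all(np.isfinite(new[name]))]
        if bad:
            for proc, trac in tend.deltas.items():
                for name, arr in trac.items():
                    if not np.all(np.isfinite(arr)):
                        raise FloatingPointError(
                            f"non-finite tendency from process {proc!r} "
                            f"on tracer {name!r} at t={t:.3f}")
            raise FloatingPointError(
                f"non-finite state in tracers {bad} at t={t:.3f}")
        return new_state, tend, diag

    # ------------------------------------------------------------------
    def _remineralise(self, flux: np.ndarray, pic_flux: np.ndarray,
                      state: TracerState, avail_no3, avail_no3_15, avail_o2,
                      tend: StepTendency, d_dic_calc, d_alk_calc,
                      dt: float, t: float) -> dict:
        """Route sinking organic matter and PIC down the columns.

        ``flux`` is (n_col, 5): P, C, N, 15N, Fe amounts (mmol / umol).
        Mutates the availability pools and writes remin tendencies; returns
        flux diagnostics.
        """
        g = self.geometry
        n = g.n_box
        vol = self._vol
        rp = self.params.redox
        iso = self.params.isotopes

        d_aer = {k: np.zeros(n) for k in ("po4", "dic", "o2", "no3",
                                          "no3_15", "alk", "fe")}
        d_wcd = {k: np.zeros(n) for k in ("po4", "dic", "no3", "no3_15",
                                          "alk", "fe")}
        d_sdd = {k: np.zeros(n) for k in ("po4", "dic", "no3", "no3_15",
                                          "alk", "fe")}
        d_sul = {k: np.zeros(n) for k in ("po4", "dic", "no3", "no3_15",
                                          "alk", "fe")}
        wc_denit_n = 0.0
        sed_denit_n = 0.0
        denit_org_n = 0.0
        sulfate_p = 0.0
        aerobic_p = 0.0

        # per-level release terms are collected and scattered once at the
        # end; only the consumption terms (NO3, O2) must update inside the
        # loop because they feed the availability caps of deeper levels
        rel_aer: list = []
        aer_boxes: list = []
        rel_wcd: list = []
        rel_sdd: list = []
        rel_sul: list = []
        cons_wcd: list = []
        cons_sdd: list = []

        def _box_scale(box, need, pool_conc, frac=1.0):
            """Per-column scale factors capping total demand per box."""
            box_need = np.bincount(box, need, minlength=n)
            pool = np.maximum(pool_conc, 0.0) * vol * frac
            s = np.minimum(1.0, pool / (box_need + 1e-6))
            return s[box]

        pic = pic_flux.copy()
        f = flux.copy()
        for lev in range(self._nlev):
            box = self._col_box[:, lev]
            fsc = self._col_fsc[:, lev]
            sed = fsc[:, None] * f
            fw = f - sed

            # attenuation exponent relaxes toward the suboxic value as O2
            # falls through the suboxia threshold (smooth in O2, so the
            # deep-transfer response to deoxygenation is continuous)
            s_ox = 0.5 + 0.5 * np.tanh(
                (avail_o2[box] - rp.suboxia_threshold) / rp.martin_ramp_width)
            b = rp.martin_b_suboxic + (rp.martin_b_oxic
                                       - rp.martin_b_suboxic) * s_ox
            att = (self._col_zb[:, lev] / self._col_zt[:, lev]) ** (-b)
            r = fw * (1.0 - att)[:, None]
            f_next = fw * att[:, None]

            # --- water-column split: denitrification then aerobic -------
            if self.n_cycle_active:
                fden = rx.effective_wc_denit_fraction(avail_o2[box],
                                                      avail_no3[box], rp)
                no3_need = fden * (0.8 * r[:, 1] + 0.6 * r[:, 2])
                fden = fden * _box_scale(box, no3_need, avail_no3)
                no3_cons = fden * (0.8 * r[:, 1] + 0.6 * r[:, 2])
                dpart = fden[:, None] * r
            else:
                no3_cons = np.zeros(self._ncol)
                dpart = np.zeros_like(r)

            apart = r - dpart
            o2_need = apart[:, 1] + 2.0 * apart[:, 2]
            s_o2 = _box_scale(box, o2_need, avail_o2)
            a_act = s_o2[:, None] * apart
            f_next = f_next + (apart - a_act)       # passed deeper

            rel_wcd.append(dpart)
            rel_aer.append(a_act)
            aer_boxes.append(box)
            cons_wcd.append(no3_cons)
            wc_denit_n += float(no3_cons.sum())
            denit_org_n += float(dpart[:, 2].sum())
            aerobic_p += float(a_act[:, 0].sum())

            # isotope effect of water-column denitrification; O2 and NO3
            # pools updated for the deeper levels
            no3_cons_box = np.bincount(box, no3_cons, minlength=n)
            f15 = _frac_flux(avail_no3 * vol, avail_no3_15 * vol,
                             no3_cons_box, iso.eps_wc_denit, iso.r_std)
            d_wcd["no3_15"] -= f15 / vol
            avail_no3 -= no3_cons_box / vol
            avail_no3_15 -= f15 / vol
            o2_cons_box = np.bincount(box, a_act[:, 1] + 2.0 * a_act[:, 2],
                                      minlength=n) / vol
            d_aer["o2"] -= o2_cons_box
            avail_o2 = avail_o2 - o2_cons_box

            # --- sediment pathway ----------------------------------------
            if sed[:, 0].max() > 0:
                o2b = avail_o2[box]
                no3b = avail_no3[box]
                demand_full = 0.8 * sed[:, 1] + 0.6 * sed[:, 2]
                if self.n_cycle_active:
                    factor = rx.sed_denit_factor(o2b, no3b, rp)
                    frac = factor * sed[:, 1] / (demand_full + _EPS)
                    frac = np.minimum(frac, 1.0)
                    frac = frac * _box_scale(box, frac * demand_full,
                                             avail_no3)
                else:
                    frac = np.zeros(self._ncol)
                sd = frac[:, None] * sed
                no3_cons_sed = frac * demand_full

                remaining = sed - sd
                r_srem = rx.sed_aerobic_scaling(o2b, rp)
                sa = r_srem[:, None] * remaining
                o2_need = sa[:, 1] + 2.0 * sa[:, 2]
                s_o2 = _box_scale(box, o2_need, avail_o2,
                                  frac=rp.sed_o2_fraction)
                sa = s_o2[:, None] * sa
                ssulf = remaining - sa

                rel_sdd.append((box, sd))
                rel_sul.append((box, ssulf))
                rel_aer.append(sa)
                aer_boxes.append(box)
                cons_sdd.append((box, no3_cons_sed))
                sed_denit_n += float(no3_cons_sed.sum())
                denit_org_n += float(sd[:, 2].sum())
                sulfate_p += float(ssulf[:, 0].sum())
                aerobic_p += float(sa[:, 0].sum())

                no3_cons_box = np.bincount(box, no3_cons_sed, minlength=n)
                f15 = _frac_flux(avail_no3 * vol, avail_no3_15 * vol,
                                 no3_cons_box, iso.eps_sed_denit, iso.r_std)
                d_sdd["no3_15"] -= f15 / vol
                avail_no3 -= no3_cons_box / vol
                avail_no3_15 -= f15 / vol
                o2_cons_box = np.bincount(box, sa[:, 1] + 2.0 * sa[:, 2],
                                          minlength=n) / vol
                d_aer["o2"] -= o2_cons_box
                avail_o2 = avail_o2 - o2_cons_box

            # --- PIC dissolution ----------------------------------------
            dis = pic * (1.0 - self._pic_pass[:, lev]) / vol[box]
            d_dic_calc += np.bincount(box, dis, minlength=n)
            d_alk_calc += np.bincount(box, 2.0 * dis, minlength=n)
            pic = pic * self._pic_pass[:, lev]

            f = f_next

        # --- fused scatters of the release terms -------------------------
        def _release(d, box_all, part_all, nitrify):
            w = 1.0 / vol[box_all]
            d["po4"] += np.bincount(box_all, part_all[:, 0] * w, minlength=n)
            d["dic"] += np.bincount(box_all, part_all[:, 1] * w, minlength=n)
            d["fe"] += np.bincount(box_all, part_all[:, 4] * w, minlength=n)
            if nitrify:
                rel_n = np.bincount(box_all, part_all[:, 2] * w, minlength=n)
                d["no3"] += rel_n
                d["alk"] -= rel_n
                d["no3_15"] += np.bincount(box_all, part_all[:, 3] * w,
                                           minlength=n)

        # water-column denitrification releases (organic N leaves as N2)
        lev_boxes = np.concatenate(
            [self._col_box[:, lev] for lev in range(self._nlev)])
        _release(d_wcd, lev_boxes, np.vstack(rel_wcd), nitrify=False)
        cons = np.bincount(lev_boxes, np.concatenate(cons_wcd),
                           minlength=n) / vol
        d_wcd["no3"] -= cons
        d_wcd["alk"] += cons

        # aerobic releases (water column + sediments, in append order)
        _release(d_aer, np.concatenate(aer_boxes), np.vstack(rel_aer),
                 nitrify=True)

        if rel_sdd:
            sdd_boxes = np.concatenate([b for b, _ in rel_sdd])
            _release(d_sdd, sdd_boxes, np.vstack([p for _, p in rel_sdd]),
                     nitrify=False)
            cons = np.bincount(np.concatenate([b for b, _ in cons_sdd]),
                               np.concatenate([c for _, c in cons_sdd]),
                               minlength=n) / vol
            d_sdd["no3"] -= cons
            d_sdd["alk"] += cons
            _release(d_sul, sdd_boxes, np.vstack([p for _, p in rel_sul]),
                     nitrify=True)

        for proc, dd in (("remin_O2", d_aer), ("wc_denit", d_wcd),
                         ("sed_denit", d_sdd), ("sulfate", d_sul)):
            for k, v in dd.items():
                tend.add(proc, k, v)
        return {
            "wc_denit_mol_yr": wc_denit_n / 1e3 / dt,
            "sed_denit_mol_yr": sed_denit_n / 1e3 / dt,
            "denit_org_n_mol_yr": denit_org_n / 1e3 / dt,
            "sulfate_p_mol_yr": sulfate_p / 1e3 / dt,
            "aerobic_p_mol_yr": aerobic_p / 1e3 / dt,
        }

    # ------------------------------------------------------------------
    def integrate(self, state: TracerState, years: float,
                  t0: float = 0.0, record_every: float = 1.0,
                  dt: float | None = None):
        """Advance ``years`` and collect annually averaged diagnostics.

        Returns (state, records): ``records`` is a list of dicts with the
        running time, atmosphere and the mean process diagnostics over each
        recording interval.
        """
        dt = self.dt if dt is None else dt
        n_steps = int(round(years / dt))
        rec_steps = max(1, int(round(record_every / dt)))
        records = []
        acc: dict[str, float] = {}
        count = 0
        scalars = ("fixation_mol_yr", "wc_denit_mol_yr", "sed_denit_mol_yr",
                   "denit_org_n_mol_yr", "c_export_mol_yr", "co2_flux_mol_yr",
                   "n_dep_mol_yr")
        for i in range(n_steps):
            t = t0 + i * dt
            state, _, diag = self.step(state, t, dt)
            for k in scalars:
                acc[k] = acc.get(k, 0.0) + diag[k]
            count += 1
            if (i + 1) % rec_steps == 0:
                rec = {k: v / count for k, v in acc.items()}
                rec["t"] = t0 + (i + 1) * dt
                rec["pco2_atm"] = self.atmosphere.pco2
                records.append(rec)
                acc = {}
                count = 0
        self._last_diag = diag
        return state, records
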