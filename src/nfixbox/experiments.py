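"""Experiment drivers: equilibration, the iron and K_Fe ladders, the
fixation-CO2 regression and the diazotroph ablation suite.

All free-atmosphere scenarios are initialised from the fixed-280 ppm
equilibrium of their ocean state (and diazotroph mode), mirroring the
protocol of the simulations this package emulates.  Equilibrium is
declared when the annual drift of the NO3, PO4, O2 and DIC inventories
falls below a tolerance, with a hard cap of 10,000 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .carbonate import AtmosphereBox, respired_carbon_pg
from .engine import Model
from .geometry import BoxGeometry
from .isotopes import d15n_org
from .remin import suboxic_fraction
from .state import TracerState, total_inventory
from .units import mol_to_pg_c, mol_to_tg_n

FE_LADDER_SCALES = (50, 80, 100, 500, 2500)
KFE_LADDER = (0.15, 0.3, 0.6)
ABLATION_MODES = ("off", "CtoP_0", "CtoP_165", "KPO4_0.1", "default")

#: surface regions between roughly 40 S and 40 N
LOW_LAT_REGIONS = ("trop_pac_east_surface", "trop_pac_west_surface",
                   "trop_atl_surface", "subtrop_surface",
                   "subtrop_s_surface")


@dataclass
class ScenarioSpec:
    """Configuration of one equilibrium experiment."""

    ocean_state: str = "mild"
    fe_pattern: str = "modern"
    fe_scale: float = 100.0
    k_fe_override: float | None = None
    diazotroph_mode: str = "default"
    atmosphere_mode: str = "fixed"
    pco2_init: float = 280.0
    max_years: float = 10_000.0
    min_years: float = 1200.0
    drift_tol_pct_per_yr: float = 1e-4
    check_every: float = 200.0
    dt: float = 0.25

    def label(self) -> str:
        k = "" if self.k_fe_override is None else f"_kfe{self.k_fe_override}"
        return (f"{self.ocean_state}_{self.fe_pattern}{int(self.fe_scale)}"
                f"_{self.diazotroph_mode}_{self.atmosphere_mode}{k}")


@dataclass
class ScenarioResult:
    """Equilibrium diagnostics of one experiment."""

    spec: ScenarioSpec
    state: TracerState
    fixation_tg: float
    wc_denit_tg: float
    sed_denit_tg: float
    denit_org_n_tg: float
    n_dep_tg: float
    suboxic_pct: float
    respired_c_pg: float
    pco2_ppm: float
    c_export_pg: float
    surface_po4: dict
    low_lat_utilisation: float
    d15n_org_regions: dict
    drift_pct_per_yr: float
    equilibrated: bool
    years_run: float

    def summary(self) -> dict:
        return {
            "label": self.spec.label(),
            "fixation_tg": self.fixation_tg,
            "wc_denit_tg": self.wc_denit_tg,
            "sed_denit_tg": self.sed_denit_tg,
            "suboxic_pct": self.suboxic_pct,
            "respired_c_pg": self.respired_c_pg,
            "pco2_ppm": self.pco2_ppm,
            "c_export_pg": self.c_export_pg,
            "low_lat_utilisation": self.low_lat_utilisation,
            "equilibrated": self.equilibrated,
            "drift_pct_per_yr": self.drift_pct_per_yr,
            "years_run": self.years_run,
        }


def build_model(spec: ScenarioSpec, geometry: BoxGeometry | None = None) -> Model:
    atm = AtmosphereBox(pco2=spec.pco2_init,
                        mode="free" if spec.atmosphere_mode == "free"
                        else "fixed")
    return Model(geometry=geometry, state_name=spec.ocean_state,
                 fe_pattern=spec.fe_pattern, fe_scale=spec.fe_scale,
                 diazotroph_mode=spec.diazotroph_mode,
                 k_fe_override=spec.k_fe_override, atmosphere=atm,
                 dt=spec.dt)


def _inventories(state: TracerState, geom: BoxGeometry,
                 pco2: float) -> np.ndarray:
    return np.array([
        total_inventory(state, geom, "no3"),
        total_inventory(state, geom, "po4"),
        total_inventory(state, geom, "o2"),
        total_inventory(state, geom, "dic"),
        pco2,
    ])


def low_lat_utilisation(state: TracerState, geom: BoxGeometry) -> float:
    """Low-latitude PO4 utilisation: 1 - (surface PO4 / supply PO4).

    Supply is the volume-weighted PO4 of the thermocline boxes that feed
    the 40 S - 40 N surface; both means are volume weighted.
    """
    surf_idx = [geom.index(t) for t in LOW_LAT_REGIONS]
    thermo_idx = [i for i, t in enumerate(geom.tags)
                  if t.startswith("thermocline")]
    v_s = geom.volume[surf_idx]
    v_t = geom.volume[thermo_idx]
    surf = float((state.po4[surf_idx] * v_s).sum() / v_s.sum())
    supply = float((state.po4[thermo_idx] * v_t).sum() / v_t.sum())
    if supply <= 0:
        return np.nan
    return 1.0 - surf / supply


def _result_from(model: Model, state: TracerState, records: list,
                 spec: ScenarioSpec, drift: float, equilibrated: bool,
                 years: float) -> ScenarioResult:
    g = model.geometry
    rec = records[-1]
    diag = model._last_diag
    clim = model.climatology

    surf_po4 = {g.tags[i]: float(state.po4[i]) for i in g.surface_indices}

    # d15N of exported organic matter per surface region, depth corrected
    surf = g.surface_indices
    d15n = d15n_org(diag["assimilated_n"], diag["assimilated_15n"],
                    diag["fixed_n"], model.params.isotopes.delta_fixation,
                    g.seafloor_km[surf],
                    model.params.isotopes.depth_correction_per_km,
                    model.params.isotopes.r_std)
    d15n_map = {g.tags[i]: float(d15n[j]) for j, i in enumerate(surf)}

    # respired C with the export-weighted C:O2 ratio of the current mix
    c_exp = diag["c_export_mol_yr"]
    p_exp = float((diag["p_export_general"]
                   + diag["p_export_diazotroph"]).sum())
    mean_ctop = c_exp and c_exp / max(p_exp * g.volume[surf].mean(), 1e-30)
    resp = respired_carbon_pg(state.o2, clim.temp_annual, clim.salinity,
                              g.volume)

    return ScenarioResult(
        spec=spec, state=state,
        fixation_tg=mol_to_tg_n(rec["fixation_mol_yr"]),
        wc_denit_tg=mol_to_tg_n(rec["wc_denit_mol_yr"]),
        sed_denit_tg=mol_to_tg_n(rec["sed_denit_mol_yr"]),
        denit_org_n_tg=mol_to_tg_n(rec["denit_org_n_mol_yr"]),
        n_dep_tg=mol_to_tg_n(rec["n_dep_mol_yr"]),
        suboxic_pct=suboxic_fraction(state.o2, g.volume),
        respired_c_pg=resp,
        pco2_ppm=model.atmosphere.pco2,
        c_export_pg=mol_to_pg_c(rec["c_export_mol_yr"]),
        surface_po4=surf_po4,
        low_lat_utilisation=low_lat_utilisation(state, g),
        d15n_org_regions=d15n_map,
        drift_pct_per_yr=drift, equilibrated=equilibrated, years_run=years,
    )


def run_to_equilibrium(spec: ScenarioSpec,
                       initial_state: TracerState | None = None,
                       geometry: BoxGeometry | None = None,
                       model: Model | None = None) -> ScenarioResult:
    """Integrate a scenario until inventory drift is below tolerance.

    Drift is the maximum relative change of the NO3, PO4, O2, DIC (and
    free-atmosphere CO2) inventories per year, evaluated over successive
    ``check_every``-year blocks.  Non-equilibrated runs are returned with
    ``equilibrated=False`` rather than discarded.
    """
    model = model or build_model(spec, geometry)
    g = model.geometry
    state = initial_state.copy() if initial_state is not None \
        else model.initial_state()

    years = 0.0
    drift = np.inf
    prev = _inventories(state, g, model.atmosphere.pco2)
    records: list = []
    equilibrated = False
    while years < spec.max_years:
        block = min(spec.check_every, spec.max_years - years)
        state, rec = model.integrate(state, block, t0=years,
                                     record_every=block)
        records.extend(rec)
        years += block
        cur = _inventories(state, g, model.atmosphere.pco2)
        drift = float(np.max(np.abs(cur - prev) / np.abs(prev)) / block * 100)
        prev = cur
        if drift < spec.drift_tol_pct_per_yr and years >= spec.min_years:
            equilibrated = True
            break
    return _result_from(model, state, records, spec, drift, equilibrated,
                        years)


@dataclass
class StateLibrary:
    """Caches the fixed-280 baseline equilibrium per (state, mode).

    ``spinup_years`` may be a float or a per-state mapping (the warm
    state approaches its attractor slowly and gets a longer cap)."""

    spinup_years: float | dict = 6000.0
    drift_tol: float = 1e-4
    dt: float = 0.25
    _cache: dict = field(default_factory=dict)

    def baseline(self, ocean_state: str,
                 diazotroph_mode: str = "default") -> ScenarioResult:
        key = (ocean_state, diazotroph_mode)
        if key not in self._cache:
            cap = (self.spinup_years.get(ocean_state, 8000.0)
                   if isinstance(self.spinup_years, dict)
                   else self.spinup_years)
            spec = ScenarioSpec(ocean_state=ocean_state,
                                diazotroph_mode=diazotroph_mode,
                                atmosphere_mode="fixed",
                                max_years=cap,
                                min_years=min(3000.0, cap),
                                drift_tol_pct_per_yr=self.drift_tol,
                                dt=self.dt)
            self._cache[key] = run_to_equilibrium(spec)
        return self._cache[key]


def _free_spec(ocean_state: str, mode: str, pattern: str, scale: float,
               k_fe: float | None, years: float, dt: float) -> ScenarioSpec:
    return ScenarioSpec(ocean_state=ocean_state, fe_pattern=pattern,
                        fe_scale=scale, k_fe_override=k_fe,
                        diazotroph_mode=mode, atmosphere_mode="free",
                        max_years=years, dt=dt)


def fe_ladder(ocean_state: str, library: StateLibrary,
              scales: Sequence[float] = FE_LADDER_SCALES,
              diazotroph_mode: str = "default",
              years: float = 4000.0) -> list[ScenarioResult]:
    """Free-atmosphere equilibria across the Fe-deposition ladder."""
    base = library.baseline(ocean_state, diazotroph_mode)
    out = []
    for scale in scales:
        pattern = "glacial" if scale in (500, 2500) else "modern"
        spec = _free_spec(ocean_state, diazotroph_mode, pattern, scale,
                          None, years, library.dt)
        out.append(run_to_equilibrium(spec, initial_state=base.state))
    return out


def kfe_ladder(ocean_state: str, library: StateLibrary,
               k_values: Sequence[float] = KFE_LADDER,
               years: float = 4000.0) -> list[ScenarioResult]:
    """Vary the diazotroph Fe half-saturation at modern deposition."""
    base = library.baseline(ocean_state)
    out = []
    for k in k_values:
        spec = _free_spec(ocean_state, "default", "modern", 100.0, k,
                          years, library.dt)
        out.append(run_to_equilibrium(spec, initial_state=base.state))
    return out


def co2_nfix_regression(results_by_state: dict) -> dict:
    """OLS of equilibrium pCO2 on N2 fixation, per state and pooled.

    Returns per-state slopes as positive 'ppm sequestered per Tg N yr-1'
    (the negated OLS slope) plus their mean and standard deviation.
    """
    slopes = {}
    for state, results in results_by_state.items():
        x = np.array([r.fixation_tg for r in results])
        y = np.array([r.pco2_ppm for r in results])
        if len(x) < 2 or np.ptp(x) == 0:
            raise ValueError(f"need >= 2 distinct points for state {state}")
        slope = np.polyfit(x, y, 1)[0]
        slopes[state] = -float(slope)
    vals = np.array(list(slopes.values()))
    return {"per_state": slopes, "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}


def ablation_suite(library: StateLibrary, ocean_state: str = "mild",
                   modes: Sequence[str] = ("off", "CtoP_0", "default"),
                   scales: Sequence[float] = (100, 500),
                   years: float = 4000.0,
                   spinup_years: float | None = None) -> dict:
    """Respired-C and pCO2 response per diazotroph representation.

    Every mode is spun to its own fixed-280 equilibrium (initialised, for
    the reduced modes, from the default state's equilibrium so the 'off'
    NO3 reservoir is the control inventory), then run across Fe scales
    with a free atmosphere.
    """
    default_base = library.baseline(ocean_state)
    out: dict = {}
    for mode in modes:
        if mode == "default":
            base = default_base
        else:
            spec = ScenarioSpec(ocean_state=ocean_state,
                                diazotroph_mode=mode,
                                atmosphere_mode="fixed",
                                max_years=spinup_years or 5000.0,
                                dt=library.dt)
            base = run_to_equilibrium(spec,
                                      initial_state=default_base.state)
            library._cache[(ocean_state, mode)] = base
        rungs = []
        for scale in scales:
            pattern = "glacial" if scale in (500, 2500) else "modern"
            spec = _free_spec(ocean_state, mode, pattern, scale, None,
                              years, library.dt)
            rungs.append(run_to_equilibrium(spec, initial_state=base.state))
        out[mode] = rungs
    return out


def fixed_n_share(ablation: dict, rung: int = -1) -> float:
    """Share (%) of the Fe-driven respired-C gain carried by fixed-N supply.

    share = (respired-C gain of the no-C-export fixers over the no-fixer
    run) / (gain of default fixers over the no-fixer run), at the glacial
    rung of the ladder.
    """
    off = ablation["off"][rung].respired_c_pg - ablation["off"][0].respired_c_pg
    ctop0 = (ablation["CtoP_0"][rung].respired_c_pg
             - ablation["CtoP_0"][0].respired_c_pg)
    full = (ablation["default"][rung].respired_c_pg
            - ablation["default"][0].respired_c_pg)
    if full - off == 0:
        return np.nan
    return 100.0 * (ctop0 - off) / (full - off)
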