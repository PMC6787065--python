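"""The full headline experiment protocol.

Runs the four physical states across the iron-deposition and K_Fe
ladders with a free atmosphere, the mild-state ablation suite, and the
utilisation comparison, and reduces them to the headline quantities: the
fixation-CO2 regression slope, the per-state glacial drawdowns, the mild
fixation gain, the fixed-N share of the respired-carbon gain, the
suboxic volume and the regional delta-15N response.

The problem sizes (spin-up and scenario caps) are the package's
desk-scale defaults; they are deliberately generous enough that runs
reach the inventory-drift tolerance in almost all cases, and every
result carries its own equilibration flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .experiments import (StateLibrary, ablation_suite,
                          co2_nfix_regression, fe_ladder, fixed_n_share,
                          kfe_ladder)

STATES = ("warm", "mild", "cool", "cold")


@dataclass
class ProtocolSizes:
    """Run-length caps (years) of the desk-scale protocol."""

    spinup: dict | float = field(
        default_factory=lambda: {"warm": 11000.0, "mild": 6000.0,
                                 "cool": 9000.0, "cold": 9000.0})
    rung: float = 5000.0
    kfe_rung: float = 3500.0
    top_rung: float = 4000.0          # cap of the 2500% rung
    ablation_spinup: float = 6000.0
    ablation_rung: float = 5000.0
    dt: float = 0.3
    fe_scales: tuple = (50, 80, 100, 500, 2500)
    kfe_values: tuple = (0.15, 0.6)
    states: tuple = STATES


@dataclass
class ProtocolResults:
    sizes: ProtocolSizes
    ladders: dict = field(default_factory=dict)     # state -> [ScenarioResult]
    regression: dict = field(default_factory=dict)
    drawdowns: dict = field(default_factory=dict)   # state -> ppm (100 vs 500)
    fixation_gains: dict = field(default_factory=dict)
    ablation: dict = field(default_factory=dict)
    fixed_n_share_pct: float = float("nan")
    utilisation_off: float = float("nan")
    utilisation_default: float = float("nan")
    mild_suboxic_pct: float = float("nan")
    d15n_shift: dict = field(default_factory=dict)  # region -> glacial-modern
    library: StateLibrary | None = None

    def rung(self, state: str, scale: float):
        for r in self.ladders[state]:
            if r.spec.k_fe_override is None and r.spec.fe_scale == scale:
                return r
        raise KeyError((state, scale))


def run_protocol(sizes: ProtocolSizes | None = None,
                 verbose: bool = False) -> ProtocolResults:
    sizes = sizes or ProtocolSizes()
    lib = StateLibrary(spinup_years=sizes.spinup, dt=sizes.dt)
    out = ProtocolResults(sizes=sizes, library=lib)

    for state in sizes.states:
        fe = []
        for scale in sizes.fe_scales:
            years = sizes.top_rung if scale == 2500 else sizes.rung
            fe += fe_ladder(state, lib, scales=(scale,), years=years)
        kf = kfe_ladder(state, lib, k_values=sizes.kfe_values,
                        years=sizes.kfe_rung)
        out.ladders[state] = fe + kf
        modern = out.rung(state, 100)
        glacial = out.rung(state, 500)
        out.drawdowns[state] = modern.pco2_ppm - glacial.pco2_ppm
        out.fixation_gains[state] = (glacial.fixation_tg
                                     - modern.fixation_tg)
        if verbose:
            print(f"[{state}] drawdown={out.drawdowns[state]:.2f} ppm "
                  f"gain={out.fixation_gains[state]:.1f} TgN "
                  f"suboxia={modern.suboxic_pct:.2f}%", flush=True)

    out.regression = co2_nfix_regression(out.ladders)
    if verbose:
        print("slopes:", {k: round(v, 3)
                          for k, v in out.regression["per_state"].items()},
              flush=True)

    # mild-state diagnostics
    mild_modern = out.rung("mild", 100)
    mild_glacial = out.rung("mild", 500)
    out.mild_suboxic_pct = mild_modern.suboxic_pct
    out.d15n_shift = {
        region: mild_glacial.d15n_org_regions[region]
        - mild_modern.d15n_org_regions[region]
        for region in mild_modern.d15n_org_regions
    }

    # ablation suite: reuse the default-mode ladder rungs
    suite = ablation_suite(lib, "mild", modes=("off", "CtoP_0", "CtoP_165"),
                           scales=(100, 500), years=sizes.ablation_rung,
                           spinup_years=sizes.ablation_spinup)
    suite["default"] = [mild_modern, mild_glacial]
    out.ablation = suite
    out.fixed_n_share_pct = fixed_n_share(suite)

    # utilisation: fixed-280 equilibria with and without an active N cycle
    out.utilisation_default = lib.baseline("mild").low_lat_utilisation
    out.utilisation_off = lib.baseline(
        "mild", "off").low_lat_utilisation
    if verbose:
        print("d15n shifts:", {k.split("_surface")[0]: round(v, 2)
                               for k, v in out.d15n_shift.items()},
              flush=True)
        print("fixed-N share:", round(out.fixed_n_share_pct, 1),
              "util off/def:", round(out.utilisation_off * 100, 2),
              round(out.utilisation_default * 100, 2), flush=True)
    return out
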