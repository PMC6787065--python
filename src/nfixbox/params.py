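"""Parameter sets for the biogeochemical processes.

All parameters are plain dataclasses so that every experiment can override
any value through configuration.  Defaults follow the published
parameterisation of the diazotroph and redox schemes; where a value is not
published the default is a documented calibration choice (see
``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


def paulmier_closure(c_to_p: float, n_to_p: float) -> tuple[float, float]:
    """Remineralisation demands implied by an organic-matter C:N:P ratio.

    Following the stoichiometric closure of Paulmier et al. for organic
    matter of composition ``C(c) N(n) P(1)``:

    * aerobic remineralisation (with nitrification of the organic N)
      consumes ``O2 : P = C:P + 2 * N:P``,
    * complete heterotrophic denitrification consumes
      ``NO3 : P = 0.8 * C:P + 0.6 * N:P``.

    For the diazotroph ratio 331:50:1 these give 431 and 294.8; for the
    canonical 106:16:1 they give 138 and 94.4.
    """
    o_rem = c_to_p + 2.0 * n_to_p
    n_rem = 0.8 * c_to_p + 0.6 * n_to_p
    return o_rem, n_rem


@dataclass
class DiazotrophParams:
    """Stoichiometry and limitation constants of the N2-fixer group.

    C:N:P:Fe = 331:50:1:0.00064 with O_rem:P and N_rem:P closed to 431 and
    294.8.  ``s_etop`` (export:production scale, mmol P m-3 day-1) is not a
    published value; the default is calibrated so that the mild ocean state
    under modern iron deposition fixes nitrogen within the canonical
    100-150 Tg N yr-1 range.
    """

    c_to_p: float = 331.0
    n_to_p: float = 50.0
    fe_to_p: float = 0.00064          # mol Fe : mol P
    o_rem_to_p: float = 431.0
    n_rem_to_p: float = 294.8
    k_fe: float = 0.3                 # umol Fe m-3
    k_po4: float = 1e-10              # mmol P m-3
    s_etop: float = 0.0003            # mmol P m-3 day-1 (calibrated)
    growth_floor: float = 0.01

    def __post_init__(self) -> None:
        for name in ("c_to_p", "n_to_p", "fe_to_p", "o_rem_to_p",
                     "n_rem_to_p", "k_fe", "k_po4", "s_etop", "growth_floor"):
            v = getattr(self, name)
            if name == "c_to_p":
                if v < 0:
                    raise ValueError(f"{name} must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")

    @classmethod
    def with_stoichiometry(cls, c_to_p: float, n_to_p: float = 50.0,
                           **kwargs) -> "DiazotrophParams":
        """Build a parameter set with remin demands closed consistently."""
        o_rem, n_rem = paulmier_closure(c_to_p, n_to_p)
        return cls(c_to_p=c_to_p, n_to_p=n_to_p,
                   o_rem_to_p=o_rem, n_rem_to_p=n_rem, **kwargs)


@dataclass
class GeneralPhytoParams:
    """General phytoplankton group with PO4-dependent C:P frugality.

    The C:P ratio follows 1 / (0.0069 * PO4 + 0.0061), a published
    phosphate-dependent frugality law: carbon enrichment of exported
    organic matter under P scarcity.  N:P is Redfield (16) and the O2 and
    NO3 remineralisation demands are closed with the same stoichiometric
    rules as the diazotrophs, per export event.
    """

    n_to_p: float = 16.0
    fe_to_p: float = 0.00004          # minimal quota, far below diazotrophs
    k_no3: float = 0.75               # mmol N m-3
    k_po4: float = 0.1                # mmol P m-3
    k_fe: float = 0.1                 # umol Fe m-3 (1/3 of diazotrophs)
    s_etop: float = 0.04              # mmol P m-3 day-1 (calibrated)
    ctop_a: float = 0.0058            # 1/(a*PO4 + b) frugality law
    ctop_b: float = 0.0024
    ctop_min: float = 55.0
    ctop_max: float = 170.0

    def c_to_p(self, po4):
        import numpy as np
        raw = 1.0 / (self.ctop_a * np.maximum(po4, 0.0) + self.ctop_b)
        return np.clip(raw, self.ctop_min, self.ctop_max)


@dataclass
class RedoxParams:
    """Thresholds and coefficients of the remineralisation redox cascade."""

    r_lim_o2: float = 7.5             # mmol O2 m-3, water-column denit threshold
    r_lim_no3: float = 30.0           # mmol NO3 m-3, denit NO3 floor
    sed_alpha: float = 0.08           # sediment denit rate intercept
    sed_beta: float = 0.1             # sediment denit rate O2-NO3 term
    sed_o2_fraction: float = 2.0 / 3.0
    hypoxia_threshold: float = 40.0   # mmol O2 m-3
    suboxia_threshold: float = 10.0   # mmol O2 m-3
    martin_b_oxic: float = 0.9        # sinking-flux attenuation exponent
    martin_b_suboxic: float = 0.4     # deeper transfer through suboxic boxes
    martin_ramp_width: float = 25.0   # mmol O2 m-3; smooth b(O2) transition
    pic_efold_m: float = 2000.0       # CaCO3 dissolution e-folding depth (m)

    def __post_init__(self) -> None:
        if self.suboxia_threshold >= self.hypoxia_threshold:
            raise ValueError("suboxia_threshold must be < hypoxia_threshold")
        if self.r_lim_o2 <= 0 or self.r_lim_no3 <= 0:
            raise ValueError("redox thresholds must be positive")


@dataclass
class FeParams:
    """Iron source/sink controls."""

    relax_target: float = 0.6         # umol Fe m-3
    relax_timescale_days: float = 365.0
    min_contact_fraction: float = 0.05  # legacy criterion, kept in config

    def __post_init__(self) -> None:
        if self.relax_target <= 0 or self.relax_timescale_days <= 0:
            raise ValueError("relaxation target and timescale must be > 0")

    @property
    def relax_timescale_yr(self) -> float:
        from .units import DAYS_PER_YEAR
        return self.relax_timescale_days / DAYS_PER_YEAR


@dataclass
class IsotopeParams:
    """Nitrogen-isotope fractionation factors (per mil).

    The isotope routines of the source model live in a cited prior work;
    these defaults are community-standard values and are fully
    configurable.
    """

    eps_wc_denit: float = 25.0
    eps_sed_denit: float = 3.0
    eps_assimilation: float = 5.0
    delta_fixation: float = -1.0
    delta_deposition: float = -2.0
    r_std: float = 0.0036765          # 15N/14N of atmospheric N2
    depth_correction_per_km: float = 0.9

    def __post_init__(self) -> None:
        if self.r_std <= 0:
            raise ValueError("r_std must be positive")
        for name in ("eps_wc_denit", "eps_sed_denit", "eps_assimilation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GasParams:
    """Air-sea exchange parameters."""

    piston_velocity_m_per_day: float = 3.0
    pco2_fixed: float = 280.0         # ppm used in fixed-atmosphere mode


@dataclass
class ModelParams:
    """Bundle of all process parameter sets."""

    diazotroph: DiazotrophParams = field(default_factory=DiazotrophParams)
    general: GeneralPhytoParams = field(default_factory=GeneralPhytoParams)
    redox: RedoxParams = field(default_factory=RedoxParams)
    iron: FeParams = field(default_factory=FeParams)
    isotopes: IsotopeParams = field(default_factory=IsotopeParams)
    gas: GasParams = field(default_factory=GasParams)
    pic_fraction: float = 0.08        # PIC at 8% of general organic C production

    def replace_diazotroph(self, **kw) -> "ModelParams":
        return replace(self, diazotroph=replace(self.diazotroph, **kw))
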