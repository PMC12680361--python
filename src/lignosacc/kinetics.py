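"""Enzyme cocktail kinetics.

The cocktail contains endoglucanase (EG: internal cellulose cuts),
cellobiohydrolase (CBH: attaches to chain ends and processively releases
cellobiose), beta-glucosidase (BGL: cellobiose -> 2 glucose), and a
non-specific hemicellulase (XYL).

End-product inhibition reduces the effective concentration of the
cellulases available for catalysis: cellobiose and glucose compete for
the active sites of EG and CBH, while BGL is inhibited by glucose only::

    [EG]  = [EG]0  - w_EG^cbs  [EG]0 [cbs] / ([EG]0 + [CBH]0 + [cbs])
                   - w_EG^glc  [EG]0 [glc] / ([EG]0 + [CBH]0 + [BGL]0 + [glc])
    [CBH] = [CBH]0 - w_CBH^cbs [CBH]0 [cbs] / ([EG]0 + [CBH]0 + [cbs])
                   - w_CBH^glc [CBH]0 [glc] / ([EG]0 + [CBH]0 + [BGL]0 + [glc])
    [BGL] = [BGL]0 - w_BGL^glc [BGL]0 [glc] / ([EG]0 + [CBH]0 + [BGL]0 + [glc])

with inhibition strengths ``w`` in [0, 1].  At extreme inhibitor loads the
expressions can turn negative; effective concentrations are clamped at 0.

Non-productive adsorption on lignin sequesters enzymes of every type in
proportion to their nominal abundance: one enzyme is lost per
``lignin_adhesion_rate`` exposed monolignols.

Bond-cleaving propensities use a pseudo Michaelis-Menten form shared per
target: ``3600 * kcat * [E]_eff / (Km + S)`` per eligible bond (S the
eligible-target count), scaled by the digestibility ratio on crystalline
targets.  All rates are per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .substrate import ConfigurationError, SubstrateState

__all__ = [
    "KineticParams",
    "CocktailConfig",
    "EnzymePool",
    "effective_concentrations",
    "lignin_sequestration",
    "steric_window",
    "class_rates",
    "total_propensity",
    "eligible_targets",
]

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants of the cocktail (the 15-slot parameter file).

    ``kcat`` in 1/s (converted to 1/h internally), ``Km`` in
    substrate-count units at microfibril scale, ``k_CBH_proc`` in
    processive cleavages per hour, inhibition strengths dimensionless in
    [0, 1], ``r_enzyme`` in nm.  Defaults give a generic substrate a
    sigmoidal 48-h digestion; the calibration module fits them to data.
    """

    kcat_EG: float = 0.001
    Km_EG: float = 500.0
    k_CBH_proc: float = 10.0
    kcat_BGL: float = 1.0
    Km_BGL: float = 100.0
    kcat_XYL: float = 0.001
    Km_XYL: float = 500.0
    kcat_CBH_attach: float = 0.001
    Km_CBH_attach: float = 500.0
    omega_EG_cbs: float = 0.2
    omega_CBH_cbs: float = 0.2
    omega_EG_glc: float = 0.2
    omega_CBH_glc: float = 0.2
    omega_BGL_glc: float = 0.2
    r_enzyme: float = 2.5

    def __post_init__(self) -> None:
        for name in (
            "kcat_EG",
            "Km_EG",
            "k_CBH_proc",
            "kcat_BGL",
            "Km_BGL",
            "kcat_XYL",
            "Km_XYL",
            "kcat_CBH_attach",
            "Km_CBH_attach",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in (
            "omega_EG_cbs",
            "omega_CBH_cbs",
            "omega_EG_glc",
            "omega_CBH_glc",
            "omega_BGL_glc",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.r_enzyme <= 0:
            raise ConfigurationError("r_enzyme must be positive")

    def with_(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)

    def with_omega(self, value: float) -> "KineticParams":
        """Set all five inhibition strengths to the same value."""
        return self.with_(
            omega_EG_cbs=value,
            omega_CBH_cbs=value,
            omega_EG_glc=value,
            omega_CBH_glc=value,
            omega_BGL_glc=value,
        )

    def scale_kcat(self, factor: float) -> "KineticParams":
        """Scale every catalytic rate (the generic ``K_enzyme`` knob)."""
        return self.with_(
            kcat_EG=self.kcat_EG * factor,
            k_CBH_proc=self.k_CBH_proc * factor,
            kcat_BGL=self.kcat_BGL * factor,
            kcat_XYL=self.kcat_XYL * factor,
            kcat_CBH_attach=self.kcat_CBH_attach * factor,
        )


@dataclass(frozen=True)
class CocktailConfig:
    """Cocktail proportions and the total enzyme count per microfibril."""

    pct_EG: float = 0.135
    pct_CBH: float = 0.353
    pct_BGL: float = 0.100
    pct_XYL: float = 0.412
    total_enz_molecules: float = 50.0

    def __post_init__(self) -> None:
        total = self.pct_EG + self.pct_CBH + self.pct_BGL + self.pct_XYL
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"cocktail fractions sum to {total}, not 1")
        if self.total_enz_molecules < 0:
            raise ConfigurationError("total_enz_molecules must be >= 0")

    def nominal_counts(self) -> dict[str, float]:
        n = self.total_enz_molecules
        return {
            "EG": self.pct_EG * n,
            "CBH": self.pct_CBH * n,
            "BGL": self.pct_BGL * n,
            "XYL": self.pct_XYL * n,
        }


@dataclass
class EnzymePool:
    """Nominal, sequestered and effective enzyme counts."""

    eg0: float
    cbh0: float
    bgl0: float
    xyl0: float
    seq_eg: float = 0.0
    seq_cbh: float = 0.0
    seq_bgl: float = 0.0
    seq_xyl: float = 0.0
    eg_eff: float = 0.0
    cbh_eff: float = 0.0
    bgl_eff: float = 0.0
    xyl_eff: float = 0.0

    @classmethod
    def from_cocktail(cls, cocktail: CocktailConfig) -> "EnzymePool":
        n = cocktail.nominal_counts()
        pool = cls(eg0=n["EG"], cbh0=n["CBH"], bgl0=n["BGL"], xyl0=n["XYL"])
        pool.eg_eff, pool.cbh_eff, pool.bgl_eff = pool.eg0, pool.cbh0, pool.bgl0
        pool.xyl_eff = pool.xyl0
        return pool


def steric_window(r_enzyme: float, r_monomer: float = 0.6) -> int:
    """Hard-sphere steric window in monomers: ``ceil(r_enzyme / (2 r_monomer))``.

    The default enzyme radius (2.5 nm) against 0.6 nm monomers gives
    ``h = 3``: a bound enzyme excludes others within 3 monomers, and a
    shielded bond needs a 2h-wide opening in the covering layer.
    """
    if r_enzyme <= 0 or r_monomer <= 0:
        raise ConfigurationError("radii must be positive")
    return max(1, int(np.ceil(r_enzyme / (2.0 * r_monomer))))


def effective_concentrations(
    pool: EnzymePool, glc: float, cbs: float, params: KineticParams
) -> EnzymePool:
    """Apply end-product inhibition to the (post-sequestration) pool.

    Inhibitor pools are counts on the same scale as the enzyme counts.
    Results are clamped at zero; effective counts never exceed nominal.
    """
    if glc < 0 or cbs < 0:
        raise ConfigurationError("inhibitor counts must be >= 0")
    eg0 = pool.eg0 - pool.seq_eg
    cbh0 = pool.cbh0 - pool.seq_cbh
    bgl0 = pool.bgl0 - pool.seq_bgl
    xyl0 = pool.xyl0 - pool.seq_xyl
    pool.eg_eff = _eq_effective(
        eg0, cbh0, bgl0, params.omega_EG_cbs, params.omega_EG_glc, cbs, glc
    )
    pool.cbh_eff = _eq_effective(
        cbh0, eg0, bgl0, params.omega_CBH_cbs, params.omega_CBH_glc, cbs, glc
    )
    denom = eg0 + cbh0 + bgl0 + glc
    loss = params.omega_BGL_glc * bgl0 * glc / denom if denom > 0 else 0.0
    pool.bgl_eff = max(0.0, bgl0 - loss)
    pool.xyl_eff = max(0.0, xyl0)
    return pool


def _eq_effective(e0, partner0, bgl0, w_cbs, w_glc, cbs, glc) -> float:
    """Effective cellulase count for EG or CBH.

    ``partner0`` is the other cellulase sharing the cellobiose pool;
    the glucose term additionally shares with BGL.
    """
    denom_cbs = e0 + partner0 + cbs
    denom_glc = e0 + partner0 + bgl0 + glc
    loss = 0.0
    if denom_cbs > 0:
        loss += w_cbs * e0 * cbs / denom_cbs
    if denom_glc > 0:
        loss += w_glc * e0 * glc / denom_glc
    return max(0.0, e0 - loss)


def lignin_sequestration(pool: EnzymePool, lignin_units: int, adhesion_rate: float) -> EnzymePool:
    """Remove lignin-adsorbed enzymes from the nominal counts.

    ``floor(exposed monolignols / adhesion_rate)`` enzymes are sequestered,
    split across types in proportion to their nominal abundance (adsorption
    is type-independent).  A smaller adhesion rate means stronger
    adsorption.
    """
    if adhesion_rate <= 0:
        raise ConfigurationError("adhesion_rate must be positive")
    if lignin_units < 0:
        raise ConfigurationError("lignin_units must be >= 0")
    n_seq = float(np.floor(lignin_units / adhesion_rate))
    total0 = pool.eg0 + pool.cbh0 + pool.bgl0 + pool.xyl0
    n_seq = min(n_seq, total0)
    if total0 > 0:
        pool.seq_eg = n_seq * pool.eg0 / total0
        pool.seq_cbh = n_seq * pool.cbh0 / total0
        pool.seq_bgl = n_seq * pool.bgl0 / total0
        pool.seq_xyl = n_seq * pool.xyl0 / total0
    return pool


# ---------------------------------------------------------------------------
# propensities
# ---------------------------------------------------------------------------

#: order of the event classes in :func:`class_rates`
EVENT_CLASSES = (
    "EG_cut_am",
    "EG_cut_cr",
    "XYL_cut_am",
    "XYL_cut_cr",
    "CBH_attach",
    "CBH_step_am",
    "CBH_step_cr",
    "BGL_split",
)


def class_rates(state: SubstrateState, pool: EnzymePool, params: KineticParams) -> np.ndarray:
    """Total propensity (per hour) of each event class, in
    :data:`EVENT_CLASSES` order.

    Assumes ``pool`` already reflects sequestration and end-product
    inhibition for the current sugar pools.
    """
    cfg = state.config
    s_eg = len(state.eg_am) + len(state.eg_cr)
    s_xyl = len(state.xyl_am) + len(state.xyl_cr)
    n_ends = len(state.cbh_ends)
    rates = np.zeros(len(EVENT_CLASSES))
    if s_eg > 0 and pool.eg_eff > 0:
        per = SECONDS_PER_HOUR * params.kcat_EG * pool.eg_eff / (params.Km_EG + s_eg)
        rates[0] = per * len(state.eg_am)
        rates[1] = per * len(state.eg_cr) * cfg.r_ca_cellu
    if s_xyl > 0 and pool.xyl_eff > 0:
        per = SECONDS_PER_HOUR * params.kcat_XYL * pool.xyl_eff / (params.Km_XYL + s_xyl)
        rates[2] = per * len(state.xyl_am)
        rates[3] = per * len(state.xyl_cr) * cfg.r_ca_hemi
    cbh_avail = max(0.0, pool.cbh_eff - len(state.bound_cbh))
    if n_ends > 0 and cbh_avail > 0:
        per = (
            SECONDS_PER_HOUR
            * params.kcat_CBH_attach
            * cbh_avail
            / (params.Km_CBH_attach + n_ends)
        )
        rates[4] = per * n_ends
    rates[5] = params.k_CBH_proc * len(state.step_am)
    rates[6] = params.k_CBH_proc * len(state.step_cr) * cfg.r_ca_cellu
    cbs = state.pools["cellobiose"]
    if cbs > 0 and pool.bgl_eff > 0:
        rates[7] = SECONDS_PER_HOUR * params.kcat_BGL * pool.bgl_eff * cbs / (params.Km_BGL + cbs)
    return rates


def total_propensity(state: SubstrateState, pool: EnzymePool, params: KineticParams) -> float:
    return float(class_rates(state, pool, params).sum())


def eligible_targets(enzyme_type: str, state: SubstrateState) -> set:
    """Current target set of one enzyme type.

    EG: exposed interior cellulose bonds; CBH: attachable free ends;
    XYL: exposed hemicellulose bonds; BGL: the cellobiose pool size.
    """
    if enzyme_type == "EG":
        return state.eg_am.as_set() | state.eg_cr.as_set()
    if enzyme_type == "XYL":
        return state.xyl_am.as_set() | state.xyl_cr.as_set()
    if enzyme_type == "CBH":
        return state.cbh_ends.as_set()
    if enzyme_type == "BGL":
        return set(range(state.pools["cellobiose"]))
    raise ConfigurationError(f"unknown enzyme type {enzyme_type!r}")
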