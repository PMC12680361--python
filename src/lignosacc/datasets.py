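"""Packaged study data and the synthetic time-course generator.

Two plain-CSV fixtures ship with the package:

- ``table1_composition.csv``: compositional assays (cellulose, lignin,
  matrix polysaccharides, acetate; % of dry mass) for two commercial
  celluloses and four plant biomasses under three pre-treatment
  conditions.  The apparent lignin in the pure celluloses is a known
  assay artifact and is flagged, so derived substrate configurations
  zero it unless the lignin mixture is explicitly requested.
- ``table2_fits.csv``: per-sample 48-h sugar yield from cellulose,
  ssNMR crystallinity index (CI), and the calibrated model parameters
  (crystallinity fraction CF, cellulose digestibility ratio r_ca).

The synthetic generator runs the forward simulator at known "true"
parameters and adds Gaussian observation noise, standing in for raw
experimental curves (which are published only as figures) in the
calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .calibrate import TimeCourse
from .engine import CocktailConfig, KineticParams, replicate_mean
from .substrate import Composition, SubstrateConfig

__all__ = [
    "load_table1",
    "load_table2",
    "compositions",
    "sample_composition",
    "sample_config",
    "SyntheticSpec",
    "generate_synthetic_timecourses",
]

_CELLULOSIC = {"avicel", "sigmacell", "avicel_lignin"}

#: default observation times (h) of the synthetic saccharification assays
DEFAULT_ASSAY_TIMES = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0, 48.0)


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("lignosacc.data").joinpath(name).open("r") as fh:
        # keep_default_na: the "NA" pre-treatment label is data, not a NaN
        return pd.read_csv(fh, keep_default_na=False, na_values=[""])


def load_table1() -> pd.DataFrame:
    """Biomass compositions (percent of dry mass), one row per sample."""
    return _read_fixture("table1_composition.csv")


def load_table2() -> pd.DataFrame:
    """48-h yields, crystallinity indices and calibrated CF / r_ca."""
    return _read_fixture("table2_fits.csv")


def sample_composition(sample_id: str, keep_artifact_lignin: bool = False) -> Composition:
    """Composition object for one sample, fractions on the 0-1 scale.

    The artifactual lignin of the pure celluloses is zeroed unless
    ``keep_artifact_lignin`` is set.  ``avicel_lignin`` denotes the 1:1
    (by mass) mixture of AVICEL with dissolved Organosolv lignin: the
    AVICEL fractions are halved and the lignin fraction set to 0.5.
    """
    t1 = load_table1()
    base_id = "avicel" if sample_id == "avicel_lignin" else sample_id
    rows = t1[t1.sample_id == base_id]
    if rows.empty:
        raise KeyError(f"unknown sample_id {sample_id!r}")
    row = rows.iloc[0]
    lignin = row.lignin_pct / 100.0
    if row.lignin_artifact and not keep_artifact_lignin:
        lignin = 0.0
    cellulose = row.cellulose_pct / 100.0
    hemi = row.mps_pct / 100.0
    acetate = row.acetate_pct / 100.0
    if sample_id == "avicel_lignin":
        cellulose, hemi, acetate = cellulose / 2, hemi / 2, acetate / 2
        lignin = 0.5
    return Composition(
        pct_cellulose=cellulose,
        pct_hemicellulose=hemi,
        pct_lignin=lignin,
        pct_acetate=acetate,
        sample_id=sample_id,
        pretreatment=row.pretreatment,
    )


def compositions() -> list[Composition]:
    """All Table-1 compositions (artifact lignin zeroed)."""
    return [sample_composition(s) for s in load_table1().sample_id]


def sample_config(sample_id: str, **overrides) -> SubstrateConfig:
    """Substrate configuration for one sample.

    CF and r_ca come from the calibrated summary table; the commercial
    celluloses (and the lignin mixture) are built free-floating, plant
    biomasses as shielded microfibrils.  The hemicellulose CF and r_ca
    default to the cellulose values.
    """
    t2 = load_table2()
    rows = t2[t2.sample_id == sample_id]
    if rows.empty:
        raise KeyError(f"unknown sample_id {sample_id!r}")
    row = rows.iloc[0]
    comp = sample_composition(sample_id)
    kwargs = dict(
        composition=comp,
        CF_cellu=row.cf_pct / 100.0,
        CF_hemi=row.cf_pct / 100.0,
        r_ca_cellu=float(row.r_ca_cellu),
        r_ca_hemi=float(row.r_ca_cellu),
        free_floating=sample_id in _CELLULOSIC,
    )
    kwargs.update(overrides)
    return SubstrateConfig(**kwargs)


# ---------------------------------------------------------------------------
# synthetic time-courses
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Recipe for simulator-generated saccharification curves.

    The defaults emulate the wet-lab assay layout: 8 sampling times over
    48 h, 3 replicates, 2 percentage points of observation noise.
    """

    config: SubstrateConfig
    params: KineticParams = field(default_factory=KineticParams)
    cocktail: CocktailConfig = field(default_factory=CocktailConfig)
    times: tuple[float, ...] = DEFAULT_ASSAY_TIMES
    n_replicates: int = 3
    noise_sd: float = 2.0
    sim_replicates: int = 5
    seed: int | None = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        times = np.asarray(self.times, dtype=float)
        if times.min() < 0 or times.max() > 48.0:
            raise ValueError("times must lie within [0, 48] h")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")


def generate_synthetic_timecourses(spec: SyntheticSpec) -> tuple[list[TimeCourse], dict]:
    """Simulate curves at the true parameters and add observation noise.

    Returns the noisy time-courses plus a truth record (parameters and
    the noiseless mean curve) for parameter-recovery scoring.
    """
    rng = np.random.default_rng(None if spec.seed is None else spec.seed + 1)
    times = np.asarray(spec.times, dtype=float)
    base = replicate_mean(
        spec.config,
        spec.cocktail,
        spec.params,
        n_rep=spec.sim_replicates,
        t_max=float(times.max()),
        sample_times=times,
        seed=spec.seed,
    )
    values = np.empty((spec.n_replicates, len(times)))
    for r in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd, size=len(times)) if spec.noise_sd > 0 else 0.0
        values[r] = np.clip(base.conversion + noise, 0.0, 100.0)
    tc = TimeCourse(
        sample_id=spec.sample_id,
        times=times,
        values=values,
        replicates=[f"rep{r+1}" for r in range(spec.n_replicates)],
    )
    truth = {
        "CF_cellu": spec.config.CF_cellu,
        "r_ca_cellu": spec.config.r_ca_cellu,
        "params": spec.params,
        "config": spec.config,
        "mean_curve": base.conversion.copy(),
        "times": times,
    }
    return [tc], truth
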