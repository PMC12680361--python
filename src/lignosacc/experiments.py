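"""Scripted in-silico experiments.

Reproducible sweeps over single model parameters on a fixed substrate:

- :func:`inhibition_sweep`: all five end-product inhibition strengths
  set equal and varied over a grid (default 0 to 1 in steps of 0.2);
- :func:`size_sweep`: enzyme radius varied, with the 48-h yields fitted
  by the right tail of a Gaussian, y(r) = G exp(-(r-mu)^2 / (2 sigma^2))
  for r >= mu;
- :func:`phenomenology_panel`: one-parameter-at-a-time perturbations of
  a control (kcat scale, inhibition, enzyme radius, CF, r_ca);
- :func:`table2_summary`: the derived quantities of the study summary
  table (pre-treatment yield differences, CF-CI gaps, rankings,
  digestibility-ratio ordering).

Because the study's own best-fit kinetics are unpublished, sweeps run on
the package's documented default parameter set and are interpreted
through directions and orderings rather than absolute curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .engine import CocktailConfig, KineticParams, Trajectory, replicate_mean
from .substrate import SubstrateConfig

__all__ = [
    "SweepResult",
    "SizeSweepFit",
    "inhibition_sweep",
    "size_sweep",
    "fit_gaussian_tail",
    "phenomenology_panel",
    "table2_summary",
    "DEFAULT_OMEGA_GRID",
]

DEFAULT_OMEGA_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

#: phenomenology knobs and the direction each is expected to push yield
PANEL_DIRECTIONS = {
    "kcat_scale": +1,
    "omega": -1,
    "r_enzyme": -1,
    "CF": -1,
    "r_ca": +1,
}


@dataclass
class SweepResult:
    """One-parameter sweep: per-grid-point replicate-mean yields."""

    parameter: str
    grid: np.ndarray
    yield_mean: np.ndarray  # 48-h (or t_max) conversion, %
    yield_sd: np.ndarray
    trajectories: list[Trajectory]
    n_rep: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "value": self.grid,
                "yield_mean_pct": self.yield_mean,
                "yield_sd_pct": self.yield_sd,
                "n_rep": self.n_rep,
            }
        )


@dataclass
class SizeSweepFit:
    """Right-tail Gaussian fit of yield versus enzyme radius."""

    G: float  # amplitude, %
    mu: float  # nm
    sigma: float  # nm
    residual: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _sweep(
    config_for,
    params_for,
    grid,
    parameter: str,
    config: SubstrateConfig,
    params: KineticParams,
    cocktail: CocktailConfig,
    n_rep: int,
    t_max: float,
    seed,
) -> SweepResult:
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    means, sds, trajs = [], [], []
    for k, v in enumerate(grid):
        tr = replicate_mean(
            config_for(config, v),
            cocktail,
            params_for(params, v),
            n_rep=n_rep,
            t_max=t_max,
            seed=seed,  # same master seed per grid point: paired comparison
        )
        means.append(tr.final_conversion())
        sds.append(float(tr.conversion_sd[-1]))
        trajs.append(tr)
    return SweepResult(
        parameter=parameter,
        grid=grid,
        yield_mean=np.array(means),
        yield_sd=np.array(sds),
        trajectories=trajs,
        n_rep=n_rep,
        seed=seed,
    )


def inhibition_sweep(
    config: SubstrateConfig,
    params: KineticParams | None = None,
    cocktail: CocktailConfig | None = None,
    grid=DEFAULT_OMEGA_GRID,
    n_rep: int = 20,
    t_max: float = 48.0,
    seed: int | None = 0,
) -> SweepResult:
    """Vary all five inhibition strengths together over ``grid``."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 0 or grid.max() > 1:
        raise ValueError("omega grid must lie in [0, 1]")
    return _sweep(
        lambda c, v: c,
        lambda p, v: p.with_omega(v),
        grid,
        "omega",
        config,
        params or KineticParams(),
        cocktail or CocktailConfig(),
        n_rep,
        t_max,
        seed,
    )


def _gauss_tail(r, G, mu, sigma):
    # right side of a Gaussian: flat at G left of the mode
    z = np.maximum(np.asarray(r) - mu, 0.0)
    return G * np.exp(-(z**2) / (2.0 * sigma**2))


def fit_gaussian_tail(radii, yields) -> SizeSweepFit:
    """Least-squares fit of y(r) = G exp(-(r-mu)^2 / (2 sigma^2)), r >= mu.

    The mode ``mu`` is itself fitted; if it falls below the smallest
    radius the whole grid is the tail.  Refuses fewer than 4 points.
    """
    radii = np.asarray(radii, dtype=float)
    yields = np.asarray(yields, dtype=float)
    if len(radii) < 4:
        raise ValueError("need at least 4 grid points to fit the Gaussian tail")
    span = radii.max() - radii.min()
    p0 = (float(yields.max()), float(radii.min()), max(span, 1.0))
    popt, _ = curve_fit(
        _gauss_tail,
        radii,
        yields,
        p0=p0,
        bounds=([0.0, 0.0, 1e-6], [200.0, radii.max(), 10.0 * max(span, 1.0)]),
        maxfev=20000,
    )
    resid = float(np.sum((yields - _gauss_tail(radii, *popt)) ** 2))
    return SizeSweepFit(G=float(popt[0]), mu=float(popt[1]), sigma=float(popt[2]), residual=resid)


def size_sweep(
    config: SubstrateConfig,
    params: KineticParams | None = None,
    cocktail: CocktailConfig | None = None,
    grid=(2.5, 5.0, 7.5, 10.0, 15.0, 20.0),
    n_rep: int = 20,
    t_max: float = 48.0,
    seed: int | None = 0,
) -> tuple[SweepResult, SizeSweepFit]:
    """Vary the enzyme radius; fit the yields with a right-tail Gaussian."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() <= 0:
        raise ValueError("radii must be positive")
    res = _sweep(
        lambda c, v: c,
        lambda p, v: p.with_(r_enzyme=v),
        grid,
        "r_enzyme",
        config,
        params or KineticParams(),
        cocktail or CocktailConfig(),
        n_rep,
        t_max,
        seed,
    )
    fit = fit_gaussian_tail(res.grid, res.yield_mean)
    return res, fit


def phenomenology_panel(
    config: SubstrateConfig,
    params: KineticParams | None = None,
    cocktail: CocktailConfig | None = None,
    deltas: dict[str, float] | None = None,
    n_rep: int = 20,
    t_max: float = 48.0,
    seed: int | None = 0,
) -> dict[str, Trajectory]:
    """Control plus one trajectory per single-parameter perturbation.

    ``deltas`` maps a knob (kcat_scale, omega, r_enzyme, CF, r_ca) to the
    perturbed value (kcat_scale: multiplicative factor; others absolute).
    """
    params = params or KineticParams()
    cocktail = cocktail or CocktailConfig()
    if deltas is None:
        deltas = {
            "kcat_scale": 2.0,
            "omega": min(1.0, params.omega_EG_glc + 0.5),
            "r_enzyme": params.r_enzyme * 3.0,
            "CF": min(1.0, config.CF_cellu + 0.3),
            "r_ca": min(1.0, config.r_ca_cellu * 4.0),
        }
    unknown = set(deltas) - set(PANEL_DIRECTIONS)
    if unknown:
        raise ValueError(f"unknown panel knobs: {sorted(unknown)}")

    def variant(knob: str, v: float) -> tuple[SubstrateConfig, KineticParams]:
        if knob == "kcat_scale":
            return config, params.scale_kcat(v)
        if knob == "omega":
            return config, params.with_omega(v)
        if knob == "r_enzyme":
            return config, params.with_(r_enzyme=v)
        if knob == "CF":
            return config.with_(CF_cellu=v, CF_hemi=v), params
        if knob == "r_ca":
            return config.with_(r_ca_cellu=v, r_ca_hemi=v), params
        raise ValueError(knob)

    out = {
        "control": replicate_mean(config, cocktail, params, n_rep=n_rep, t_max=t_max, seed=seed)
    }
    for knob, v in deltas.items():
        cfg, par = variant(knob, v)
        out[knob] = replicate_mean(cfg, cocktail, par, n_rep=n_rep, t_max=t_max, seed=seed)
    return out


def parameter_recovery(
    seed: int,
    cf_true: float = 0.45,
    r_ca_true: float = 0.30,
    noise_sd: float = 2.0,
    n_obs_replicates: int = 3,
    length_fibril: int = 30,
    n_generations: int = 35,
    n_subgenerations: int = 8,
    n_replicates: int = 6,
) -> dict:
    """End-to-end calibration check on simulator-generated curves.

    Synthetic saccharification curves (8 assay times, Gaussian observation
    noise) are generated at known substrate parameters; the generational
    search then fits CF and r_ca from scratch.  Returns the truth, the
    estimates, and their errors.
    """
    from .calibrate import FitParam, FitSpec, SaccharificationModel
    from .datasets import SyntheticSpec, generate_synthetic_timecourses
    from .substrate import Composition

    comp = Composition(pct_cellulose=0.8, sample_id="syn")
    truth_cfg = SubstrateConfig(
        composition=comp,
        length_fibril=length_fibril,
        free_floating=True,
        CF_cellu=cf_true,
        CF_hemi=cf_true,
        r_ca_cellu=r_ca_true,
        r_ca_hemi=r_ca_true,
    )
    cocktail = CocktailConfig(total_enz_molecules=12)
    spec = SyntheticSpec(
        config=truth_cfg,
        cocktail=cocktail,
        noise_sd=noise_sd,
        n_replicates=n_obs_replicates,
        seed=seed,
        sample_id="syn",
    )
    tcs, truth = generate_synthetic_timecourses(spec)
    fitspec = FitSpec(
        per_sample=[
            FitParam("CF_cellu", 0.0, 1.0),
            FitParam("r_ca_cellu", 1e-4, 1.0, scale="log"),
        ],
        ci_targets={"syn": 100.0 * cf_true},
        n_generations=n_generations,
        n_subgenerations=n_subgenerations,
        n_replicates=n_replicates,
    )
    base = truth_cfg.with_(CF_cellu=0.5, r_ca_cellu=0.1)
    model = SaccharificationModel(tcs, {"syn": base}, fitspec, cocktail=cocktail)
    result = model.fit(seed=seed)
    cf_fit = result.per_sample_params["syn"]["CF_cellu"]
    r_ca_fit = result.per_sample_params["syn"]["r_ca_cellu"]
    return {
        "cf_true": cf_true,
        "cf_fit": cf_fit,
        "cf_error": cf_fit - cf_true,
        "r_ca_true": r_ca_true,
        "r_ca_fit": r_ca_fit,
        "r_ca_factor": max(r_ca_fit / r_ca_true, r_ca_true / r_ca_fit),
        "best_objective": result.best_objective,
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# summary-table arithmetic
# ---------------------------------------------------------------------------


def table2_summary(table2: pd.DataFrame) -> dict:
    """Derived quantities from the per-sample summary table.

    Returns a dict with: the swelling penalty (NS+OCAT minus YS+OCAT 48-h
    yield) per biomass, the CI minus CF gap per sample, the shared
    cellulosic yield (commercial celluloses), CI and yield rankings per
    pre-treatment, and the digestibility-ratio ordering check
    NS+OCAT > untreated >= YS+OCAT per biomass.
    """
    df = table2.set_index("sample_id")
    biomasses = ("beech", "miscanthus", "sida", "walnut")

    def need(sid: str) -> pd.Series:
        if sid not in df.index:
            raise KeyError(f"summary table is missing sample {sid!r}")
        return df.loc[sid]

    ns_ys = {
        b: float(need(f"{b}_ns_ocat").yield_48h_pct - need(f"{b}_ys_ocat").yield_48h_pct)
        for b in biomasses
    }
    ci_cf = {sid: float(row.ci_pct - row.cf_pct) for sid, row in df.iterrows()}
    cellulosic = {
        sid: float(need(sid).yield_48h_pct) for sid in ("avicel", "sigmacell")
    }
    shared = (
        cellulosic["avicel"] if cellulosic["avicel"] == cellulosic["sigmacell"] else None
    )

    rankings = {}
    plant = table2[table2.pretreatment.isin(["untreated", "NS+OCAT", "YS+OCAT"])]
    for pre, grp in plant.groupby("pretreatment"):
        rankings[pre] = {
            "ci_ascending": list(grp.sort_values("ci_pct").sample_id),
            "yield_descending": list(
                grp.sort_values("yield_48h_pct", ascending=False).sample_id
            ),
        }

    r_ca_trend = {
        b: bool(
            need(f"{b}_ns_ocat").r_ca_cellu > need(f"{b}_untreated").r_ca_cellu
            and need(f"{b}_untreated").r_ca_cellu >= need(f"{b}_ys_ocat").r_ca_cellu
        )
        for b in biomasses
    }

    return {
        "ns_minus_ys_yield_pct": ns_ys,
        "ci_minus_cf_pct": ci_cf,
        "cellulosic_yield_shared_pct": shared,
        "rankings": rankings,
        "r_ca_trend_ns_gt_untreated_ge_ys": r_ca_trend,
    }
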