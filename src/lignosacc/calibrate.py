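"""Generational random-search calibration of the saccharification model.

:class:`SaccharificationModel` pairs experimental (or synthetic)
saccharification time-courses with substrate configurations and a
:class:`FitSpec`; :meth:`SaccharificationModel.fit` runs the search and
returns a :class:`FitResult` with the estimates, the objective trace and
a summary table.

The search proceeds through generations: each generation spawns
``n_subgenerations`` candidates by randomly perturbing the incumbent
parameter vector within its bounds, evaluates the objective (mean squared
distance between the replicate-averaged simulated curves and the data,
plus a crystallinity-index penalty), and adopts the best candidate only
if it improves on the incumbent; otherwise the incumbent seeds the next
generation again.  The minimum over all generations is the fit.

Kinetic and inhibition parameters are shared across all samples of the
model (one pre-treatment condition), while the substrate parameters
(crystallinity fraction CF, digestibility ratio r_ca) are per sample.

Objective evaluations reuse one fixed set of replicate seeds derived from
the master seed (common random numbers), making the objective a
deterministic function of the parameters within a fit and the accepted
trace non-increasing by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import CocktailConfig, KineticParams, replicate_mean
from .substrate import ConfigurationError, SubstrateConfig, average_crystallinity

__all__ = [
    "TimeCourse",
    "FitParam",
    "FitSpec",
    "FitResult",
    "SaccharificationModel",
    "summarize_fit",
]

logger = logging.getLogger(__name__)

#: parameter names living on KineticParams (sharable across samples)
KINETIC_NAMES = frozenset(
    {
        "kcat_EG",
        "Km_EG",
        "k_CBH_proc",
        "kcat_BGL",
        "Km_BGL",
        "kcat_XYL",
        "Km_XYL",
        "kcat_CBH_attach",
        "Km_CBH_attach",
        "omega_EG_cbs",
        "omega_CBH_cbs",
        "omega_EG_glc",
        "omega_CBH_glc",
        "omega_BGL_glc",
        "r_enzyme",
    }
)

#: parameter names living on SubstrateConfig (fitted per sample)
SUBSTRATE_NAMES = frozenset(
    {"CF_cellu", "CF_hemi", "r_ca_cellu", "r_ca_hemi", "mu_defect", "N_defect"}
)


@dataclass
class TimeCourse:
    """One sample's saccharification curve(s).

    ``values`` is (n_replicates, n_times) in percent sugar release from
    cellulose; ``times`` in hours, strictly increasing.
    """

    sample_id: str
    times: np.ndarray
    values: np.ndarray
    replicates: list[str] = field(default_factory=list)
    errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.sample_id}: times must be strictly increasing")
        if self.values.shape[1] != len(self.times):
            raise ValueError(f"{self.sample_id}: values/times shape mismatch")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValueError(f"{self.sample_id}: values outside [0, 100]")
        if not self.replicates:
            self.replicates = [f"rep{i+1}" for i in range(self.values.shape[0])]

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass(frozen=True)
class FitParam:
    """One fitted parameter: bounds and perturbation scale type.

    ``scale='log'`` uses multiplicative log-normal perturbation steps
    (rate-like parameters spanning decades), ``'linear'`` additive uniform
    steps (fractions).  Bounds are enforced by reflection.
    """

    name: str
    low: float
    high: float
    scale: str = "linear"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)) or self.low >= self.high:
            raise ConfigurationError(f"{self.name}: bounds must be finite with low < high")
        if self.scale not in ("log", "linear"):
            raise ConfigurationError(f"{self.name}: scale must be 'log' or 'linear'")
        if self.scale == "log" and self.low <= 0:
            raise ConfigurationError(f"{self.name}: log-scale bounds must be positive")

    def initial(self) -> float:
        if self.scale == "log":
            return math.sqrt(self.low * self.high)
        return 0.5 * (self.low + self.high)


@dataclass
class FitSpec:
    """Search space and hyper-parameters of the generational fit.

    ``shared`` parameters (kinetics/inhibition) apply to every sample;
    ``per_sample`` parameters (CF, r_ca, ...) are fitted independently for
    each sample.  ``ci_targets`` maps samples to crystallinity-index
    targets (percent); ``ci_weight`` is the penalty weight (None: scaled
    automatically so the penalty matches the curve term at
    initialisation).
    """

    shared: list[FitParam] = field(default_factory=list)
    per_sample: list[FitParam] = field(default_factory=list)
    ci_targets: dict[str, float] = field(default_factory=dict)
    ci_weight: float | None = None
    n_generations: int = 60
    n_subgenerations: int = 8
    n_replicates: int = 5
    perturbation_scale: float = 0.25
    t_max: float = 48.0
    initial: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.shared:
            if p.name not in KINETIC_NAMES:
                raise ConfigurationError(f"unknown shared parameter {p.name!r}")
        for p in self.per_sample:
            if p.name not in SUBSTRATE_NAMES:
                raise ConfigurationError(f"unknown per-sample parameter {p.name!r}")


@dataclass
class FitResult:
    """Outcome of a generational calibration."""

    shared_params: dict[str, float]
    per_sample_params: dict[str, dict[str, float]]
    kinetics: KineticParams
    configs: dict[str, SubstrateConfig]
    best_objective: float
    objective_trace: list[float]
    cf_avg: dict[str, float]  # percent, carbohydrate-bond average
    ci_targets: dict[str, float]
    ci_weight: float
    seed: int | None
    n_evaluations: int = 0

    def summary(self) -> pd.DataFrame:
        """Per-sample table: fitted CF vs CI target, fitted r_ca."""
        rows = []
        for sid, cfg in self.configs.items():
            ci = self.ci_targets.get(sid, np.nan)
            rows.append(
                {
                    "sample_id": sid,
                    "CF_cellu": cfg.CF_cellu,
                    "r_ca_cellu": cfg.r_ca_cellu,
                    "cf_avg_pct": self.cf_avg[sid],
                    "ci_pct": ci,
                    "cf_minus_ci": self.cf_avg[sid] - ci,
                }
            )
        return pd.DataFrame(rows)


class SaccharificationModel:
    """Saccharification time-courses + substrate configurations, fitted by
    generational random search.

    Parameters
    ----------
    timecourses : list of TimeCourse
        One entry per sample.
    configs : dict sample_id -> SubstrateConfig
        Substrate build recipes; per-sample fitted parameters override
        the corresponding fields.
    spec : FitSpec
        Search space and hyper-parameters.
    base_params : KineticParams
        Starting kinetics; shared fitted parameters override fields.
    """

    def __init__(
        self,
        timecourses: list[TimeCourse],
        configs: dict[str, SubstrateConfig],
        spec: FitSpec,
        base_params: KineticParams | None = None,
        cocktail: CocktailConfig | None = None,
    ):
        self.timecourses = {tc.sample_id: tc for tc in timecourses}
        if set(self.timecourses) != set(configs):
            raise ConfigurationError(
                f"sample sets differ: curves {sorted(self.timecourses)} vs "
                f"configs {sorted(configs)}"
            )
        missing = set(spec.ci_targets) - set(configs)
        if missing:
            raise ConfigurationError(f"CI targets for unknown samples: {sorted(missing)}")
        self.configs = dict(configs)
        self.spec = spec
        self.base_params = base_params or KineticParams()
        self.cocktail = cocktail or CocktailConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        configs: dict[str, SubstrateConfig],
        spec: FitSpec,
        **kwargs,
    ) -> "SaccharificationModel":
        """Build from a tidy frame with columns
        ``time_h, value_pct, sample_id, replicate``."""
        tcs = []
        for sid, grp in df.groupby("sample_id"):
            piv = grp.pivot_table(
                index="replicate", columns="time_h", values="value_pct", aggfunc="mean"
            ).sort_index(axis=1)
            tcs.append(
                TimeCourse(
                    sample_id=str(sid),
                    times=piv.columns.to_numpy(dtype=float),
                    values=piv.to_numpy(dtype=float),
                    replicates=[str(r) for r in piv.index],
                )
            )
        return cls(tcs, configs, spec, **kwargs)

    # -- parameter vector plumbing -----------------------------------------

    def _param_list(self) -> list[tuple[str, str | None, FitParam]]:
        """(key, sample or None, FitParam) in a fixed order."""
        out = [(p.name, None, p) for p in self.spec.shared]
        for sid in sorted(self.configs):
            out.extend((p.name, sid, p) for p in self.spec.per_sample)
        return out

    def _initial_vector(self) -> dict:
        vec = {}
        for name, sid, p in self._param_list():
            init = self.spec.initial.get(name if sid is None else f"{sid}:{name}")
            vec[(name, sid)] = float(init) if init is not None else p.initial()
        return vec

    def _materialise(self, vec: dict) -> tuple[KineticParams, dict[str, SubstrateConfig]]:
        kin_updates = {n: v for (n, sid), v in vec.items() if sid is None}
        kinetics = replace(self.base_params, **kin_updates) if kin_updates else self.base_params
        configs = {}
        for sid, cfg in self.configs.items():
            upd = {n: v for (n, s), v in vec.items() if s == sid}
            configs[sid] = replace(cfg, **upd) if upd else cfg
        return kinetics, configs

    def _perturb(self, vec: dict, rng: np.random.Generator) -> dict:
        s = self.spec.perturbation_scale
        new = {}
        for name, sid, p in self._param_list():
            x = vec[(name, sid)]
            if p.scale == "log":
                y = math.log(x) + rng.normal(0.0, s * math.log(p.high / p.low) / 2.0)
                y = _reflect(y, math.log(p.low), math.log(p.high))
                new[(name, sid)] = math.exp(y)
            else:
                y = x + rng.uniform(-s, s) * (p.high - p.low)
                new[(name, sid)] = _reflect(y, p.low, p.high)
        return new

    # -- objective -----------------------------------------------------------

    def objective(
        self,
        kinetics: KineticParams,
        configs: dict[str, SubstrateConfig],
        ci_weight: float,
        n_rep: int | None = None,
        seed: int | None = 0,
    ) -> float:
        """Sum over samples of the squared curve misfit (replicate-mean
        simulation vs replicate-mean data) plus the weighted squared
        CF-CI mismatch (percent scale)."""
        n_rep = n_rep or self.spec.n_replicates
        sse = 0.0
        for sid, tc in self.timecourses.items():
            cfg = configs[sid]
            sim = replicate_mean(
                cfg,
                self.cocktail,
                kinetics,
                n_rep=n_rep,
                t_max=self.spec.t_max,
                sample_times=tc.times,
                seed=seed,
            )
            sse += float(np.sum((sim.conversion - tc.mean()) ** 2))
            if sid in self.spec.ci_targets:
                cf_pct = 100.0 * average_crystallinity(cfg)
                sse += ci_weight * (cf_pct - self.spec.ci_targets[sid]) ** 2
        return sse

    def _curve_and_ci_terms(self, kinetics, configs, seed) -> tuple[float, float]:
        curve = self.objective(kinetics, configs, ci_weight=0.0, seed=seed)
        ci = sum(
            (100.0 * average_crystallinity(configs[sid]) - t) ** 2
            for sid, t in self.spec.ci_targets.items()
        )
        return curve, ci

    # -- fitting ---------------------------------------------------------------

    def fit(
        self,
        seed: int | None = 0,
        n_generations: int | None = None,
        objective_fn=None,
    ) -> FitResult:
        """Run the generational search.

        ``objective_fn(vec_dict) -> float``, if given, replaces the
        simulation objective (surrogate testing).
        """
        spec = self.spec
        n_gen = n_generations or spec.n_generations
        master = np.random.SeedSequence(seed)
        pert_rng = np.random.default_rng(master.spawn(1)[0])
        # one fixed evaluation seed: common random numbers across the fit
        eval_seed = int(master.generate_state(1)[0] % (2**31 - 1))

        vec = self._initial_vector()

        if objective_fn is None:
            kin0, cfg0 = self._materialise(vec)
            if spec.ci_weight is None and spec.ci_targets:
                curve0, ci0 = self._curve_and_ci_terms(kin0, cfg0, eval_seed)
                ci_weight = curve0 / ci0 if ci0 > 1e-12 else 1.0
            else:
                ci_weight = spec.ci_weight or 0.0

            def evaluate(v: dict) -> float:
                kin, cfgs = self._materialise(v)
                return self.objective(kin, cfgs, ci_weight, seed=eval_seed)

        else:
            ci_weight = spec.ci_weight or 0.0
            evaluate = objective_fn

        n_eval = 0
        incumbent, inc_obj = vec, evaluate(vec)
        n_eval += 1
        best, best_obj = dict(incumbent), inc_obj
        trace = [inc_obj]
        for gen in range(n_gen):
            cands = [self._perturb(incumbent, pert_rng) for _ in range(spec.n_subgenerations)]
            objs = [evaluate(c) for c in cands]
            n_eval += len(cands)
            k = int(np.argmin(objs))
            if objs[k] < inc_obj:
                incumbent, inc_obj = cands[k], objs[k]
            if inc_obj < best_obj:
                best, best_obj = dict(incumbent), inc_obj
            trace.append(inc_obj)
            logger.debug("generation %d: incumbent objective %.4g", gen, inc_obj)

        kinetics, configs = self._materialise(best)
        cf_avg = {sid: 100.0 * average_crystallinity(cfg) for sid, cfg in configs.items()}
        return FitResult(
            shared_params={n: v for (n, s), v in best.items() if s is None},
            per_sample_params={
                sid: {n: v for (n, s), v in best.items() if s == sid}
                for sid in self.configs
            },
            kinetics=kinetics,
            configs=configs,
            best_objective=best_obj,
            objective_trace=trace,
            cf_avg=cf_avg,
            ci_targets=dict(spec.ci_targets),
            ci_weight=ci_weight,
            seed=seed,
            n_evaluations=n_eval,
        )


def _reflect(x: float, low: float, high: float) -> float:
    """Reflect x into [low, high]."""
    width = high - low
    if width <= 0:
        return low
    y = (x - low) % (2.0 * width)
    return low + (y if y <= width else 2.0 * width - y)


def summarize_fit(
    result: FitResult,
    table2: pd.DataFrame,
    n_rep: int = 5,
    seed: int | None = 0,
    cocktail: CocktailConfig | None = None,
) -> pd.DataFrame:
    """Compare a fit against the reference summary table.

    Per sample: fitted CF (percent) vs measured CI, their difference, the
    fitted digestibility ratio and the simulated 48-h yield.  Adds
    per-pre-treatment Spearman rank agreement between CI and yield.
    """
    from scipy.stats import spearmanr

    cocktail = cocktail or CocktailConfig()
    rows = []
    for sid, cfg in result.configs.items():
        t2 = table2[table2.sample_id == sid]
        ci = float(t2.ci_pct.iloc[0]) if not t2.empty else np.nan
        sim = replicate_mean(
            cfg, cocktail, result.kinetics, n_rep=n_rep, t_max=48.0, seed=seed
        )
        rows.append(
            {
                "sample_id": sid,
                "pretreatment": t2.pretreatment.iloc[0] if not t2.empty else "",
                "cf_pct": result.cf_avg[sid],
                "ci_pct": ci,
                "cf_minus_ci": result.cf_avg[sid] - ci,
                "r_ca_cellu": cfg.r_ca_cellu,
                "sim_yield_48h_pct": sim.final_conversion(),
            }
        )
    df = pd.DataFrame(rows)
    corrs = {}
    for pre, grp in df.groupby("pretreatment"):
        if len(grp) >= 3 and grp.ci_pct.notna().all():
            rho = spearmanr(grp.ci_pct, grp.sim_yield_48h_pct).statistic
        else:
            rho = np.nan
        corrs[pre] = rho
    df["ci_yield_rank_corr"] = df.pretreatment.map(corrs)
    return df
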