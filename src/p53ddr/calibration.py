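"""Multistart least-squares calibration of the DDR model to GFP time courses.

The fit shares one set of kinetic parameters across the four reporter
datasets (p53, MDM2, p21, BTG2) and three cisplatin concentrations, with a
separate affine observable map (scaling, offset) per reporter.  Every
objective evaluation starts the simulation from the stress-free steady
state of the candidate parameter set, so basal conditions are consistent by
construction.  Optimization runs in log10 parameter space with a
trust-region-reflective solver, restarted from Latin-hypercube-sampled
initial points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from p53ddr.model import (
    RATE_PARAM_NAMES,
    REPORTERS,
    IntegrationError,
    KineticParameters,
    ModelState,
    ObservableMap,
    SteadyStateError,
    StimulusSchedule,
    simulate,
    steady_state,
)

__all__ = [
    "GfpDataset",
    "FitConfig",
    "FitResult",
    "objective",
    "lhs_sample",
    "fit",
    "minimal_cost_family",
    "select_from_family",
]

#: Applied cisplatin concentration (uM) per concentration index.
APPLIED_CONCENTRATIONS = {1: 1.0, 2: 2.5, 3: 5.0}

_REQUIRED_COLUMNS = ("reporter", "concentration_index", "replicate", "time_h", "intensity")

#: Model species summed per reporter (p53-GFP tags both phosphoforms).
_REPORTER_TOTAL = {
    "p53": ("P53", "P53p"),
    "mdm2": ("MDM2",),
    "p21": ("P21",),
    "btg2": ("BTG2",),
}


class GfpDataset:
    """Normalized GFP reporter time courses in tidy form.

    Wraps a DataFrame with columns ``reporter`` (p53/mdm2/p21/btg2),
    ``concentration_index`` (1, 2, 3 for 1, 2.5, 5 uM), ``replicate``,
    ``time_h`` and ``intensity`` (min-max normalized, background-corrected;
    values may slightly exceed [0, 1]).
    """

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in _REQUIRED_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"GfpDataset missing columns: {missing}")
        df = records.copy()
        bad = set(df["reporter"]) - set(REPORTERS)
        if bad:
            raise ValueError(f"unknown reporters in dataset: {sorted(bad)}")
        bad_ci = set(df["concentration_index"]) - set(APPLIED_CONCENTRATIONS)
        if bad_ci:
            raise ValueError(f"concentration_index must be in {{1,2,3}}, got {sorted(bad_ci)}")
        lo, hi = df["intensity"].min(), df["intensity"].max()
        if lo < -0.2 - 1e-9 or hi > 1.2 + 1e-9:
            raise ValueError(
                f"normalized intensities outside [-0.2, 1.2]: range [{lo}, {hi}]"
            )
        self.records = df.reset_index(drop=True)

    def reporters(self) -> list[str]:
        return sorted(set(self.records["reporter"]))

    def replicate_means(self) -> pd.DataFrame:
        """Mean intensity over replicates per (reporter, concentration, time)."""
        return (
            self.records.groupby(["reporter", "concentration_index", "time_h"], as_index=False)[
                "intensity"
            ]
            .mean()
            .sort_values(["reporter", "concentration_index", "time_h"])
            .reset_index(drop=True)
        )

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GfpDataset":
        return cls(pd.read_csv(path, sep="\t"))


def default_bounds() -> dict[str, tuple[float, float]]:
    """Log-uniform sampling bounds per free parameter (linear scale)."""
    bounds = {}
    for name in RATE_PARAM_NAMES:
        if name.startswith("Km_") or name.startswith("EC"):
            bounds[name] = (1e-2, 1e2)
        else:
            bounds[name] = (1e-4, 1e2)
    return bounds


@dataclass
class FitConfig:
    """Configuration of the multistart calibration.

    ``fixed`` maps parameter names to pinned values; the effective-dose
    anchor ``EC1 = 1`` is always fixed to resolve the scale degeneracy
    between stress amplitude and damage kinetics.  Observable scaling and
    offset are profiled out analytically per reporter at every objective
    evaluation (they enter the residual linearly), so only kinetic
    parameters are searched.
    """

    n_starts: int = 100
    bounds: dict[str, tuple[float, float]] = field(default_factory=default_bounds)
    fixed: dict[str, float] = field(default_factory=lambda: {"EC1": 1.0})
    observable_map: ObservableMap | None = None  # None: profiled analytically
    hill_n: int = 4
    seed: int = 0
    sim_rtol: float = 1e-6
    sim_atol: float = 1e-9
    xtol: float = 1e-8
    ftol: float = 1e-8
    max_nfev: int | None = None

    def __post_init__(self):
        if "EC1" not in self.fixed:
            raise ValueError("EC1 must be fixed in any calibration context")
        for name, (lo, hi) in self.bounds.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and 0 < lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    @property
    def free_names(self) -> list[str]:
        return [n for n in RATE_PARAM_NAMES if n not in self.fixed]


@dataclass
class FitResult:
    params: KineticParameters
    observable_map: ObservableMap
    cost: float
    converged: bool
    start_index: int
    rank: int = -1
    message: str = ""

    def sort_key(self):
        # deterministic tie-break: cost, then L2 norm of log-parameters
        with np.errstate(all="ignore"):
            norm = float(np.linalg.norm(np.log(np.abs(self.params.as_array()) + 1e-300)))
        return (self.cost, norm, self.start_index)


def _simulated_totals(
    params: KineticParameters,
    times_by_conc: dict[int, np.ndarray],
    rtol: float,
    atol: float,
) -> tuple[ModelState, dict[int, dict[str, np.ndarray]]]:
    """Simulate from steady state and return per-reporter species totals."""
    ss = steady_state(params)
    out: dict[int, dict[str, np.ndarray]] = {}
    for ci, times in times_by_conc.items():
        schedule = StimulusSchedule(EC=params.ec_for_index(ci), tau=params.tau)
        traj = simulate(params, ss, schedule, times, rtol=rtol, atol=atol)
        out[ci] = {
            rep: sum(traj.species(sp) for sp in _REPORTER_TOTAL[rep])
            for rep in REPORTERS
        }
    return ss, out


def _profile_observable(model_total: np.ndarray, data: np.ndarray) -> tuple[float, float]:
    """Closed-form least-squares (scaling, offset) with scaling > 0."""
    x = model_total
    y = data
    vx = np.var(x)
    if vx <= 1e-30:
        return 1e-6, float(np.mean(y))
    slope = float(np.cov(x, y, bias=True)[0, 1] / vx)
    if slope <= 0:
        slope = 1e-6
    inter = float(np.mean(y) - slope * np.mean(x))
    return slope, inter


def _residuals_for_params(
    params: KineticParameters,
    data_means: pd.DataFrame,
    rtol: float,
    atol: float,
    omap: ObservableMap | None = None,
) -> tuple[np.ndarray, ObservableMap]:
    """Residual vector over all (reporter, concentration, time) cells.

    When ``omap`` is None the per-reporter scaling/offset are profiled
    analytically (jointly over that reporter's concentrations and times).
    """
    times_by_conc = {
        int(ci): np.asarray(sorted(g["time_h"].unique()), float)
        for ci, g in data_means.groupby("concentration_index")
    }
    _, totals = _simulated_totals(params, times_by_conc, rtol, atol)

    residuals = []
    scaling, offset = {}, {}
    for rep in REPORTERS:
        sub = data_means[data_means["reporter"] == rep]
        if sub.empty:
            scaling[rep], offset[rep] = 1.0, 0.0
            continue
        model_vals, data_vals = [], []
        for ci, g in sub.groupby("concentration_index"):
            times = times_by_conc[int(ci)]
            idx = np.searchsorted(times, g["time_h"].to_numpy())
            model_vals.append(totals[int(ci)][rep][idx])
            data_vals.append(g["intensity"].to_numpy())
        x = np.concatenate(model_vals)
        y = np.concatenate(data_vals)
        if omap is None:
            s, o = _profile_observable(x, y)
        else:
            s, o = omap.scaling[rep], omap.offset[rep]
        scaling[rep], offset[rep] = s, o
        residuals.append(s * x + o - y)
    fitted_map = ObservableMap(scaling=scaling, offset=offset)
    return np.concatenate(residuals), fitted_map


def objective(
    params: KineticParameters,
    omap: ObservableMap | None,
    data: GfpDataset,
    sim_rtol: float = 1e-6,
    sim_atol: float = 1e-9,
) -> float:
    """Sum of squared residuals between model observables and the data.

    Residuals are computed on replicate means, one per (reporter,
    concentration, time).  Returns ``inf`` when the steady state or the
    integration fails, so that multistart optimization discards the start.
    """
    means = data.replicate_means()
    try:
        res, _ = _residuals_for_params(params, means, sim_rtol, sim_atol, omap=omap)
    except (SteadyStateError, IntegrationError):
        return float("inf")
    return float(np.dot(res, res))


def lhs_sample(
    bounds: dict[str, tuple[float, float]] | list[tuple[float, float]],
    n: int,
    seed: int,
) -> np.ndarray:
    """Latin hypercube sample of ``n`` points, log-uniform within bounds.

    Each dimension is stratified into ``n`` equal-probability bins with
    exactly one point per bin; returns points on the linear scale with
    shape (n, d).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(bounds, dict):
        pairs = list(bounds.values())
    else:
        pairs = list(bounds)
    lo = np.log10([p[0] for p in pairs])
    hi = np.log10([p[1] for p in pairs])
    sampler = qmc.LatinHypercube(d=len(pairs), seed=seed)
    unit = sampler.random(n)
    return 10.0 ** (lo + unit * (hi - lo))


def fit(data: GfpDataset, config: FitConfig) -> list[FitResult]:
    """Run the multistart trust-region calibration and rank the results.

    Every start enforces steady-state initial conditions through the
    objective; failed starts (no steady state, failed integration, solver
    abort) are reported with infinite cost.  Raises ``RuntimeError`` when
    no start converges.
    """
    for rep in REPORTERS:
        if not (data.records["reporter"] == rep).any():
            raise ValueError(f"dataset has no records for reporter {rep!r}")

    means = data.replicate_means()
    free = config.free_names
    starts = lhs_sample({n: config.bounds[n] for n in free}, config.n_starts, config.seed)
    log_lo = np.log10([config.bounds[n][0] for n in free])
    log_hi = np.log10([config.bounds[n][1] for n in free])

    def build_params(theta_log: np.ndarray) -> KineticParameters:
        vals = dict(config.fixed)
        vals.update({n: 10.0**v for n, v in zip(free, theta_log)})
        vals["hill_n"] = config.hill_n
        return KineticParameters.from_dict(vals)

    n_res = len(means)

    def resid(theta_log: np.ndarray) -> np.ndarray:
        try:
            r, _ = _residuals_for_params(
                build_params(theta_log), means, config.sim_rtol, config.sim_atol
            )
            if not np.all(np.isfinite(r)):
                raise IntegrationError("non-finite residuals")
            return r
        except (SteadyStateError, IntegrationError):
            return np.full(n_res, 1e6)

    results: list[FitResult] = []
    for i, start in enumerate(starts):
        theta0 = np.log10(start)
        try:
            sol = least_squares(
                resid,
                theta0,
                bounds=(log_lo, log_hi),
                method="trf",
                xtol=config.xtol,
                ftol=config.ftol,
                max_nfev=config.max_nfev,
            )
            params = build_params(sol.x)
            r, omap = _residuals_for_params(
                params, means, config.sim_rtol, config.sim_atol
            )
            cost = float(np.dot(r, r))
            converged = bool(sol.success) and np.isfinite(cost) and cost < 1e11
            results.append(
                FitResult(params, omap, cost if converged else float("inf"),
                          converged, i, message=str(sol.message))
            )
        except (SteadyStateError, IntegrationError, ValueError) as exc:
            results.append(
                FitResult(
                    build_params(theta0),
                    ObservableMap(),
                    float("inf"),
                    False,
                    i,
                    message=f"start failed: {exc}",
                )
            )

    if not any(r.converged for r in results):
        diag = "; ".join(f"start {r.start_index}: {r.message}" for r in results[:10])
        raise RuntimeError(f"no converged starts out of {len(results)} ({diag})")

    results.sort(key=FitResult.sort_key)
    for rank, r in enumerate(results):
        r.rank = rank
    return results


def minimal_cost_family(results: list[FitResult], rel_tol: float = 1e-6) -> list[FitResult]:
    """Converged results within ``rel_tol`` relative cost of the minimum."""
    conv = [r for r in results if r.converged and math.isfinite(r.cost)]
    if not conv:
        return []
    cmin = min(r.cost for r in conv)
    span = rel_tol * max(cmin, 1e-300)
    return [r for r in conv if r.cost - cmin <= span]


def select_from_family(
    family: list[FitResult], seed: int | None = None
) -> FitResult:
    """Pick a representative: lowest rank, or seeded random choice."""
    if not family:
        raise ValueError("empty minimal-cost family")
    ordered = sorted(family, key=FitResult.sort_key)
    if seed is None:
        return ordered[0]
    rng = np.random.default_rng(seed)
    return ordered[int(rng.integers(len(ordered)))]
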