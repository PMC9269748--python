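"""Kinetic model of cisplatin-induced p53 signaling.

The model tracks ten species: DNA damage (``DD``), p53 mRNA and the two p53
protein forms (unphosphorylated ``P53`` and phosphorylated ``P53p``), and
mRNA/protein pairs for the three transcriptional targets MDM2, p21 (CDKN1A)
and BTG2.  Cisplatin enters as an exponentially decaying effective stress
``S(t)`` that feeds DNA damage; damage drives p53 phosphorylation;
phosphorylated p53 induces target transcription through a Hill function
(exponent 4 by default, reflecting tetrameric DNA binding) and stimulates
repair.  MDM2 protein closes a second negative feedback by degrading both
p53 forms.

All concentrations are in arbitrary units and time is in hours; absolute
scale is unidentifiable from min-max-normalized reporter data and is carried
by the affine observable maps instead.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import warnings

from scipy.integrate import ODEintWarning, odeint
from scipy.optimize import brentq, fsolve

__all__ = [
    "SPECIES",
    "RATE_PARAM_NAMES",
    "KineticParameters",
    "ModelState",
    "ObservableMap",
    "StimulusSchedule",
    "Trajectory",
    "IntegrationError",
    "SteadyStateError",
    "effective_stimulus",
    "rhs",
    "simulate",
    "observe",
    "steady_state",
    "disrupt_feedback",
]

#: Canonical species ordering used for all state vectors.
SPECIES = (
    "DD",
    "P53_RNA",
    "P53",
    "P53p",
    "MDM2_RNA",
    "MDM2",
    "P21_RNA",
    "P21",
    "BTG2_RNA",
    "BTG2",
)

#: Kinetic parameter names in canonical order (excludes the structural
#: switch ``hill_n``).
RATE_PARAM_NAMES = (
    "ks_DD",
    "kd_DD",
    "tau",
    "EC1",
    "EC2",
    "EC3",
    "ks_p53_RNA",
    "kd_p53_RNA",
    "ks_p53",
    "kd_p53",
    "kp",
    "kdp",
    "kd_p53p",
    "kd_p53_mdm2",
    "kd_p53p_mdm2",
    "ks_mdm2_RNA",
    "ks_mdm2_p53p",
    "Km_mdm2",
    "kd_mdm2_RNA",
    "ks_mdm2",
    "kd_mdm2",
    "ks_p21_RNA",
    "ks_p21_p53p",
    "Km_p21",
    "kd_p21_RNA",
    "ks_p21",
    "kd_p21",
    "ks_btg2_RNA",
    "ks_btg2_p53p",
    "Km_btg2",
    "kd_btg2_RNA",
    "ks_btg2",
    "kd_btg2",
)

REPORTERS = ("p53", "mdm2", "p21", "btg2")

#: Reporter name -> species summed by its observable function.
_REPORTER_SPECIES = {
    "p53": ("P53", "P53p"),
    "mdm2": ("MDM2",),
    "p21": ("P21",),
    "btg2": ("BTG2",),
}

#: Names of mRNA species per gene symbol, for cohort readouts.
GENE_TO_MRNA = {
    "TP53": "P53_RNA",
    "MDM2": "MDM2_RNA",
    "CDKN1A": "P21_RNA",
    "BTG2": "BTG2_RNA",
}


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces non-finite states."""

    def __init__(self, message: str, params: "KineticParameters | None" = None):
        super().__init__(message)
        self.params = params


class SteadyStateError(RuntimeError):
    """Raised when no steady state can be found for a parameter set."""


@dataclass(frozen=True)
class KineticParameters:
    """Full set of rate constants for the DDR model.

    ``hill_n`` is a structural switch (4 for tetrameric p53-p DNA binding,
    1 for the monomeric variant), not a fitted parameter.
    """

    ks_DD: float
    kd_DD: float
    tau: float
    EC1: float
    EC2: float
    EC3: float
    ks_p53_RNA: float
    kd_p53_RNA: float
    ks_p53: float
    kd_p53: float
    kp: float
    kdp: float
    kd_p53p: float
    kd_p53_mdm2: float
    kd_p53p_mdm2: float
    ks_mdm2_RNA: float
    ks_mdm2_p53p: float
    Km_mdm2: float
    kd_mdm2_RNA: float
    ks_mdm2: float
    kd_mdm2: float
    ks_p21_RNA: float
    ks_p21_p53p: float
    Km_p21: float
    kd_p21_RNA: float
    ks_p21: float
    kd_p21: float
    ks_btg2_RNA: float
    ks_btg2_p53p: float
    Km_btg2: float
    kd_btg2_RNA: float
    ks_btg2: float
    kd_btg2: float
    hill_n: int = 4

    def __post_init__(self):
        for name in RATE_PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} is not finite: {v}")
        if self.hill_n not in (1, 4):
            raise ValueError(f"hill_n must be 1 or 4, got {self.hill_n}")

    def as_array(self) -> np.ndarray:
        """Rate parameters as a float vector in canonical order."""
        return np.array([getattr(self, n) for n in RATE_PARAM_NAMES], float)

    def replace(self, **changes) -> "KineticParameters":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_array(cls, values: Sequence[float], hill_n: int = 4) -> "KineticParameters":
        if len(values) != len(RATE_PARAM_NAMES):
            raise ValueError(
                f"expected {len(RATE_PARAM_NAMES)} values, got {len(values)}"
            )
        kw = {n: float(v) for n, v in zip(RATE_PARAM_NAMES, values)}
        return cls(hill_n=hill_n, **kw)

    def to_dict(self) -> dict:
        d = {n: getattr(self, n) for n in RATE_PARAM_NAMES}
        d["hill_n"] = self.hill_n
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "KineticParameters":
        kw = {n: float(d[n]) for n in RATE_PARAM_NAMES}
        return cls(hill_n=int(d.get("hill_n", 4)), **kw)

    def to_json(self, path, fixed: Iterable[str] = ("EC1",)) -> None:
        """Serialize as a flat name->value JSON map with a ``fixed`` list."""
        payload = self.to_dict()
        payload["fixed"] = sorted(fixed)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> tuple["KineticParameters", list[str]]:
        with open(path) as fh:
            payload = json.load(fh)
        fixed = list(payload.pop("fixed", ["EC1"]))
        return cls.from_dict(payload), fixed

    def ec_for_index(self, concentration_index: int) -> float:
        """Effective concentration for applied dose index 1/2/3 (1, 2.5, 5 uM)."""
        try:
            return {1: self.EC1, 2: self.EC2, 3: self.EC3}[concentration_index]
        except KeyError:
            raise ValueError(f"concentration index must be 1, 2 or 3, got {concentration_index}")


@dataclass(frozen=True)
class ModelState:
    """One point in the 10-dimensional model state space."""

    DD: float
    P53_RNA: float
    P53: float
    P53p: float
    MDM2_RNA: float
    MDM2: float
    P21_RNA: float
    P21: float
    BTG2_RNA: float
    BTG2: float

    def __post_init__(self):
        for name in SPECIES:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"state entry {name} is not finite")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SPECIES], float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ModelState":
        return cls(**{n: float(v) for n, v in zip(SPECIES, values)})

    def min_value(self) -> float:
        return float(min(getattr(self, n) for n in SPECIES))


@dataclass(frozen=True)
class ObservableMap:
    """Affine maps from model species to GFP reporter intensities.

    The p53 observable is ``scaling * (P53 + P53p) + offset`` because the
    GFP tag is carried by both phosphorylation states; the other reporters
    map their protein species directly.
    """

    scaling: Mapping[str, float] = field(
        default_factory=lambda: {r: 1.0 for r in REPORTERS}
    )
    offset: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.0 for r in REPORTERS}
    )

    def __post_init__(self):
        if set(self.scaling) != set(REPORTERS) or set(self.offset) != set(REPORTERS):
            raise ValueError(f"observable map must define exactly reporters {REPORTERS}")
        for r, s in self.scaling.items():
            if not s > 0:
                raise ValueError(f"scaling for {r} must be positive, got {s}")

    def to_dict(self) -> dict:
        return {
            "scaling": dict(self.scaling),
            "offset": dict(self.offset),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ObservableMap":
        return cls(scaling=dict(d["scaling"]), offset=dict(d["offset"]))


@dataclass(frozen=True)
class StimulusSchedule:
    """Exponentially decaying effective cisplatin stress.

    ``S(t) = EC * exp(-tau * (t - exposure_start))`` for t >= exposure_start,
    0 before.
    """

    EC: float
    tau: float
    exposure_start: float = 0.0

    def __post_init__(self):
        if self.EC < 0:
            raise ValueError(f"EC must be >= 0, got {self.EC}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")


@dataclass
class Trajectory:
    """Solution of the model on a time grid, optionally with observables."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 10), columns in SPECIES order
    observables: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (self.times.size, len(SPECIES)):
            raise ValueError("states must have one row per time point")

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    def to_tidy(self):
        """Tidy records: (time, species, value), plus observable rows
        (time, reporter, observable_value) when observables are attached."""
        import pandas as pd

        rows = [
            {"time": t, "species": sp, "value": self.states[i, j]}
            for i, t in enumerate(self.times)
            for j, sp in enumerate(SPECIES)
        ]
        df = pd.DataFrame(rows)
        if self.observables is not None:
            obs = pd.DataFrame(
                [
                    {"time": t, "reporter": rep, "observable_value": v}
                    for rep, vals in self.observables.items()
                    for t, v in zip(self.times, vals)
                ]
            )
            df = pd.concat([df, obs], ignore_index=True)
        return df

    def to_tsv(self, path) -> None:
        self.to_tidy().to_csv(path, sep="\t", index=False)


def effective_stimulus(schedule: StimulusSchedule, t) -> float | np.ndarray:
    """Effective cisplatin stress at time ``t`` (hours)."""
    t = np.asarray(t, float)
    dt = t - schedule.exposure_start
    out = np.where(dt >= 0, schedule.EC * np.exp(-schedule.tau * np.maximum(dt, 0.0)), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def _rhs_raw(y: np.ndarray, p: "KineticParameters", s: float) -> np.ndarray:
    """Time derivatives of the 10 species; ``s`` is the stress value.

    The Hill base uses max(P53p, 0): transient negative undershoots from
    perturbed parameter sets must not raise complex powers.
    """
    (dd, p53r, p53, p53p, m2r, m2, p21r, p21, btr, bt) = y
    n = p.hill_n
    ph = p53p if p53p > 0.0 else 0.0
    phn = ph**n

    h_m2 = phn / (p.Km_mdm2**n + phn)
    h_p21 = phn / (p.Km_p21**n + phn)
    h_bt = phn / (p.Km_btg2**n + phn)

    return np.array(
        [
            p.ks_DD - p.kd_DD * dd * p53p + s,
            p.ks_p53_RNA - p.kd_p53_RNA * p53r,
            p.ks_p53 * p53r
            + p.kdp * p53p
            - p.kp * p53 * dd
            - p.kd_p53 * p53
            - p.kd_p53_mdm2 * p53 * m2,
            p.kp * p53 * dd
            - p.kdp * p53p
            - p.kd_p53p * p53p
            - p.kd_p53p_mdm2 * p53p * m2,
            p.ks_mdm2_RNA + p.ks_mdm2_p53p * h_m2 - p.kd_mdm2_RNA * m2r,
            p.ks_mdm2 * m2r - p.kd_mdm2 * m2,
            p.ks_p21_RNA + p.ks_p21_p53p * h_p21 - p.kd_p21_RNA * p21r,
            p.ks_p21 * p21r - p.kd_p21 * p21,
            p.ks_btg2_RNA + p.ks_btg2_p53p * h_bt - p.kd_btg2_RNA * btr,
            p.ks_btg2 * btr - p.kd_btg2 * bt,
        ]
    )


def _hill_deriv(p53p: float, km: float, n: int) -> float:
    """d/dP53p of the Hill activation term, with the clipped base."""
    if p53p <= 0.0:
        return 0.0
    denom = km**n + p53p**n
    return n * km**n * p53p ** (n - 1) / (denom * denom)


def _jac_raw(y: np.ndarray, p: "KineticParameters") -> np.ndarray:
    """Analytic Jacobian of :func:`_rhs_raw` (stress-independent)."""
    (dd, _p53r, p53, p53p, _m2r, m2, _p21r, _p21, _btr, _bt) = y
    J = np.zeros((10, 10))
    # DD
    J[0, 0] = -p.kd_DD * p53p
    J[0, 3] = -p.kd_DD * dd
    # P53_RNA
    J[1, 1] = -p.kd_p53_RNA
    # P53
    J[2, 0] = -p.kp * p53
    J[2, 1] = p.ks_p53
    J[2, 2] = -p.kp * dd - p.kd_p53 - p.kd_p53_mdm2 * m2
    J[2, 3] = p.kdp
    J[2, 5] = -p.kd_p53_mdm2 * p53
    # P53p
    J[3, 0] = p.kp * p53
    J[3, 2] = p.kp * dd
    J[3, 3] = -p.kdp - p.kd_p53p - p.kd_p53p_mdm2 * m2
    J[3, 5] = -p.kd_p53p_mdm2 * p53p
    # target branches: rows (rna, prot) = (4,5), (6,7), (8,9)
    n = p.hill_n
    for i, gene in ((4, "mdm2"), (6, "p21"), (8, "btg2")):
        J[i, 3] = getattr(p, f"ks_{gene}_p53p") * _hill_deriv(
            p53p, getattr(p, f"Km_{gene}"), n
        )
        J[i, i] = -getattr(p, f"kd_{gene}_RNA")
        J[i + 1, i] = getattr(p, f"ks_{gene}")
        J[i + 1, i + 1] = -getattr(p, f"kd_{gene}")
    return J


def rhs(state: ModelState, params: KineticParameters, stimulus_value: float) -> np.ndarray:
    """Evaluate the model right-hand side at one state.

    Returns the 10 time derivatives in :data:`SPECIES` order.
    """
    if not math.isfinite(stimulus_value):
        raise ValueError("stimulus value must be finite")
    return _rhs_raw(state.as_array(), params, stimulus_value)


def simulate(
    params: KineticParameters,
    initial: ModelState,
    schedule: StimulusSchedule,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model over ``t_grid`` with stress from ``schedule``.

    Uses a stiff-capable variable-step solver (LSODA); defaults resolve the
    trajectory well beyond the 0.1 % accuracy contract.
    """
    t_grid = np.asarray(t_grid, float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at or after 0")

    y0 = initial.as_array()
    t0 = min(0.0, float(t_grid[0]))
    ec, tau_s, start = schedule.EC, schedule.tau, schedule.exposure_start

    def f(t, y):
        s = ec * math.exp(-tau_s * (t - start)) if t >= start else 0.0
        return _rhs_raw(y, params, s)

    def jac(t, y):
        return _jac_raw(y, params)

    t_ode = t_grid if t_grid[0] == t0 else np.concatenate(([t0], t_grid))
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", ODEintWarning)
        y, info = odeint(
            f,
            y0,
            t_ode,
            Dfun=jac,
            rtol=rtol,
            atol=atol,
            tfirst=True,
            full_output=True,
            mxstep=100000,
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(y)):
        raise IntegrationError(
            f"integration failed: {info['message']}", params=params
        )
    if t_ode is not t_grid:
        y = y[1:]
    return Trajectory(times=t_grid, states=y)


def observe(traj: Trajectory, omap: ObservableMap, reporters: Sequence[str] = REPORTERS) -> dict[str, np.ndarray]:
    """Map a trajectory to GFP reporter intensities.

    The result is also stored on ``traj.observables``.
    """
    out: dict[str, np.ndarray] = {}
    for rep in reporters:
        if rep not in _REPORTER_SPECIES:
            raise KeyError(f"unknown reporter {rep!r}")
        if rep not in omap.scaling:
            raise KeyError(f"observable map missing reporter {rep!r}")
        total = sum(traj.species(sp) for sp in _REPORTER_SPECIES[rep])
        out[rep] = omap.scaling[rep] * total + omap.offset[rep]
    traj.observables = out
    return out


def _target_branch_steady(p: KineticParameters, p53p: float, gene: str):
    """Closed-form mRNA/protein steady state for one Hill-induced target."""
    n = p.hill_n
    ph = max(p53p, 0.0)
    ks_rna = getattr(p, f"ks_{gene}_RNA")
    ks_act = getattr(p, f"ks_{gene}_p53p")
    km = getattr(p, f"Km_{gene}")
    kd_rna = getattr(p, f"kd_{gene}_RNA")
    ks_prot = getattr(p, f"ks_{gene}")
    kd_prot = getattr(p, f"kd_{gene}")
    hill = ph**n / (km**n + ph**n) if (km**n + ph**n) != 0 else 0.0
    rna = (ks_rna + ks_act * hill) / kd_rna
    prot = ks_prot * rna / kd_prot
    return rna, prot


def _cascade_state(p: KineticParameters, p53p: float) -> np.ndarray:
    """Full state implied by a candidate P53p via the closed-form cascade."""
    p53_rna = p.ks_p53_RNA / p.kd_p53_RNA
    m2r, m2 = _target_branch_steady(p, p53p, "mdm2")
    p21r, p21 = _target_branch_steady(p, p53p, "p21")
    btr, bt = _target_branch_steady(p, p53p, "btg2")
    dd = p.ks_DD / (p.kd_DD * p53p)
    # P53 from the P53p balance: kp*P53*DD = (kdp + kd_p53p + kd_p53p_mdm2*M)*P53p
    p53 = (p.kdp + p.kd_p53p + p.kd_p53p_mdm2 * m2) * p53p / (p.kp * dd)
    return np.array([dd, p53_rna, p53, p53p, m2r, m2, p21r, p21, btr, bt])


def _p53p_residual(p: KineticParameters, p53p: float) -> float:
    """Residual of the P53 balance with all other species eliminated."""
    y = _cascade_state(p, p53p)
    return float(_rhs_raw(y, p, 0.0)[2])


def steady_state(
    params: KineticParameters,
    residual_tol: float = 1e-8,
    _allow_integration_fallback: bool = True,
) -> ModelState:
    """Solve the stress-free (S = 0) steady state.

    Strategy: eliminate every species analytically in terms of P53p (p53
    mRNA, DD, the three target branches, and P53 through the P53p balance),
    then root-find the remaining scalar P53 balance by bracketing.  If the
    scalar reduction is inapplicable (e.g. parameters perturbed to zero or
    negative values), fall back to a multidimensional root find seeded from
    small positive states and finally to long-time integration.

    Raises :class:`SteadyStateError` if no root passes the residual
    tolerance.  A root with negative entries is returned as-is; callers that
    must filter such donors check :meth:`ModelState.min_value`.
    """
    # Scalar bracketing path, valid for strictly positive parameters.
    pvec = params.as_array()
    if np.all(pvec > 0):
        try:
            lo, hi = 1e-12, 1.0
            flo = _p53p_residual(params, lo)
            fhi = _p53p_residual(params, hi)
            # Expand the bracket geometrically; the residual is positive for
            # P53p -> 0+ and eventually negative (cubic decay terms win).
            n_expand = 0
            while flo * fhi > 0 and n_expand < 200:
                hi *= 2.0
                fhi = _p53p_residual(params, hi)
                n_expand += 1
            if flo * fhi <= 0:
                root = brentq(
                    lambda x: _p53p_residual(params, x), lo, hi, xtol=1e-14, rtol=1e-14
                )
                y = _cascade_state(params, root)
                if np.max(np.abs(_rhs_raw(y, params, 0.0))) <= residual_tol:
                    return ModelState.from_array(y)
        except (ValueError, ZeroDivisionError, FloatingPointError, OverflowError):
            pass

    # Multidimensional root find from a few heuristic seeds.
    seeds = [np.full(len(SPECIES), v) for v in (0.1, 1.0, 10.0)]
    if np.all(pvec > 0):
        with np.errstate(all="ignore"):
            for guess in (1e-3, 1e-1, 1.0):
                try:
                    y = _cascade_state(params, guess)
                    if np.all(np.isfinite(y)):
                        seeds.insert(0, y)
                except (ZeroDivisionError, FloatingPointError, OverflowError):
                    pass
    for seed in seeds:
        with np.errstate(all="ignore"):
            y, info, ier, _ = fsolve(
                lambda v: _rhs_raw(v, params, 0.0), seed, full_output=True, xtol=1e-12
            )
        if ier == 1 and np.all(np.isfinite(y)):
            if np.max(np.abs(_rhs_raw(y, params, 0.0))) <= residual_tol:
                return ModelState.from_array(y)

    # Last resort: relax the system by long-time integration.
    if _allow_integration_fallback:
        try:
            traj = simulate(
                params,
                ModelState.from_array(np.full(len(SPECIES), 1.0)),
                StimulusSchedule(EC=0.0, tau=0.0),
                np.array([0.0, 1e5]),
            )
            y = traj.states[-1]
            with np.errstate(all="ignore"):
                y2, info, ier, _ = fsolve(
                    lambda v: _rhs_raw(v, params, 0.0), y, full_output=True, xtol=1e-12
                )
            if ier == 1 and np.max(np.abs(_rhs_raw(y2, params, 0.0))) <= residual_tol:
                return ModelState.from_array(y2)
        except (IntegrationError, ValueError):
            pass

    raise SteadyStateError("no steady state found for the given parameter set")


def disrupt_feedback(params: KineticParameters, efficiency: float) -> KineticParameters:
    """Scale the MDM2-dependent p53 degradation rates by ``efficiency``.

    ``efficiency = 0.2`` models 20 % residual feedback (strong disruption,
    as with Nutlin); ``efficiency = 1`` is the intact model.
    """
    if not 0 < efficiency <= 1:
        raise ValueError(f"efficiency must be in (0, 1], got {efficiency}")
    return params.replace(
        kd_p53_mdm2=params.kd_p53_mdm2 * efficiency,
        kd_p53p_mdm2=params.kd_p53p_mdm2 * efficiency,
    )
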