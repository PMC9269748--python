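"""Virtual donor cohorts by parameter perturbation.

A virtual donor is the base (calibrated) parameter set with independent
Gaussian noise added to every free parameter: p -> p + x with
x ~ N(0, (c*p)^2), where the variability factor ``c`` scales donor-to-donor
spread.  Each donor is simulated from its own stress-free steady state;
basal readouts are the steady-state mRNA levels and treated readouts are
the mRNA levels 8 and 24 h after applying the effective stress for the
nominal 3.3 uM cisplatin dose (interpolated between the calibrated
effective concentrations).  Donors whose steady state has a negative
species, or for which the solver fails, are removed and counted.
Mechanism scans multiply targeted rate constants by a factor ``r`` before
perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from p53ddr.model import (
    GENE_TO_MRNA,
    RATE_PARAM_NAMES,
    IntegrationError,
    KineticParameters,
    ModelState,
    SteadyStateError,
    StimulusSchedule,
    simulate,
    steady_state,
)

__all__ = [
    "MECHANISMS",
    "CohortConfig",
    "VirtualDonor",
    "CohortSet",
    "perturb_parameters",
    "apply_r_factor",
    "stress_at_nominal",
    "simulate_donor",
    "add_measurement_noise",
    "generate_cohorts",
]

#: Mechanism name -> parameters scaled by the r-factor.
MECHANISMS = {
    "dephosphorylation": ("kdp",),
    "mdm2_synthesis": ("ks_mdm2_p53p",),
    "mdm2_feedback": ("kd_p53_mdm2", "kd_p53p_mdm2"),
}

GENES = tuple(GENE_TO_MRNA)  # TP53, MDM2, CDKN1A, BTG2

#: Applied cisplatin doses (uM) mapped onto the calibrated EC parameters.
APPLIED_DOSES = (1.0, 2.5, 5.0)


@dataclass
class CohortConfig:
    """Study design for virtual-cohort generation.

    Defaults follow the reference design: 1000 cohorts of 50 donors,
    variability factor c = 0.2 from the study grid {0.001, 0.01, 0.1, 0.2},
    8/24-h readouts at a nominal 3.3 uM dose, and log-normal measurement
    noise with sigma = 0.125 on every readout.
    """

    c: float = 0.2
    n_cohorts: int = 1000
    cohort_size: int = 50
    readout_times: tuple[float, ...] = (8.0, 24.0)
    nominal_concentration: float = 3.3
    sigma: float = 0.125
    r_factors: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    fixed: tuple[str, ...] = ("EC1",)
    sim_rtol: float = 1e-7
    sim_atol: float = 1e-9

    def __post_init__(self):
        if self.c < 0:
            raise ValueError("variability factor c must be >= 0")
        if self.cohort_size < 2:
            raise ValueError("cohort_size must be >= 2")
        if any(t <= 0 for t in self.readout_times):
            raise ValueError("readout times must be > 0")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        for mech in self.r_factors:
            if mech not in MECHANISMS:
                raise ValueError(f"unknown mechanism {mech!r}; choose from {sorted(MECHANISMS)}")


@dataclass
class VirtualDonor:
    """One perturbed parameter set with its steady state and readouts.

    ``readouts`` maps (gene, condition, time_h) -> mRNA level in model
    units; basal readouts repeat the steady-state value at both times.
    Invalid donors (negative steady state or solver failure) carry no
    readouts.
    """

    params: KineticParameters | None
    steady: ModelState | None
    readouts: dict[tuple[str, str, float], float]
    valid: bool
    failure: str = ""


@dataclass
class CohortSet:
    """Cohorts of valid donors plus removal bookkeeping and provenance."""

    cohorts: list[list[VirtualDonor]]
    n_generated: int
    n_removed: int
    removal_reasons: dict[str, int]
    base_params: KineticParameters | None
    config: CohortConfig | None

    @property
    def n_valid(self) -> int:
        return sum(len(c) for c in self.cohorts)

    @property
    def removal_fraction(self) -> float:
        return self.n_removed / self.n_generated if self.n_generated else 0.0

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortSet":
        """Rebuild a readout-only cohort set from its tidy table.

        Donors carry readouts but no parameter sets or steady states;
        sufficient for correlation analysis.
        """
        cohorts: list[list[VirtualDonor]] = []
        for _, cohort_df in df.groupby("cohort"):
            cohort = []
            for _, donor_df in cohort_df.groupby("donor"):
                readouts = {
                    (r.gene, r.condition, float(r.time_h)): float(r.value)
                    for r in donor_df.itertuples()
                }
                cohort.append(VirtualDonor(None, None, readouts, bool(donor_df["valid"].all())))
            cohorts.append(cohort)
        n_valid = sum(len(c) for c in cohorts)
        return cls(
            cohorts=cohorts,
            n_generated=n_valid,
            n_removed=0,
            removal_reasons={},
            base_params=None,
            config=None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table: cohort, donor, gene, condition, time_h, value."""
        rows = []
        for ci, cohort in enumerate(self.cohorts):
            for di, donor in enumerate(cohort):
                for (gene, cond, t), v in donor.readouts.items():
                    rows.append((ci, di, gene, cond, t, v, donor.valid))
        return pd.DataFrame(
            rows, columns=["cohort", "donor", "gene", "condition", "time_h", "value", "valid"]
        )


def perturb_parameters(
    base: KineticParameters,
    c: float,
    n: int,
    seed: int | np.random.Generator,
    fixed: tuple[str, ...] = ("EC1",),
) -> list[KineticParameters]:
    """Draw ``n`` perturbed parameter sets: p -> p + N(0, (c*p)^2).

    Draws are independent per parameter and per donor.  Parameters listed
    in ``fixed`` and the structural ``hill_n`` are left untouched.
    Negative draws are retained; pathological sets are filtered later via
    their steady states.
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base_vec = base.as_array()
    free_mask = np.array([name not in fixed for name in RATE_PARAM_NAMES])
    sigma = c * np.abs(base_vec) * free_mask
    draws = rng.normal(loc=base_vec, scale=sigma, size=(n, base_vec.size))
    return [KineticParameters.from_array(row, hill_n=base.hill_n) for row in draws]


def apply_r_factor(params: KineticParameters, mechanism: str, r: float) -> KineticParameters:
    """Scale the mechanism's rate constant(s) by ``r`` (before perturbation)."""
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}; choose from {sorted(MECHANISMS)}")
    if not r > 0:
        raise ValueError(f"r must be > 0, got {r}")
    changes = {name: getattr(params, name) * r for name in MECHANISMS[mechanism]}
    return params.replace(**changes)


def stress_at_nominal(ec_by_applied: dict[float, float], nominal: float) -> float:
    """Effective stress at a nominal applied dose by linear interpolation.

    ``ec_by_applied`` maps applied concentrations (uM) to calibrated
    effective concentrations; no extrapolation outside the calibrated
    range.
    """
    doses = np.array(sorted(ec_by_applied), float)
    ecs = np.array([ec_by_applied[d] for d in doses], float)
    if not doses[0] <= nominal <= doses[-1]:
        raise ValueError(
            f"nominal dose {nominal} outside calibrated range [{doses[0]}, {doses[-1]}]"
        )
    return float(np.interp(nominal, doses, ecs))


def nominal_stress_for(params: KineticParameters, nominal: float = 3.3) -> float:
    """Interpolated effective stress for ``nominal`` uM from EC1..EC3."""
    ec_map = dict(zip(APPLIED_DOSES, (params.EC1, params.EC2, params.EC3)))
    return stress_at_nominal(ec_map, nominal)


def simulate_donor(
    params: KineticParameters,
    stress_ec: float,
    times: tuple[float, ...] = (8.0, 24.0),
    sim_rtol: float = 1e-7,
    sim_atol: float = 1e-9,
) -> VirtualDonor:
    """Solve one donor's steady state and treated mRNA readouts.

    Never raises: solver failures and negative steady states are recorded
    on the returned donor's validity flag.
    """
    try:
        ss = steady_state(params)
    except SteadyStateError as exc:
        return VirtualDonor(params, None, {}, False, failure=f"steady-state: {exc}")
    if ss.min_value() < 0:
        return VirtualDonor(params, ss, {}, False, failure="negative steady state")

    t_grid = np.asarray(sorted(times), float)
    try:
        traj = simulate(
            params,
            ss,
            StimulusSchedule(EC=stress_ec, tau=params.tau),
            t_grid,
            rtol=sim_rtol,
            atol=sim_atol,
        )
    except IntegrationError as exc:
        return VirtualDonor(params, ss, {}, False, failure=f"integration: {exc}")

    readouts: dict[tuple[str, str, float], float] = {}
    for gene, species in GENE_TO_MRNA.items():
        basal = getattr(ss, species)
        for t in t_grid:
            readouts[(gene, "basal", float(t))] = basal
        treated = traj.species(species)
        for t, v in zip(t_grid, treated):
            readouts[(gene, "treated", float(t))] = float(v)
    return VirtualDonor(params, ss, readouts, True)


def add_measurement_noise(
    values: np.ndarray | float,
    sigma: float,
    seed: int | np.random.Generator,
) -> np.ndarray | float:
    """Log-normal measurement noise: ln(y') ~ N(ln y, sigma^2).

    ``sigma = 0`` is the identity.  Values must be positive when noise is
    applied.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    arr = np.asarray(values, float)
    if sigma == 0:
        return values
    if np.any(arr <= 0):
        raise ValueError("measurement noise requires positive values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = np.exp(rng.normal(np.log(arr), sigma))
    if np.isscalar(values) or arr.ndim == 0:
        return float(noisy)
    return noisy


def generate_cohorts(base: KineticParameters, config: CohortConfig) -> CohortSet:
    """Generate virtual-donor cohorts from a base parameter set.

    Order of operations: apply r-factors to the base set, then per donor
    perturb, solve the steady state, filter invalid donors, simulate the
    8/24-h readouts and add measurement noise.  One master seed spawns
    per-cohort and per-donor RNG substreams, so any cohort is reproducible
    independently of execution order.  Raises ``RuntimeError`` when more
    than half of a cohort's donors are invalid (degenerate regime).
    """
    scanned = base
    for mech, r in config.r_factors.items():
        scanned = apply_r_factor(scanned, mech, r)

    master = np.random.SeedSequence(config.seed)
    cohort_seeds = master.spawn(config.n_cohorts)

    cohorts: list[list[VirtualDonor]] = []
    n_removed = 0
    reasons: dict[str, int] = {"steady-state": 0, "negative steady state": 0, "integration": 0, "noise": 0}
    for cs in cohort_seeds:
        donor_seeds = cs.spawn(config.cohort_size)
        cohort: list[VirtualDonor] = []
        bad = 0
        for ds in donor_seeds:
            rng = np.random.default_rng(ds)
            pset = perturb_parameters(scanned, config.c, 1, rng, fixed=config.fixed)[0]
            stress = nominal_stress_for(pset, config.nominal_concentration)
            donor = simulate_donor(
                pset,
                stress,
                config.readout_times,
                sim_rtol=config.sim_rtol,
                sim_atol=config.sim_atol,
            )
            if donor.valid and config.sigma > 0:
                keys = sorted(donor.readouts)
                clean = np.array([donor.readouts[k] for k in keys])
                if np.any(clean <= 0):
                    donor = VirtualDonor(
                        donor.params, donor.steady, {}, False, failure="noise: non-positive readout"
                    )
                else:
                    noisy = add_measurement_noise(clean, config.sigma, rng)
                    donor.readouts = dict(zip(keys, noisy))
            if donor.valid:
                cohort.append(donor)
            else:
                bad += 1
                key = donor.failure.split(":")[0]
                reasons[key] = reasons.get(key, 0) + 1
        if bad > config.cohort_size / 2:
            raise RuntimeError(
                f"degenerate regime: {bad}/{config.cohort_size} invalid donors in one cohort"
            )
        n_removed += bad
        cohorts.append(cohort)

    return CohortSet(
        cohorts=cohorts,
        n_generated=config.n_cohorts * config.cohort_size,
        n_removed=n_removed,
        removal_reasons={k: v for k, v in reasons.items() if v},
        base_params=base,
        config=config,
    )
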