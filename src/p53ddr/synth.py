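"""Synthetic data generators.

Every generator is deterministic under its seed and returns its ground
truth next to the data, so downstream modules can be exercised end-to-end
without any external dataset:

* GFP reporter time courses simulated from a known parameter set, with
  per-plate background and multiplicative measurement noise (emulating
  live-cell reporter imaging of p53/MDM2/p21/BTG2 under 1, 2.5 and 5 uM
  cisplatin);
* single-cell intensity samples (log-normal, motivating geometric-mean
  aggregation);
* donor count matrices with configurable cross-gene correlation structure
  (including a negative TP53-MDM2 entry), three MDM2 probes, technical
  replicates, negative-binomial counting noise, low-library bait samples
  and high-zero filler genes to exercise both preprocessing filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from p53ddr.calibration import APPLIED_CONCENTRATIONS, GfpDataset
from p53ddr.counts import CountMatrix
from p53ddr.model import (
    REPORTERS,
    KineticParameters,
    ObservableMap,
    StimulusSchedule,
    observe,
    simulate,
    steady_state,
)
from p53ddr.params import DEFAULT_OBSERVABLE_MAP, DEFAULT_PARAMS

__all__ = [
    "GfpGeneratorConfig",
    "CountGeneratorConfig",
    "generate_gfp_dataset",
    "generate_raw_plate",
    "generate_single_cell_intensities",
    "generate_count_matrix",
]


@dataclass
class GfpGeneratorConfig:
    """Ground truth and noise model for synthetic GFP time courses."""

    params: KineticParameters = field(default_factory=lambda: DEFAULT_PARAMS)
    observable_map: ObservableMap = field(default_factory=lambda: DEFAULT_OBSERVABLE_MAP)
    replicates: int = 4
    time_grid: np.ndarray = field(default_factory=lambda: np.arange(1.0, 65.0, 1.5))
    noise_sd: float = 0.05  # multiplicative log-normal sd
    background_offset: float = 0.1  # raw-plate mode only
    background_drift: float = 0.002  # raw-plate intensity drift per hour
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _truth_curves(config: GfpGeneratorConfig) -> dict[str, dict[int, np.ndarray]]:
    """Noise-free observables per reporter and concentration index."""
    p = config.params
    ss = steady_state(p)
    curves: dict[str, dict[int, np.ndarray]] = {r: {} for r in REPORTERS}
    for ci in APPLIED_CONCENTRATIONS:
        traj = simulate(
            p, ss, StimulusSchedule(EC=p.ec_for_index(ci), tau=p.tau), config.time_grid
        )
        obs = observe(traj, config.observable_map)
        for rep in REPORTERS:
            curves[rep][ci] = obs[rep]
    return curves


def generate_gfp_dataset(config: GfpGeneratorConfig) -> tuple[GfpDataset, dict]:
    """Simulate a normalized multi-replicate GFP dataset plus ground truth.

    One reporter corresponds to one imaging plate, so min-max
    normalization runs per reporter over its three concentrations jointly.
    Replicates receive independent multiplicative log-normal noise; with
    ``noise_sd = 0`` the dataset equals the normalized truth exactly.
    """
    rng = np.random.default_rng(config.seed)
    curves = _truth_curves(config)

    normalized: dict[str, dict[int, np.ndarray]] = {}
    for rep in REPORTERS:
        pooled = np.concatenate([curves[rep][ci] for ci in APPLIED_CONCENTRATIONS])
        lo, hi = pooled.min(), pooled.max()
        if hi == lo:
            raise ValueError(f"flat ground-truth curve for reporter {rep}")
        normalized[rep] = {
            ci: (curves[rep][ci] - lo) / (hi - lo) for ci in APPLIED_CONCENTRATIONS
        }

    rows = []
    for rep in REPORTERS:
        for ci in APPLIED_CONCENTRATIONS:
            truth = normalized[rep][ci]
            for r in range(config.replicates):
                if config.noise_sd > 0:
                    noisy = truth * np.exp(
                        rng.normal(0.0, config.noise_sd, size=truth.size)
                    )
                    noisy = np.clip(noisy, -0.2, 1.2)
                else:
                    noisy = truth
                for t, v in zip(config.time_grid, noisy):
                    rows.append((rep, ci, r + 1, float(t), float(v)))
    dataset = GfpDataset(
        pd.DataFrame(
            rows,
            columns=["reporter", "concentration_index", "replicate", "time_h", "intensity"],
        )
    )
    truth_record = {
        "params": config.params,
        "observable_map": config.observable_map,
        "raw_curves": curves,
        "normalized_curves": normalized,
        "time_grid": config.time_grid,
    }
    return dataset, truth_record


def generate_raw_plate(config: GfpGeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Raw image-level plate table for the processing pipeline.

    One plate per reporter.  Treated wells carry the model observable on a
    plate background (offset plus linear drift); control (DMEM) wells
    carry background only.  Two technical-replicate images per well with
    independent multiplicative noise.  Columns match
    :func:`p53ddr.timecourse.process_plate`.
    """
    rng = np.random.default_rng(config.seed)
    curves = _truth_curves(config)
    conc_label = {ci: f"cisplatin_{APPLIED_CONCENTRATIONS[ci]}uM" for ci in APPLIED_CONCENTRATIONS}

    rows = []
    for rep in REPORTERS:
        plate = f"plate_{rep}"
        for biorep in range(1, config.replicates + 1):
            for ci in APPLIED_CONCENTRATIONS:
                treat = conc_label[ci]
                well = f"{rep}_{treat}_r{biorep}"
                for ti, t in enumerate(config.time_grid):
                    background = config.background_offset + config.background_drift * t
                    signal = background + curves[rep][ci][ti]
                    for image in (1, 2):
                        noise = (
                            np.exp(rng.normal(0.0, config.noise_sd))
                            if config.noise_sd > 0
                            else 1.0
                        )
                        rows.append(
                            (plate, well, treat, rep, biorep, float(t),
                             f"{well}_t{ti}_i{image}", signal * noise)
                        )
            # matched control well per biological replicate
            well = f"{rep}_DMEM_r{biorep}"
            for ti, t in enumerate(config.time_grid):
                background = config.background_offset + config.background_drift * t
                for image in (1, 2):
                    noise = (
                        np.exp(rng.normal(0.0, config.noise_sd))
                        if config.noise_sd > 0
                        else 1.0
                    )
                    rows.append(
                        (plate, well, "DMEM", rep, biorep, float(t),
                         f"{well}_t{ti}_i{image}", background * noise)
                    )
    raw = pd.DataFrame(
        rows,
        columns=["plate", "well", "treatment", "reporter", "replicate", "time_h",
                 "image", "image_geomean"],
    )
    return raw, {"curves": curves, "config": config}


def generate_single_cell_intensities(
    n_cells: int, mu: float = 0.0, sigma: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Log-normal single-cell GFP intensities; geometric mean -> exp(mu)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(mu, sigma, size=n_cells))


CORE_GENES = ("TP53", "MDM2", "CDKN1A", "BTG2")


def _default_correlation() -> np.ndarray:
    """Default donor-level latent correlation among the four core genes.

    Mimics the observed donor structure: weak positive coupling of TP53
    with CDKN1A and BTG2, and a negative TP53-MDM2 entry.
    """
    # order: TP53, MDM2, CDKN1A, BTG2
    return np.array(
        [
            [1.0, -0.3, 0.25, 0.25],
            [-0.3, 1.0, 0.0, 0.0],
            [0.25, 0.0, 1.0, 0.2],
            [0.25, 0.0, 0.2, 1.0],
        ]
    )


@dataclass
class CountGeneratorConfig:
    """Design of the synthetic donor count matrix.

    Donor-level variability lives in a correlated log-normal latent layer
    (so the cross-gene correlation structure, including a negative
    TP53-MDM2 entry, is freely configurable); counts are negative binomial
    around sample-scaled latent means.
    """

    n_donors: int = 50
    n_filler: int = 46
    concentrations: tuple[float, ...] = (0.0, 0.1, 1.0, 3.3)
    times: tuple[float, ...] = (8.0, 24.0)
    tech_replicates: int = 3
    core_log_means: dict[str, float] = field(
        default_factory=lambda: {"TP53": 7.0, "MDM2": 6.5, "CDKN1A": 5.5, "BTG2": 6.0}
    )
    correlation: np.ndarray = field(default_factory=_default_correlation)
    donor_sd: float = 0.4
    induction: dict[str, float] = field(
        default_factory=lambda: {"TP53": 0.0, "MDM2": 1.0, "CDKN1A": 0.8, "BTG2": 0.9}
    )
    dispersion: float = 20.0  # NB size parameter; larger -> closer to Poisson
    sample_scale_sd: float = 0.15
    n_low_library: int = 4
    low_library_scale: float = 0.02
    n_high_zero_fillers: int = 8
    zero_inflation: float = 0.2
    filler_log_mean_range: tuple[float, float] = (7.0, 9.2)
    seed: int = 0

    def __post_init__(self):
        corr = np.asarray(self.correlation, float)
        if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
            raise ValueError("correlation must be a symmetric 4x4 matrix")
        if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def generate_count_matrix(config: CountGeneratorConfig) -> tuple[CountMatrix, dict]:
    """Draw a donor count matrix plus its latent ground truth.

    Returns the :class:`CountMatrix` (probes x samples with metadata) and a
    truth dict holding the per-donor latent log-means, the names of the
    low-library bait samples and of the high-zero filler probes.
    """
    rng = np.random.default_rng(config.seed)

    corr = np.asarray(config.correlation, float)
    # eigenvalue-clipped square root: tolerates exactly-singular inputs
    w, v = np.linalg.eigh(corr)
    L = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    z = rng.standard_normal((config.n_donors, 4))
    core_latent = z @ L.T * config.donor_sd  # donor x core-gene log deviations

    filler_names = [f"FILLER{i:03d}" for i in range(1, config.n_filler + 1)]
    filler_means = rng.uniform(*config.filler_log_mean_range, size=config.n_filler)
    filler_latent = rng.normal(0.0, 0.3, size=(config.n_donors, config.n_filler))
    high_zero = set(
        rng.choice(filler_names, size=min(config.n_high_zero_fillers, config.n_filler),
                   replace=False)
    )

    probes = ["TP53_p1", "MDM2_p1", "MDM2_p2", "MDM2_p3", "CDKN1A_p1", "BTG2_p1"]
    probe_gene = {
        "TP53_p1": "TP53", "MDM2_p1": "MDM2", "MDM2_p2": "MDM2", "MDM2_p3": "MDM2",
        "CDKN1A_p1": "CDKN1A", "BTG2_p1": "BTG2",
    }
    # small probe-specific offsets so the three MDM2 probes differ
    probe_offset = {p: off for p, off in zip(probes, (0.0, -0.2, 0.0, 0.2, 0.0, 0.0))}
    for name in filler_names:
        probes.append(name)
        probe_gene[name] = name

    conditions = [
        (conc, t) for conc in config.concentrations for t in config.times
    ]
    samples, meta_rows = [], []
    for d in range(config.n_donors):
        for conc, t in conditions:
            for r in range(1, config.tech_replicates + 1):
                sid = f"d{d:02d}_c{conc}_t{int(t)}_r{r}"
                samples.append(sid)
                meta_rows.append((sid, f"donor{d:02d}", "PHH", "cisplatin" if conc else "control", conc, t, r))
    metadata = pd.DataFrame(
        meta_rows,
        columns=["sample", "donor", "cell_type", "compound", "concentration_uM", "time_h", "replicate"],
    ).set_index("sample")

    scales = np.exp(rng.normal(0.0, config.sample_scale_sd, size=len(samples)))
    low_lib = set(rng.choice(samples, size=min(config.n_low_library, len(samples)), replace=False))
    for i, sid in enumerate(samples):
        if sid in low_lib:
            scales[i] *= config.low_library_scale

    counts = np.zeros((len(probes), len(samples)), dtype=np.int64)
    size = config.dispersion
    for j, sid in enumerate(samples):
        d = int(sid[1:3])
        conc = metadata.loc[sid, "concentration_uM"]
        means = np.empty(len(probes))
        for i, probe in enumerate(probes):
            gene = probe_gene[probe]
            if gene in CORE_GENES:
                gi = CORE_GENES.index(gene)
                eff = config.induction[gene] * conc / (conc + 1.0)
                log_mu = (
                    config.core_log_means[gene]
                    + probe_offset[probe]
                    + core_latent[d, gi]
                    + eff
                )
            else:
                fi = filler_names.index(gene)
                log_mu = filler_means[fi] + filler_latent[d, fi]
            means[i] = np.exp(log_mu)
        means *= scales[j]
        p_nb = size / (size + means)
        counts[:, j] = rng.negative_binomial(size, p_nb)
        for i, probe in enumerate(probes):
            if probe in high_zero and rng.random() < config.zero_inflation:
                counts[i, j] = 0

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=probes, columns=samples),
        probe_to_gene=pd.Series(probe_gene),
        metadata=metadata,
    )
    truth = {
        "core_latent": pd.DataFrame(
            core_latent, index=[f"donor{d:02d}" for d in range(config.n_donors)],
            columns=list(CORE_GENES),
        ),
        "low_library_samples": sorted(low_lib),
        "high_zero_probes": sorted(high_zero),
        "config": config,
    }
    return matrix, truth
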