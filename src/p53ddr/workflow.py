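"""End-to-end pipeline orchestration with reproducible provenance.

Stages (fixed order): synthetic GFP data, time-course processing, model
calibration, synthetic counts, count preprocessing, virtual cohorts,
correlation report.  Each enabled stage reads the previous stage's files,
so a run is resumable and each output carries a provenance sidecar naming
the config hash and master seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import p53ddr
from p53ddr.calibration import FitConfig, GfpDataset, fit, minimal_cost_family, select_from_family
from p53ddr.cohort import CohortConfig, CohortSet, generate_cohorts
from p53ddr.correlation import build_report, donor_table_from_counts
from p53ddr.counts import CountMatrix, preprocess
from p53ddr.model import KineticParameters
from p53ddr.params import DEFAULT_PARAMS
from p53ddr.synth import (
    CountGeneratorConfig,
    GfpGeneratorConfig,
    generate_count_matrix,
    generate_gfp_dataset,
    generate_raw_plate,
)
from p53ddr.timecourse import process_plate

__all__ = ["RunConfig", "run_pipeline", "write_provenance"]

STAGES = (
    "synth_gfp",
    "process_timecourse",
    "fit",
    "synth_counts",
    "preprocess_counts",
    "cohort",
    "correlate",
)

#: Stage -> the stage whose outputs it consumes (None = no dependency).
_DEPENDS = {
    "synth_gfp": None,
    "process_timecourse": "synth_gfp",
    "fit": "synth_gfp",
    "synth_counts": None,
    "preprocess_counts": "synth_counts",
    "cohort": None,  # falls back to packaged parameters when fit is disabled
    "correlate": "cohort",
}


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    fit_options: dict = field(default_factory=dict)
    cohort_options: dict = field(default_factory=dict)
    gfp_options: dict = field(default_factory=dict)
    counts_options: dict = field(default_factory=dict)
    correlate_options: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(out_path, config_digest: str, seed: int, **extra) -> None:
    """Sidecar JSON naming the config hash and seed of an output file."""
    payload = {
        "output": str(out_path),
        "config_sha256_16": config_digest,
        "seed": seed,
        "package_version": p53ddr.__version__,
        **extra,
    }
    side = Path(str(out_path) + ".provenance.json")
    side.write_text(json.dumps(payload, indent=2, default=str))


def _validate(config: RunConfig, out: Path) -> None:
    """Fail before execution when a disabled dependency's output is absent."""
    outputs = {
        "synth_gfp": out / "gfp_raw.tsv",
        "synth_counts": out / "counts.tsv",
        "cohort": out / "cohorts.tsv",
    }
    for stage in config.stages:
        dep = _DEPENDS.get(stage)
        if dep and dep not in config.stages and dep in outputs:
            if not outputs[dep].exists():
                raise ValueError(
                    f"stage {stage!r} needs output of disabled stage {dep!r} "
                    f"({outputs[dep]}), which does not exist"
                )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a run manifest.

    Identical config and seed reproduce all stochastic outputs bitwise.  A
    stage failure is recorded in the manifest and downstream stages are
    skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _validate(config, out)
    digest = config.digest()

    manifest: dict = {
        "config_sha256_16": digest,
        "seed": config.seed,
        "package_version": p53ddr.__version__,
        "stages": {},
    }
    failed = False
    for stage in STAGES:
        if stage not in config.stages:
            continue
        record: dict = {"status": "skipped (upstream failure)"}
        if not failed:
            t0 = time.time()
            try:
                outputs = _run_stage(stage, config, out, digest)
                record = {
                    "status": "ok",
                    "outputs": [str(p) for p in outputs],
                    "wall_s": round(time.time() - t0, 3),
                }
            except Exception as exc:  # recorded, not raised: manifest is the contract
                record = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
                failed = True
        manifest["stages"][stage] = record

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _run_stage(stage: str, config: RunConfig, out: Path, digest: str) -> list[Path]:
    seed = config.seed
    if stage == "synth_gfp":
        gcfg = GfpGeneratorConfig(seed=seed, **config.gfp_options)
        dataset, _ = generate_gfp_dataset(gcfg)
        raw, _ = generate_raw_plate(gcfg)
        p1, p2 = out / "gfp_normalized.tsv", out / "gfp_raw.tsv"
        dataset.to_tsv(p1)
        raw.to_csv(p2, sep="\t", index=False)
        for p in (p1, p2):
            write_provenance(p, digest, seed)
        return [p1, p2]

    if stage == "process_timecourse":
        raw = pd.read_csv(out / "gfp_raw.tsv", sep="\t")
        processed = process_plate(raw)
        p = out / "gfp_processed.tsv"
        processed.to_csv(p, sep="\t", index=False)
        write_provenance(p, digest, seed)
        return [p]

    if stage == "fit":
        dataset = GfpDataset.from_tsv(out / "gfp_normalized.tsv")
        fcfg = FitConfig(seed=seed, **config.fit_options)
        results = fit(dataset, fcfg)
        best = select_from_family(minimal_cost_family(results))
        p = out / "fit_best_params.json"
        best.params.to_json(p, fixed=list(fcfg.fixed))
        summary = out / "fit_results.json"
        summary.write_text(
            json.dumps(
                [
                    {
                        "rank": r.rank,
                        "start_index": r.start_index,
                        "cost": r.cost,
                        "converged": r.converged,
                    }
                    for r in results
                ],
                indent=2,
            )
        )
        for path in (p, summary):
            write_provenance(path, digest, seed, n_starts=fcfg.n_starts)
        return [p, summary]

    if stage == "synth_counts":
        ccfg = CountGeneratorConfig(seed=seed, **config.counts_options)
        matrix, _ = generate_count_matrix(ccfg)
        p1, p2, p3 = out / "counts.tsv", out / "counts_metadata.tsv", out / "probe_map.tsv"
        matrix.counts.to_csv(p1, sep="\t")
        matrix.metadata.to_csv(p2, sep="\t")
        matrix.probe_to_gene.rename("gene").to_csv(p3, sep="\t")
        for p in (p1, p2, p3):
            write_provenance(p, digest, seed)
        return [p1, p2, p3]

    if stage == "preprocess_counts":
        matrix = _load_counts(out)
        norm = preprocess(matrix)
        p = out / "counts_normalized.tsv"
        norm.to_csv(p, sep="\t")
        write_provenance(p, digest, seed)
        return [p]

    if stage == "cohort":
        params_file = out / "fit_best_params.json"
        if params_file.exists():
            base, _ = KineticParameters.from_json(params_file)
        else:
            base = DEFAULT_PARAMS
        ccfg = CohortConfig(seed=seed, **config.cohort_options)
        cohorts = generate_cohorts(base, ccfg)
        p = out / "cohorts.tsv"
        cohorts.to_dataframe().to_csv(p, sep="\t", index=False)
        write_provenance(
            p, digest, seed,
            n_generated=cohorts.n_generated,
            n_removed=cohorts.n_removed,
            base_params=base.to_dict(),
        )
        return [p]

    if stage == "correlate":
        cohorts = CohortSet.from_dataframe(
            pd.read_csv(out / "cohorts.tsv", sep="\t")
        )
        observed_path = out / "counts_normalized.tsv"
        if observed_path.exists():
            matrix = _load_counts(out)
            norm = pd.read_csv(observed_path, sep="\t", index_col=0)
            observed = donor_table_from_counts(norm, matrix)
        else:
            raise ValueError("correlate stage requires preprocess_counts output")
        report = build_report(cohorts, observed, seed=seed, **config.correlate_options)
        p = out / "correlation_report.tsv"
        report.to_tsv(p)
        write_provenance(p, digest, seed)
        return [p]

    raise ValueError(f"unknown stage {stage!r}")


def _load_counts(out: Path) -> CountMatrix:
    counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col=0)
    metadata = pd.read_csv(out / "counts_metadata.tsv", sep="\t", index_col=0)
    probe_map = pd.read_csv(out / "probe_map.tsv", sep="\t", index_col=0)["gene"]
    return CountMatrix(counts=counts, probe_to_gene=probe_map, metadata=metadata)
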