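"""Cross-donor correlation analysis with bootstrap confidence intervals.

Compares Pearson correlations between basal TP53 expression and target-gene
expression (MDM2, CDKN1A, BTG2) across donors in two worlds: distributions
over virtual cohorts generated from the kinetic model, and point estimates
from an observed donor expression table with percentile-bootstrap 95 %
confidence intervals.  The report records, for each (target gene,
condition, time) cell, whether the observed correlation is compatible with
the virtual distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from p53ddr.cohort import CohortSet

__all__ = [
    "DonorExpressionTable",
    "CorrelationReport",
    "pearson",
    "cohort_correlation_distribution",
    "bootstrap_ci",
    "build_report",
]

_TABLE_COLUMNS = ("donor", "gene", "condition", "time_h", "value")


class DonorExpressionTable:
    """Per-donor expression values in tidy form.

    Columns: ``donor``, ``gene``, ``condition`` (``basal`` or ``treated``),
    ``time_h``, ``value``.  Observed data carry log2-normalized counts;
    virtual data carry raw model mRNA levels — Pearson correlations are
    computed within one table, never across scales.
    """

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in _TABLE_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"DonorExpressionTable missing columns: {missing}")
        dup = records.duplicated(subset=["donor", "gene", "condition", "time_h"])
        if dup.any():
            raise ValueError("duplicate (donor, gene, condition, time) entries")
        self.records = records.reset_index(drop=True)

    def n_donors(self) -> int:
        return self.records["donor"].nunique()

    def pair_vectors(
        self, target_gene: str, condition: str, time_h: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Aligned (basal TP53, target) vectors across donors.

        Basal TP53 is taken at the same time point as the target readout.
        Donors missing either value are dropped.
        """
        df = self.records
        x = df[(df["gene"] == "TP53") & (df["condition"] == "basal") & (df["time_h"] == time_h)]
        y = df[(df["gene"] == target_gene) & (df["condition"] == condition) & (df["time_h"] == time_h)]
        merged = x.merge(y, on="donor", suffixes=("_x", "_y"))
        return merged["value_x"].to_numpy(float), merged["value_y"].to_numpy(float)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DonorExpressionTable":
        return cls(pd.read_csv(path, sep="\t"))


def donor_table_from_counts(
    normalized: pd.DataFrame,
    matrix,
    genes: tuple[str, ...] = ("TP53", "MDM2", "CDKN1A", "BTG2"),
    treated_concentration: float = 3.3,
    times: tuple[float, ...] = (8.0, 24.0),
) -> DonorExpressionTable:
    """Donor expression table from a preprocessed count matrix.

    ``basal`` is the vehicle control at the matching time point and
    ``treated`` the nominal-dose condition; technical replicates are
    averaged and multi-probe genes (MDM2) are collapsed by probe mean.
    """
    from p53ddr.counts import collapse_probes  # local import avoids a cycle

    meta = matrix.metadata.loc[[s for s in normalized.columns if s in matrix.metadata.index]]
    rows = []
    for cond_name, conc in (("basal", 0.0), ("treated", treated_concentration)):
        for t in times:
            sel = meta[(meta["concentration_uM"] == conc) & (meta["time_h"] == t)]
            if sel.empty:
                continue
            sub = normalized[sel.index]
            by_donor = sub.T.groupby(sel["donor"]).mean().T
            for gene in genes:
                values = collapse_probes(by_donor, matrix.probe_to_gene, gene)
                for donor, v in values.items():
                    rows.append((donor, gene, cond_name, float(t), float(v)))
    return DonorExpressionTable(
        pd.DataFrame(rows, columns=["donor", "gene", "condition", "time_h", "value"])
    )


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation.

    Returns ``nan`` (an explicit undefined flag, never silently zero) when
    either vector has zero variance; requires length >= 3.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.clip(np.dot(xc, yc) / (sx * sy), -1.0, 1.0))


def _pearson_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise Pearson for matrices of paired resamples (nan when undefined)."""
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return np.clip(out, -1.0, 1.0)


def cohort_correlation_distribution(
    cohorts: CohortSet,
    target_gene: str,
    condition: str,
    time_h: float,
) -> tuple[np.ndarray, int]:
    """One correlation per cohort: basal TP53 vs the target readout.

    Returns the defined correlations and the count of undefined (zero
    variance) cohorts; raises if every cohort is undefined.
    """
    values = []
    n_undef = 0
    for cohort in cohorts.cohorts:
        if len(cohort) < 3:
            n_undef += 1
            continue
        x = np.array([d.readouts[("TP53", "basal", time_h)] for d in cohort])
        y = np.array([d.readouts[(target_gene, condition, time_h)] for d in cohort])
        r = pearson(x, y)
        if math.isnan(r):
            n_undef += 1
        else:
            values.append(r)
    if not values:
        raise ValueError(
            f"all {len(cohorts.cohorts)} cohort correlations undefined for "
            f"({target_gene}, {condition}, {time_h})"
        )
    return np.array(values), n_undef


@dataclass
class BootstrapCI:
    low: float
    high: float
    point: float
    n_reps: int
    n_undefined: int

    @property
    def undefined_warning(self) -> bool:
        return self.n_undefined > 0.1 * self.n_reps


def bootstrap_ci(
    table: DonorExpressionTable,
    target_gene: str,
    condition: str,
    time_h: float,
    n_reps: int = 1000,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile-bootstrap 95 % CI for the observed donor correlation.

    Donors are resampled with replacement (resample size equal to the donor
    count), the correlation recomputed per replicate, and the 2.5/97.5
    percentiles of the defined replicates returned.
    """
    x, y = table.pair_vectors(target_gene, condition, time_h)
    if x.size < 3:
        raise ValueError(f"need >= 3 donors, got {x.size}")
    point = pearson(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_reps, x.size))
    rs = _pearson_rows(x[idx], y[idx])
    defined = rs[~np.isnan(rs)]
    n_undef = int(np.isnan(rs).sum())
    if defined.size == 0:
        raise ValueError("all bootstrap replicate correlations undefined")
    lo, hi = np.percentile(defined, [2.5, 97.5])
    return BootstrapCI(float(lo), float(hi), point, n_reps, n_undef)


@dataclass
class CorrelationReport:
    """Virtual-vs-observed correlation comparison, one row per cell."""

    cells: pd.DataFrame  # gene, condition, time_h, r_obs, ci_low, ci_high,
    # virt_median, virt_q1, virt_q3, virt_lo, virt_hi, n_undefined, verdict

    def verdict(self, gene: str, condition: str, time_h: float) -> str:
        df = self.cells
        row = df[
            (df["gene"] == gene) & (df["condition"] == condition) & (df["time_h"] == time_h)
        ]
        if row.empty:
            raise KeyError(f"no report cell for ({gene}, {condition}, {time_h})")
        return row.iloc[0]["verdict"]

    def inside_fraction(self) -> float:
        ok = self.cells["verdict"].isin(["inside"])
        usable = self.cells["verdict"] != "missing"
        return float(ok.sum() / usable.sum()) if usable.any() else float("nan")

    def to_tsv(self, path) -> None:
        self.cells.to_csv(path, sep="\t", index=False)


def build_report(
    cohorts: CohortSet,
    observed: DonorExpressionTable,
    target_genes: tuple[str, ...] = ("MDM2", "CDKN1A", "BTG2"),
    conditions: tuple[str, ...] = ("basal", "treated"),
    times: tuple[float, ...] = (8.0, 24.0),
    n_boot: int = 1000,
    seed: int = 0,
) -> CorrelationReport:
    """Assemble the virtual-vs-observed comparison for all requested cells.

    A cell's verdict is ``inside`` when the observed correlation falls
    inside the virtual inter-quartile range, or its bootstrap CI overlaps
    that range; ``outside`` otherwise; ``missing`` cells are recorded
    explicitly rather than dropped.
    """
    rows = []
    for gene in target_genes:
        for cond in conditions:
            for t in times:
                try:
                    virt, n_undef = cohort_correlation_distribution(cohorts, gene, cond, t)
                    ci = bootstrap_ci(observed, gene, cond, t, n_reps=n_boot, seed=seed)
                except (KeyError, ValueError) as exc:
                    rows.append(
                        dict(gene=gene, condition=cond, time_h=t, r_obs=np.nan,
                             ci_low=np.nan, ci_high=np.nan, virt_median=np.nan,
                             virt_q1=np.nan, virt_q3=np.nan, virt_lo=np.nan,
                             virt_hi=np.nan, n_undefined=-1, verdict="missing",
                             note=str(exc))
                    )
                    continue
                q1, med, q3 = np.percentile(virt, [25, 50, 75])
                lo, hi = virt.min(), virt.max()
                in_iqr = q1 <= ci.point <= q3
                ci_overlap = (ci.low <= q3) and (ci.high >= q1)
                rows.append(
                    dict(gene=gene, condition=cond, time_h=t, r_obs=ci.point,
                         ci_low=ci.low, ci_high=ci.high, virt_median=float(med),
                         virt_q1=float(q1), virt_q3=float(q3), virt_lo=float(lo),
                         virt_hi=float(hi), n_undefined=n_undef,
                         verdict="inside" if (in_iqr or ci_overlap) else "outside",
                         note="")
                )
    return CorrelationReport(pd.DataFrame(rows))
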