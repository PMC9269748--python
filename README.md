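# p53ddr

Kinetic modeling of p53 DNA-damage-response dynamics and virtual-donor
cohort analysis.

## The problem

Cisplatin-induced DNA damage activates p53, which drives transcription of
*MDM2*, *CDKN1A* (p21) and *BTG2* — and MDM2 in turn degrades p53, closing
a negative feedback.  Time-resolved protein data for this pathway are
available from engineered reporter cell lines, but primary hepatocytes
from different donors vary widely, and it is unclear how far cell-line
dynamics extrapolate to that donor variability.  `p53ddr` is built for
researchers who want to test such extrapolations quantitatively: it
couples an ODE model of the pathway, calibrated on reporter time courses,
to a virtual-donor framework whose predicted cross-donor expression
correlations can be compared against observed donor count data.

## The model

Ten ODEs track DNA damage *DD*, p53 mRNA/protein/phospho-protein, and
mRNA–protein pairs for the three targets.  Cisplatin acts as an effective
stress `S(t) = EC_i·exp(−τt)` feeding damage; damage phosphorylates p53;
p53-p stimulates repair (feedback 1), activates target transcription
through a Hill term `P53p⁴/(Km⁴ + P53p⁴)` (tetrameric DNA binding;
exponent 1 available as a variant), and induces MDM2, which degrades both
p53 forms (feedback 2).  Reporter observables are affine maps, with the
p53 observable scaling `P53 + P53p`.

Main components:

| module | purpose |
| --- | --- |
| `p53ddr.model` | ODE system, steady states, simulation, feedback disruption |
| `p53ddr.calibration` | multistart trust-region least squares on GFP time courses |
| `p53ddr.cohort` | virtual donors: parameter perturbation, r-scans, noisy 8/24-h mRNA readouts |
| `p53ddr.correlation` | Pearson correlations, bootstrap CIs, virtual-vs-observed report |
| `p53ddr.timecourse` | geometric-mean aggregation, background correction, min-max normalization, B-spline resampling, peak delay / latency / viability features |
| `p53ddr.counts` | library/zero filters, median-of-ratios size factors, log2 transform, probe collapsing, expression clustering |
| `p53ddr.synth` | synthetic GFP, single-cell and donor-count generators with ground truth |
| `p53ddr.workflow`, `p53ddr.cli` | end-to-end pipeline (`p53ddr run`) and subcommands |

## Worked example

Simulate the packaged calibrated-like parameter set from its steady state
under the 5 μM effective dose, then generate a small virtual cohort and
correlate basal *TP53* with treated *MDM2* mRNA:

```python
import numpy as np
from p53ddr import DEFAULT_PARAMS, StimulusSchedule, simulate, steady_state
from p53ddr.cohort import CohortConfig, generate_cohorts
from p53ddr.correlation import cohort_correlation_distribution

ss = steady_state(DEFAULT_PARAMS)
grid = np.arange(1.0, 65.1, 1.5)
traj = simulate(DEFAULT_PARAMS, ss,
                StimulusSchedule(EC=DEFAULT_PARAMS.EC3, tau=DEFAULT_PARAMS.tau), grid)
total_p53 = traj.species("P53") + traj.species("P53p")
print(f"total p53 peaks at {grid[total_p53.argmax()]:.1f} h "
      f"({total_p53.max() / total_p53[0]:.2f}-fold over basal)")
print(f"MDM2 protein peaks at {grid[traj.species('MDM2').argmax()]:.1f} h")

cohorts = generate_cohorts(DEFAULT_PARAMS,
                           CohortConfig(c=0.2, n_cohorts=20, cohort_size=50, seed=1))
vals, _ = cohort_correlation_distribution(cohorts, "MDM2", "treated", 8.0)
print(f"removed {cohorts.n_removed}/{cohorts.n_generated} donors; "
      f"median TP53-MDM2 correlation {np.median(vals):+.2f}")
```

prints

```
total p53 peaks at 31.0 h (2.11-fold over basal)
MDM2 protein peaks at 64.0 h
removed 0/1000 donors; median TP53-MDM2 correlation +0.45
```

Total p53 rises with a multi-hour lag and peaks around 30 h, the MDM2
protein follows tens of hours later, essentially no perturbed donor has a
negative steady state at c = 0.2, and basal *TP53* predicts treated *MDM2*
positively across virtual donors — the model structurally cannot produce
the negative TP53–MDM2 correlation that donor data can show, which is
exactly what the report in `p53ddr.correlation.build_report` makes
visible.

The same flow from a shell:

```sh
p53ddr synth --kind gfp --seed 0 --out-dir results
p53ddr fit --data results/gfp_normalized.tsv --n-starts 20 --seed 0 --out results/best.json
p53ddr cohort --params results/best.json --c 0.2 --n-cohorts 100 --seed 0 --out results/cohorts.tsv
```

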