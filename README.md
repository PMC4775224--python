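# forcefret

Combined optical-trap force spectroscopy and single-molecule FRET analysis
of RNA aptamer folding, with a synthetic dumbbell-assay generator so every
stage of the pipeline is testable against known ground truth.

## The problem

In a dual-trap "fleezers" experiment a TPP-riboswitch aptamer is tethered
between two beads through DNA handles while a donor/acceptor dye pair on
its P3 and L5 helix arms reports their tertiary arrangement.  Each cycle
has a low-load (< 5 pN) **refolding period**, during which the helix arms
interconvert between *apart* (APO), *weakly bound* (WB) and *strongly
bound / docked* (SB) configurations, followed by a linear **force ramp**
(200 nm/s) that unfolds the molecule in abrupt extension gains ("rips").
The opening force of the first rip classifies the secondary-structure
conformation — F (no bound ligand, opening below 11.5 pN), F′•TPP (weakly
bound, 11.5–21 pN), F″•TPP (tightly bound, above 21 pN) — while the FRET
efficiency tracks the tertiary state.

The package implements the full analysis chain:

- **`wlc` / `fec`** — Marko–Siggia worm-like-chain elasticity,
  `F(x) = (kBT/P)·[¼(1−x/L)⁻² − ¼ + x/L]`, its numeric inverse, double-WLC
  series branches, rip detection on baseline-detrended extension steps with
  force-drop corroboration, opening-force classification.
- **`fret`** — corrections for donor→acceptor leakage (β), detection
  imbalance (γ) and background, with `E = I_A/(I_A + I_D)`; estimators for
  β (donor-only frames) and γ (anticorrelated transition steps); the
  Förster relation `E = 1/[1 + (R/R₀)⁶]`; the 255-nm absorbance formula for
  Trolox-quinone content.
- **`states`** — k-means (k = 3) clustering of opening events with
  midpoint-derived axis thresholds; segment-level assignment of FRET
  trajectories to APO/WB/SB against the thresholds (0.57 / 0.74 by
  default); four-Gaussian least-squares fits of the pooled FRET histogram
  (bin width 0.025).
- **`hmm`** — sequential four-state hidden Markov model (UF–A–B–C,
  tridiagonal transitions) on concatenated refolding trajectories;
  directional rates from Viterbi-decoded dwell times with boundary
  censoring.
- **`simulate`** — the generator: continuous-time Markov tertiary dynamics,
  quasi-static dumbbell mechanics with Gaussian-distributed rupture forces
  per conformation, and Poisson photon channels with crosstalk, imbalance,
  background, optional bleaching and blinking.

## A worked example

```python
import forcefret as ff

cfg = ff.RunConfig(
    simulator=ff.condition_sim_config("TPP", refold_duration=20.0),
    io=ff.IOConfig(n_traces=30, seed=11),
)
bundle = ff.run_pipeline(cfg)
for state, s in bundle.state_stats.items():
    print(state, round(s["mean"], 3), round(s["variance"], 4), s["n"])
```

prints

```
APO 0.459 0.0068 1486
WB 0.732 0.0095 2380
SB 0.801 0.0023 8404
```

i.e. the pooled FRET means and variances of the frames assigned to each
helix-arm state: the arms-apart state near E ≈ 0.46, the mobile weakly
bound state near 0.73 with visibly larger variance, and the docked state
near 0.80 with the smallest spread — matching the emission levels the
generator was configured with.  The `examples/` directory has one short
script per capability (simulation, rip analysis, FRET corrections,
threshold clustering, refolding kinetics, full report).

A thin command-line interface wraps the same stages:

```bash
forcefret simulate --config run.toml --n-traces 50 --seed 1 --out traces/
forcefret fec --traces traces/ --out rips.csv
forcefret report --config run.toml --out report/
```

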