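# Methods

## Model

The microtubule end is a 13-protofilament B-lattice of αβ-tubulin dimers
(8 nm axial rise) built on a GMPCPP seed. One simulation instance models
one end — plus or minus — as contiguous per-protofilament stacks with no
internal vacancies; "terminal" always means farthest from the seed. Three
reaction types drive a Gillespie direct-method event loop:

* **association** at the single candidate site atop each protofilament,
  first order in free tubulin: `on-rate = k_on · [tubulin]` per site, with
  the end-specific `k_on` and no difference between GDP- and
  GMPCPP-tubulin. The incoming subunit's nucleotide is drawn from the
  GDP-tubulin fraction of the reservoir (inexhaustible; no depletion).
* **dissociation** of terminal subunits at `k_off = k_on · K_D`, where the
  site affinity depends on the contact class — longitudinal-only
  (`K_D^long`), corner, i.e. one longitudinal plus one lateral contact
  (`K_D^corner`), bucket, i.e. two laterals (`K_D^corner²/K_D^long` by
  free-energy additivity: one lateral bond is worth
  `ln(K_D^long/K_D^corner)`) — and on the *governing nucleotide*. Under the
  interface-acting mechanism the plus-end governing nucleotide is the one
  buried beneath the terminal subunit; under the self-acting mechanism it
  is the terminal subunit's own. At the minus-end both rules pick the
  terminal subunit's nucleotide, making the mechanisms equivalent there. A
  governing GDP multiplies the affinities by a single weakening factor
  (≈3500-fold for the calibrated set, 3000-fold for the illustrative set).
  Lateral bonds themselves are nucleotide-insensitive.
* **nucleotide exchange** at exposed plus-end terminals only (the minus-end
  α-interface exposes no nucleotide). Dissociation of the bound nucleotide
  is rate-limiting: GDP leaves at `k_ex` and GMPCPP/GTP 12.5-fold faster,
  mirroring tubulin's 12.5-fold weaker affinity for GMPCPP; the replacement
  is drawn from the *free-nucleotide* mole fractions (e.g. 25/1000 for the
  25 µM GDP mix), not from the tubulin-bound fractions.

GTP hydrolysis, catastrophe and explicit tubulin conformations are outside
the model, matching the GMPCPP experimental regime it describes.

### Seam representation

The 3-start helix of a 13-protofilament lattice concentrates a 1.5-dimer
axial mismatch at the seam. Because 1.5 is not an integer number of dimer
rows, the default seam pairs each seam subunit with the **two** partners it
half-overlaps, each worth half a lateral bond on the free-energy scale
(`K_D = K_D^long · (K_D^corner/K_D^long)^b` with b in steps of ½). Integer
offsets (a single full-strength partner, axially shifted) remain available
through `LatticeConfig.seam_offset_rows` for sensitivity tests. The choice
matters: with the calibrated parameters the half-bond seam reproduces the
measured all-GMPCPP endpoint rates (plus ≈ 2.35 vs 2.2 nm/s, minus ≈ 0.99
vs 1.0 nm/s), whereas rounding the offset to 2 integer rows underestimates
both by ≈ 20% and rounding to 1 by ≈ 30% — growth is rate-limited by how
corner-site waves cross the seam, so the seam rule is the one structural
knob with leverage on absolute rates. The offset's sign is mirrored between
polarities (the lattice seen from the minus-end is the plus-end lattice
upside-down), which makes minus-end trajectories exact statistical
time-rescalings of plus-end ones when exchange is off.

## Parameters

| symbol | meaning | calibrated | illustrative |
|---|---|---|---|
| k_on⁺ | plus-end on-rate constant (µM⁻¹s⁻¹ per PF) | 0.74 | 1.0 |
| k_on⁻ | minus-end on-rate constant | 0.31 | 1.0 |
| K_D^long | longitudinal-only affinity (µM) | 86 | 100 |
| K_D^corner | corner affinity (µM) | 0.025 | 0.1 |
| K_D^long,GDP | GDP-weakened longitudinal (µM) | 3×10⁵ | 3×10⁵ |
| K_D^corner,GDP | GDP-weakened corner (µM) | 87 | 300 |
| k_ex | GDP exchange rate at plus tips (s⁻¹) | 0–1 scanned; 0.4 typical | 0 |
| r | K_D^GMPCPP / K_D^GDP | 12.5 | — |

The calibrated affinities come from fits of the same model family to
GMPCPP growth-rate data; the minus-end on-rate is refit here by the
common-random-numbers optimizer (`fit_kon_end`) against the minus-end
calibration line `GR⁻ = 0.9·[tub_CPP] − 0.05` nm/s. The illustrative set
exists only to exhibit the mechanism contrast at 1 µM tubulin.

## Solution composition

GDP and GMPCPP compete for tubulin's exchangeable site. With both far above
their K_Ds, the GMPCPP-tubulin fraction is
`f_CPP = [CPP]/([CPP] + [GDP]·r)`; the package carries the full
competitive-inhibition expression as well, and the simplification deviates
by < 0.1% over the experimental mixes at K_D^CPP = 0.5 µM. The same model
inverted gives the free-nucleotide GDP mole fraction from a GDP-tubulin
fraction (`free_gdp_fraction`), used as the default replacement-draw
composition in exchange scans.

## Estimators and fits

* Growth rate of a trace = OLS slope of the 13-protofilament mean length
  (nm, seed top = 0) sampled on a 1 s grid over the whole trace; traces at
  these parameters have no stalls, and steady state is reached within the
  first sampling intervals, so full-trace OLS is unbiased.
* Replicate protocols follow the study design: 50 × 600 s per condition
  (300 s during on-rate fitting), replicate *r* seeded `base_seed + r`.
  Scans reuse replicate seeds across conditions and across mechanism
  modes, so mechanism-blind tables are *identical*, not merely similar.
* Condition summaries: mean, SD (ddof 1; 0 for n = 1), SEM = SD/√n.
* Line fits and the affinity-ratio fit are least squares weighted by
  1/SEM (conditions with n = 1 are excluded with a warning); the ratio is
  fit on log r to keep it positive across decades, with the standard error
  propagated back to the r scale.
* `fit_kon_end` minimizes SEM-weighted squared error between simulated and
  target mean rates over k_on: an 8-point log grid over the bracket, a
  unimodality diagnostic, then golden-section refinement to 1% in k_on.
  Every candidate k_on is evaluated with the same replicate seeds; without
  common random numbers the Monte-Carlo noise defeats bracketing.
* Binding assays: corrected signal `y = (F_tub − F_blank)/(F_bsa −
  F_blank)`; its SEM from the relative-error propagation formula
  `√(Σ(SEM_i/mean_i)²)·(F̄_tub/F̄_bsa)` (accurate when the blank's relative
  SEM is small); isotherm `y = B − A·c/(c + K_D)` and competition
  `y = C + A·c/(c + K_D^nuc(1 + c_6T/K_D^6T))` fit by bounded nonlinear
  least squares with coarse-grid starting values, the competition amplitude
  constrained to the isotherm's realized quench at the fixed 6-thio-GTP
  concentration.

## Synthetic data

Generators are pure functions of (truth, design, seed). Growth datasets
draw i.i.d. Gaussian replicates around model- or simulation-derived
condition means with SD = cv·|mean| (default cv 0.25, a free knob chosen to
visually match per-microtubule scatter, not a measured value) floored at
0.05 nm/s; n = 60 per condition by default. Fluorescence datasets emulate
three replicate plate wells per point with a BSA channel attenuated by a
titrant-absorbance proxy, constructed so the corrected signal equals the
model curve exactly at zero noise. What passing recovery tests show is that
the estimators invert these generative models at realistic noise; they do
not certify the noise model itself against real kymograph or plate data
(real replicate scatter is neither Gaussian nor homoscedastic, and real
titrations drift).

## Numerical choices

Direct-method sampling uses one exponential clock over the summed rate;
per-protofilament rates are updated incrementally (an event touches only
its protofilament and lateral neighbors) with a periodic full re-sum to
cancel float drift. Buffered uniforms from a single `numpy` PCG64 stream
make a seed fix the whole trajectory; `step()` and the optimized `run()`
loop consume the identical stream. A locked basal row keeps columns
non-empty; a zero total rate (eroded lattice, no tubulin) advances time to
the horizon as a stall. The optional `max_rows` cap exists to make the
state space finite for master-equation validation. The engine derives its
neighbor and rate tables from the lattice and kinetics modules at
construction, so the hot loop cannot drift from the public rate laws.

## Known limitations

* Absolute rates inherit the seam representation; the half-bond rule is a
  structural hypothesis constrained by the published parameter/rate pairs,
  not an independently measured geometry. Plus-end growth runs ≈ 7% above
  the published endpoint value, and mixed-nucleotide rates inherit that
  margin.
* With exchange off, plus and minus ends are exact time-rescalings of each
  other, so the simulated ratio of apparent on-rate constants equals
  k_on⁺/k_on⁻ = 2.39 — slightly above the ≈ 2.0 measured experimentally;
  the simulated plus-end apparent on-rate is accordingly ≈ 3.5 rather than
  3 µM⁻¹s⁻¹ per microtubule whenever the minus line is recovered.
* No hydrolysis, catastrophe, conformational states, sheet/tapered tips,
  lattice defects or multi-seam lattices; none are needed for the GMPCPP
  growth regime, all are out of scope beyond it.
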