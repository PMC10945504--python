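# mtgrowth

Kinetic Monte Carlo modelling of microtubule plus- and minus-end elongation
in mixed GDP/GMPCPP nucleotide.

## The scientific problem

GTP-tubulin is preferentially incorporated at growing microtubule ends, but
*how* the bound nucleotide sets the strength of tubulin:tubulin contacts is
a mechanistic fork:

* **self-acting (cis)** — the nucleotide bound to a tubulin dictates how
  tightly *that* tubulin holds onto the lattice;
* **interface-acting (trans)** — the nucleotide buried at the dimer:dimer
  interface dictates how tightly the *two* flanking tubulins interact.

The two ends of the microtubule discriminate between these mechanisms. At
the minus-end the terminal subunit's nucleotide *is* the interfacial
nucleotide, so the mechanisms coincide; at the plus-end two different
nucleotides are in play (one exposed on the terminal subunit, one buried
beneath it), so the mechanisms predict different sensitivities to
GDP-tubulin. Under the interface-acting mechanism a GDP-tubulin landing on
a GMPCPP interface binds *strongly*, resides long, and poisons its
protofilament — so GDP-tubulin suppresses plus-end growth
super-stoichiometrically, while minus-end growth falls only in proportion
to the loss of GMPCPP-tubulin. Nucleotide exchange at exposed plus-end
terminals (rate-limited by dissociation of the bound nucleotide) rescues
poisoned protofilaments and sets the magnitude of the effect.

This package implements, as tested reusable code:

* a 13-protofilament B-lattice with a seam (`mtgrowth.lattice`), contact
  classification (longitudinal-only / corner / bucket sites), and the rate
  laws `on-rate = k_on·[tubulin]`, `k_off = k_on·K_D(site, nucleotide)`
  (`mtgrowth.kinetics`);
* a Gillespie-type event loop producing length-vs-time traces and
  replicate growth-rate statistics (`mtgrowth.engine`);
* the competitive nucleotide-binding model
  `f_CPP = [CPP]/([CPP] + [GDP]·r)`, `r = K_D^CPP/K_D^GDP`, the minus-end
  calibration line `GR = 0.9·[tub_CPP] − 0.05` nm/s, and the weighted
  global fit for `r` (`mtgrowth.equilibrium`);
* the 6-thio-GTP fluorescence-quench isotherm and competition fits with
  inner-filter correction and SEM propagation (`mtgrowth.binding`);
* simulation-based calibration: growth-line fits, refitting end-specific
  on-rate constants with common random numbers, and the
  nucleotide-exchange-rate scan (`mtgrowth.calibrate`);
* synthetic-data generators with recorded ground truth for all recovery
  tests (`mtgrowth.synth`).

## Worked example

Simulate both ends at 1.25 µM all-GMPCPP tubulin with the calibrated
parameters (k_on⁺ = 0.74 µM⁻¹s⁻¹, k_on⁻ = 0.31 µM⁻¹s⁻¹, K_D^long = 86 µM,
K_D^corner = 25 nM), then add the 25 µM GDP / 975 µM GMPCPP mix with
exchange at 0.4 s⁻¹:

```python
from dataclasses import replace
from mtgrowth import (CALIBRATED_PARAMS, AffinityRatio, LatticeConfig,
                      NucleotideMix, SimProtocol, SolutionState,
                      fraction_strong_tubulin, run_protocol)

proto = SimProtocol(duration=600.0, n_replicates=50, base_seed=1)
plus = run_protocol(LatticeConfig(polarity="plus"), CALIBRATED_PARAMS,
                    SolutionState(tubulin_total=1.25), proto)
minus = run_protocol(LatticeConfig(polarity="minus"), CALIBRATED_PARAMS,
                     SolutionState(tubulin_total=1.25), proto)
print(f"all-GMPCPP: plus {plus.mean_rate:.2f} nm/s, minus {minus.mean_rate:.2f} nm/s")

frac = 1 - fraction_strong_tubulin(NucleotideMix(975, 25), AffinityRatio(12.5))
mixed = run_protocol(
    LatticeConfig(polarity="plus"),
    replace(CALIBRATED_PARAMS, k_exchange_gdp=0.4),
    SolutionState(tubulin_total=1.25, frac_gdp_tubulin=frac, free_frac_gdp=0.025),
    proto)
print(f"25 uM GDP mix: plus {mixed.mean_rate:.2f} nm/s")
```

prints

```
all-GMPCPP: plus 2.35 nm/s, minus 0.99 nm/s
25 uM GDP mix: plus 1.28 nm/s
```

i.e. 2.5% GDP in the nucleotide pool (24% of the tubulin, after competitive
binding) roughly halves plus-end growth — the protofilament-poisoning
signature — while the same solution slows the minus-end only ~35%
(`analysis/04_mixed_nucleotide.py` prints the full table).

The numbered scripts under `analysis/` walk the full study: mechanism
contrast (01), growth calibration and the k_on⁻ refit (02), affinity-ratio
and binding-assay fits (03), calibrated mixed-nucleotide scans (04) and the
exchange-rate scan (05). Each writes its tables under `results/`.

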