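# memtether

Analysis pipeline for single-molecule optical-tweezers measurements of
protein–membrane binding, built around the C2 domains of synaptotagmin-1
(Syt1) and extended synaptotagmin-2 (E-Syt2).  A protein anchored to a
bead-supported lipid bilayer by a polypeptide linker is pulled through a
DNA handle; at constant trap separation its extension flickers between a
membrane-bound and an unbound level.  The package turns such
extension–time trajectories into zero-force binding energies and
kinetics, and converts the tethered measurements into bimolecular ones.

Who it is for: force-spectroscopy practitioners analyzing dumbbell
assays of membrane (or ligand) binding, and method developers who need a
ground-truth simulator for two-state trajectory estimators.

## The models at the core

**Tether correction (Gaussian chain).**  A linker of contour length L and
persistence length P, anchored at height h0 with the bound ligand at h1,
presents its free end to the membrane at an average effective
concentration

c̄ = (1 / s N_A) (3 / 4πPL)^½ exp(−3h²/4PL),  h = h0 − h1,

with s the area per lipid.  Then k_on = k_b / c̄, K_on = K_b / c̄ and
E_on = E_b − kBT ln(c̄ / 1 M); the unbinding rate is tether-independent.
A tandem domain pair joined by a short linker acquires a coupling energy
kBT ln(c / 1 M) in the same way, which lets the energy of an unmeasurable
domain be obtained by subtraction.

**Trajectory idealization (two-state HMM).**  Mean-filtered trajectories
are fitted by Baum–Welch EM with Gaussian emissions; the Viterbi path
gives dwell times and per-state mean forces; the per-step transition
matrix gives continuous-time binding/unbinding rates.

**Zero-force extrapolation (Boltzmann + Kramers).**  On a contour-length
reaction coordinate with wells at G(0) = −E_b, G(L) = 0 and a barrier
G(l‡) = E‡, the force-tilted potential G̃(l,F) = G(l) + E_stretch(l,F) −
F·x(l,F)/kBT yields P_ub = 1/(1+e^{ΔG̃}), k_ub = k_m e^{−[G̃(l‡)−G̃(0)]},
k_b = k_m e^{−[G̃(l‡)−G̃(L)]}.  A weighted nonlinear least-squares fit of
{P_ub, log k_b, log k_ub, Δx} across forces returns E_b, E‡, l‡ with
molecule-bootstrap uncertainties.

**Synthetic data.**  A seeded generator produces constant-separation
telegraph trajectories (Gillespie kinetics at the state-specific dumbbell
forces, WLC mechanics, Ornstein–Uhlenbeck bead noise) and pulling ramps
with binding flicker and Bell-rate unfolding rips, with exact ground
truth recorded for every output.

## Worked example

Correct a tethered measurement (Syt1 C2AB: E_b = 10.8 kBT,
log₁₀ k_b = 4.6, anchored by a 73-aa linker) to the bimolecular frame:

```python
from memtether import (GaussianTether, TetheredBindingMeasurement,
                       correct_measurement)

tether = GaussianTether.from_linker_aa(73)   # P=0.6 nm, h0=6, h1=2, s=0.7 nm^2
meas = TetheredBindingMeasurement(binding_energy=10.8,
                                  log10_binding_rate=4.6,
                                  log10_unbinding_rate=0.0)
corr = correct_measurement(meas, tether)
print(f"c_bar = {corr.effective_concentration:.3f} M, "
      f"dEc = {corr.correction_energy:.2f} kBT, "
      f"E_on = {corr.bimolecular_energy:.1f} kBT, "
      f"k_on = {10**corr.log10_bimolecular_rate:.2e} /M/s")
```

prints

```
c_bar = 0.137 M, dEc = 1.99 kBT, E_on = 12.8 kBT, k_on = 2.91e+05 /M/s
```

i.e. the 73-aa tether holds the domain at an effective ~0.14 M, so the
tethered assay under-reports the binding energy by ~2 kBT; removing the
tether gives a bimolecular energy of 12.8 kBT and an on-rate constant of
2.9×10⁵ M⁻¹s⁻¹.

The numbered drivers under `analysis/` run the full studies and write
tables under `results/`:

```bash
python analysis/01_tether_corrections.py   # corrected table, coupling, C2A decomposition
python analysis/02_benchmark_roundtrip.py  # simulate -> HMM -> landscape recovery
python analysis/03_fec_demo.py             # pulling-curve flicker and unfolding rips
```

`02_benchmark_roundtrip.py` ends with, per construct (fit/truth):

```
E-Syt2 C2AB  Eb 4.57/4.60 kBT  dx_ts 1.01/1.00 nm  F_eq 2.54/2.55 pN
E-Syt2 C2C   Eb 12.00/12.00 kBT  dx_ts 0.88/0.70 nm  F_eq 6.46/6.46 pN
Syt1 C2AB    Eb 10.86/10.80 kBT  dx_ts 1.43/1.40 nm  F_eq 4.81/4.79 pN
Syt1 C2B     Eb 7.41/7.40 kBT  dx_ts 1.09/1.00 nm  F_eq 3.83/3.82 pN
```

showing that the estimator chain recovers binding energies within a
fraction of kBT and transition-state distances within ~0.2 nm under
realistic noise and dumbbell compliance.

The same pipeline is scriptable from the shell via the `memtether` CLI
(`simulate`, `fit-hmm`, `fit-landscape`, `correct-tether`, `report`); see
`memtether --help`.

## Layout

```
src/memtether/     polymer, tether, trajectory/hmm, landscape, synth,
                   pipeline, io, cli, datasets (+ data/table1.csv)
analysis/          numbered narrative drivers
scripts/           acceptance.py
tests/             pytest suite (unit, property, acceptance)
docs/methods.md    models, defaults, numerical choices, limitations
```
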