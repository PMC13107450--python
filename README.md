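# cidnpkit

Analysis toolkit for photo-CIDNP studies of covalently linked
donor–acceptor dyads — flavin–tryptophan pairs joined by oligoproline
linkers in particular. Light-induced electron transfer in such systems
creates spin-correlated radical pairs whose nuclear spin polarization
(photo-CIDNP) reports on the reaction mechanism: whether recombination
happens *intramolecularly* in a compact biradical or *intermolecularly*
between radicals on different molecules, and how the cis/trans state of
the proline linker gates the two pathways. The package is aimed at
magnetic-resonance spectroscopists and modellers who need the
computational side of such a study under one roof:

* **Time-resolved CIDNP kinetics** — the cyclic-photoreaction model

      R(t)      = R₀ / (1 + k_t R₀ t)
      dP_R/dt   = −k_t P_R R − k_t β R² − P_R/T₁
      dP/dt     = +k_t P_R R + k_t β R²,     β = γ P_G / R₀

  with global (shared-parameter) least-squares fitting of k_tR₀, nuclear
  paramagnetic relaxation times T₁ and detector scales across many
  traces, multi-start optimization, variable projection of the scales,
  and an identifiability profiler.
* **Field-cycling analysis** — Kaptein's high-field sign rule
  Γ = sgn(Δg)·sgn(a)·μ·ε, the exchange-regime rule Γ = sgn(J_ex)·μ·ε,
  the level-anticrossing condition B_LAC = |J_ex|/(gμ_B), field-regime
  banding, concentration-series normalization, and a rule-based
  classifier that labels a set of field profiles as biradical
  (J-resonance), intermolecular (Δg), low-field hyperfine, or silent.
* **Conformer-ensemble geometry** — proline cis/trans labelling from ω
  dihedrals, ring-center distances and inter-plane angles, π-stacking
  (3–6.5 Å, <45° or >135°) and hydrogen-bond (H···O < 3 Å, both angles
  >130°) classification, and conditional probabilities per linker
  configuration.
* **Diffusion** — Stejskal–Tanner fitting of pulsed-field-gradient
  decays and conformer compactness comparison.
* **Synthetic data** — seeded generators for every input above with
  known ground truth, so each analysis closes the loop in tests.

## Worked example

Simulate one dyad's kinetics (ten delays over 0–100 µs, 4 µs detection
pulse, 5% noise), refit it globally with a shared termination rate, and
classify a field-profile set:

```python
import numpy as np
from cidnpkit import (KineticParameters, PulseTiming, FitSpec,
                      fit_kinetics, classify_mechanism)
from cidnpkit.synthetic import gen_kinetic_trace, gen_field_profiles

# --- kinetics: flavin (T1 = 120 us) and tryptophan (T1 = 150 us) traces
pulse = PulseTiming(4e-6)
traces = []
dyad = [("F8'", 120e-6), ("W2", 150e-6), ("W6", 150e-6)]
for seed, (label, t1) in enumerate(dyad):
    p = KineticParameters(kt_R0=1e5, T1=t1)
    tr, _ = gen_kinetic_trace(p, delays=np.linspace(0, 100e-6, 10),
                              pulse=pulse, noise_level=0.05,
                              proton_label=label, seed=seed)
    traces.append(tr)

spec = FitSpec(shared={"kt_R0": "shared", "T1": ["F", "W", "W"]}, seed=0)
res = fit_kinetics(traces, pulse, spec)
print({k: f"{v:.3g}" for k, v in res.estimates.items()
       if k == "kt_R0" or k.startswith("T1")})

# --- field profiles: a minor-conformer biradical signature
profiles, _ = gen_field_profiles("J_BIRADICAL", ["F8'", "W6", "W2"],
                                 peak_field=13e-3, snr=10, seed=1)
call = classify_mechanism(profiles)
print(call.label.value, f"peak {call.peak_field*1e3:.1f} mT",
      f"uniformity {call.sign_uniformity:.2f}")
```

Output:

    {'kt_R0': '1.01e+05', 'T1[F]': '0.000127', 'T1[W]': '0.00014'}
    J_BIRADICAL peak 12.5 mT uniformity 1.00

The fit recovers the generating termination rate (1e5 s⁻¹) and both
relaxation times (127 µs and 140 µs against the true 120 µs and 150 µs)
from thirty noisy points; the classifier identifies the
uniform emissive mid-field maximum with a silent high field as
intramolecular biradical recombination, locating the level anticrossing
at the nearest grid point to the true 13 mT.

A command-line interface mirrors the library:

    cidnpkit synth kinetics --kt-r0 1e5 --t1-us 120 --out trace.tsv
    cidnpkit fit-kinetics --traces trace.tsv --pulse-us 4
    cidnpkit classify-field --profiles profiles.tsv
    cidnpkit geom-analyze --traj frames.xyz --masks masks.cfg
    cidnpkit run --config pipeline.json

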