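# ncsaxs

Analysis toolkit for salt-induced nucleosome disassembly studied by
contrast-variation and time-resolved small-angle X-ray scattering
(SAXS).

A nucleosome core particle (NCP) wraps ~147 bp of duplex DNA in a
~1.65–1.9-turn left-handed superhelix around a histone octamer.
Raising NaCl destabilizes the particle: DNA unwraps and the histones
dissociate. Two experimental tricks make the process observable in
solution:

* **Contrast variation** — the solvent electron density is raised with
  sucrose until it matches the protein (ρ_solv = ρ_prot, at ~50% w/w
  sucrose), "blanking" the histones so that I(q) reports the DNA alone.
* **Stopped-flow mixing** — NCPs in 0.2 M NaCl are mixed 2:3 with a 3 M
  NaCl buffer (final 1.88 M) and the detector records 20 ms frames,
  resolving disassembly from 20 ms to minutes.

The package implements the full computational chain for this kind of
experiment, on synthetic data with known ground truth:

| stage | module | what it does |
|---|---|---|
| models | `ncsaxs.conformers` | coarse-grained two-beads-per-bp DNA conformers: wrapped superhelix, partially released (symmetric / asymmetric / "J"), straight duplex; the 32-member candidate pool |
| scattering | `ncsaxs.scatter` | three-phase contrast model (solvent / protein / DNA) and Debye-sum profiles `I(q) = Σᵢⱼ wᵢwⱼ sin(qrᵢⱼ)/(qrᵢⱼ)` |
| reduction | `ncsaxs.reduce` | detector-frame azimuthal averaging with σ = stdev/√N_pix, monitor normalization, buffer subtraction |
| inversion | `ncsaxs.ift` | regularized indirect Fourier transform to the pair-distance distribution P(R), with the three-criterion Dmax scan and I(0)/R_g from the moments |
| features | `ncsaxs.features` | the d1 (~20 Å, duplex diameter), d2 (~40 Å, overlapping DNA ends) and d3 (~80 Å, wrap diameter) diagnostics, and the wrapped / J-intermediate / unwrapped state call |
| ensembles | `ncsaxs.ensemble` | non-negative mixture fits of the pool against data (exact NNLS, optional seeded GA), χ² and the asymmetric weight fraction |
| kinetics | `ncsaxs.kinetics` | mixing arithmetic, time binning, kinetic SVD component counting, I(0,t)/R_g(t) traces, single/double exponential rate fits |
| generator | `ncsaxs.synthetic` | seeded equilibrium salt series and stopped-flow series under sequential kinetic schemes, Poisson detector frames, manifest with all generating truth |

The default kinetic schemes encode the two disassembly modes of strong
(Widom 601) and weak (5S) positioning sequences: 601 forms a
long-lived "J"-shaped intermediate (one DNA arm released, the core
still bound) that holds for ~0.2 s and then dissociates at 0.74 s⁻¹;
5S decays in two phases, 41.6 s⁻¹ then 1.13 s⁻¹, with no stable
intermediate.

## Worked example

The `pipeline` verb runs the whole chain on synthetic data — an
equilibrium NaCl titration at 50% sucrose analyzed by P(R) + feature
calls + ensemble fits, and stopped-flow series at 0% sucrose analyzed
by SVD and I(0,t) rate fits:

```sh
ncsaxs pipeline --seed 3 --out summary.json
```

The summary (seed 3) contains, per salt point,

| NaCl | state call | Dmax (Å) | R_g (Å) | χ² | asym. fraction |
|---|---|---|---|---|---|
| 0.2 M | ambiguous | 110 | 45.4 | 1.05 | 0.00 |
| 0.5 M | ambiguous | 140 | 46.0 | 0.96 | 0.16 |
| 1.0 M | intermediate_J | 260 | 74.6 | 0.92 | 0.83 |
| 1.5 M | intermediate_J | 320 | 93.7 | 1.01 | 0.74 |
| 2.0 M | unwrapped | 440 | 138.9 | 1.07 | 0.14 |

R_g expands from ~45 Å (compact wrapped particle) toward the free-DNA
value, the J-intermediate window carries a predominantly asymmetric
ensemble, and the 2 M endpoint is called unwrapped. The kinetics block
reports the refit rates against the generating truth:

```
"601": {"rates_per_s": [0.753], "true_rates_per_s": [0.74],  "svd_components": 2}
"5S":  {"rates_per_s": [38.1, 1.11], "true_rates_per_s": [41.6, 1.13], "svd_components": 3}
```

Other verbs (`simulate`, `pool`, `scatter`, `reduce`, `ift`,
`features`, `eom`, `kinetics`) expose the individual stages; see
`ncsaxs --help`.

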