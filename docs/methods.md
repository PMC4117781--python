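# Methods

## Coarse-grained DNA models

Every conformer is a rigid bead composite with two beads per base
pair, placed diametrically at the backbone radius about the local
duplex axis and advanced by the B-DNA twist. Defaults
(`HelixParams`):

| parameter | default | meaning |
|---|---|---|
| `rise_per_bp` | 3.4 Å | B-DNA axial rise |
| `twist_per_bp` | 34.3° | B-DNA helical twist |
| `duplex_radius` | 11 Å | backbone-bead radius; calibrated so the duplex-diameter signature in model P(R)s sits at the canonical d1 ≈ 20 Å (the raw backbone radius would put the pair-density centroid at ~18.4 Å because near-diametric neighbours pile up just below 2r) |
| `superhelix_radius` | 41.9 Å | nucleosomal superhelix radius |
| `superhelix_pitch` | 25.9 Å/turn | superhelix pitch |
| `wrapped_turns` | derived | see below |

The turn count of a full wrap is derived from the contour length:
147 bp at 3.4 Å/bp occupy 1.88 start-to-end turns at this radius and
pitch. The familiar 1.65-turn figure is the crystallographic
entry/exit convention and cannot hold all 147 bp at B-DNA rise (the
path would be 12% short); an explicit `wrapped_turns` is honoured but
warned about when it is inconsistent beyond 2%. The derived-turn
geometry also places the wrap-diameter feature d3 at ≈ 78–79 Å,
consistent with its ≈ 80 Å assignment.

Partially released conformers keep a central wrapped arc (the
proportional share of the full wrap) and extend straight arms
tangentially at the release points, with the twist phase continuous
along the whole molecule. Releasing everything degenerates to the
straight duplex. Arms are rigid: no bending, no flexibility ensemble.

The candidate pool holds exactly 32 members: the full wrap, 7
symmetric releases (9–64 bp per end), 8 single-end releases
(18–147 bp) in both orientations, and 4 unequal two-end patterns in
both orientations — 24 of 32 asymmetric. Mirror-image orientations
are deliberately both present: P(R) and I(q) cannot distinguish them,
and the ensemble fitter reports such pairs as degenerate rather than
hiding the ambiguity. `classify_symmetry` calls a member wrapped if
both ends have released < 10 bp, free if ≤ 10 bp remain, and
symmetric/asymmetric by |L − R| ≤ 10 bp; the 10 bp threshold is a
package convention.

An optional pseudo-histone core (8 beads on two staggered rings near
the superhelix axis) stands in for the octamer in contrast and
composition bookkeeping. It is schematic: reference R_g values that
depend on the atomic octamer (e.g. the ~82 Å J-plus-intact-octamer
benchmark) are not reproduced by it.

## Contrast and scattering

Three uniform phases: ρ_solv(0% sucrose, 0 M) = 0.334, ρ_prot = 0.42,
ρ_dna = 0.55 e/Å³. Solvent density rises linearly with sucrose weight
fraction (calibrated to match the protein at 50% w/w) and with NaCl
(+0.009 e/Å³ per mol/L). Because the salt term shifts the match
point, `ContrastModel.matched_at(sucrose, nacl)` recalibrates the
sucrose slope so matching holds exactly in a given working buffer —
this mirrors beamline practice, where the matching buffer is titrated
per condition, and the synthetic generator uses it for every
sucrose-contrast dataset.

Per-bead weights are (ρ_phase − ρ_solv)·V_bead with V_dna = 300 Å³
per backbone bead and V_prot = 13 500 Å³ per core bead (sized so the
octamer-to-DNA forward-scattering ratio is roughly that of a 108 kDa
octamer against 147 bp DNA). Profiles come from the Debye double sum
over point beads, optionally damped by a Gaussian bead form factor
exp(−q²σ²). The bead half-width σ defaults to 1.5 Å; larger values
wash out the weak d2 feature (see below). The default q-grid is 200
log-spaced points over 0.007–0.25 Å⁻¹, the instrument band.

## P(R): histogram route and regularized inversion

`pofr_from_model` is the ground-truth route: a weighted histogram of
all pairwise bead distances, each pair spread by the Gaussian pair
kernel (√2·σ) of the bead half-width, normalized so 4π∫P dr = I(0) =
(Σw)². The stored R_g uses the exact ordered-pair second moment
(including the zero-distance diagonal in the denominator), so it
equals the coordinate R_g for any bead count; for the continuous-body
moment formula the diagonal is negligible beyond ~100 beads.

`ift_regularized` inverts a measured profile: non-negative P on a
201-point uniform r-grid with pinned endpoints, a second-difference
smoothness penalty α, solved by non-negative least squares on the
stacked system. Two numerical choices matter:

* **Scale invariance.** The system is normalized by the peak
  weighted intensity before solving, so a given α means the same
  degree of smoothing for a weak late-time frame and a strong early
  one. Without this, a fixed α over-smooths compact-species frames by
  orders of magnitude relative to extended ones.
* **α selection.** χ² is non-decreasing in α, so the grid
  (10⁻⁶–10³, 19 points) is scanned upward and the largest α whose
  reduced χ² stays within 10% of the best fit (or of the noise floor
  χ² = 1, whichever is larger) wins — the smoothest distribution
  statistically indistinguishable from the best fit. An L-curve
  corner was tried first and is unstable on near-noiseless model
  profiles.

`scan_dmax` operationalizes the practitioner's three Dmax criteria in
order: (i) good fit — χ² within 1.2× of max(best, 1) and below an
absolute cap of 5; (ii) stability — P changes by < 5% (relative L2)
against the next-larger candidate; (iii) a smooth decaying tail over
the last 10% of [0, Dmax]. The smallest candidate passing all three
wins; if none passes, the best-χ² result is returned flagged
`unstable`. All thresholds are keyword arguments.

I(0) and R_g derive from the P(R) moments (I(0) = 4π∫P,
R_g² = ∫r²P / 2∫P), as in standard regularized-IFT practice.

## d1/d2/d3 features and state calls

Search windows: d1 ∈ [10, 30] Å (duplex diameter), d2 ∈ [33, 55] Å
(overlapping DNA ends), d3 ∈ [55, 100] Å (wrap diameter). The d2
window starts at 33 Å rather than 30 Å because every conformer with
released arms shows a spurious ~30 Å peak — the second harmonic of
the duplex cross-section ladder — that would otherwise read as an
end-overlap signature.

`detect_peaks` follows the histogram protocol: 5-point moving average
(reflect-padded), peaks by prominence ≥ 5% of the global maximum,
parabolic sub-grid refinement, the most prominent peak per window.
An optional band-limit mode replaces the boxcar with a low-pass
filter at the instrument band (raised-cosine rolloff to
qmax = 0.25 Å⁻¹): rigid discrete bead models carry coherent
helical-repeat combs (~16 Å period) that no measured profile could
show, and the band limit removes them without touching resolvable
structure. `analyze_pddf` combines the two routes — d1/d2 from the
boxcar protocol (they sit near the band edge, where the filter would
bias their locations), the d3 presence flag from the band-limited
one — before calling the state.

State rules (`call_state`): wrapped ⇔ d2 ∧ d3 ∧ Dmax < 150 Å;
J-intermediate ⇔ d3 ∧ ¬d2 ∧ Dmax > 250 Å; unwrapped ⇔ d1 ∧ ¬d3 ∧
Dmax > 400 Å; otherwise ambiguous. On the default pool the caller
agrees with geometry-derived expectations on 29/32 members; the
logged disagreements are the near-wrapped (9, 9) member (its d2
prominence sits at the detection threshold) and the two 110 bp
single-end releases (arc too short for d3 yet not yet free). The d2
criterion is intrinsically marginal in this coarse representation —
its prominence is a few percent — so on experimental-resolution
(IFT-reconstructed) P(R)s the wrapped call frequently degrades to
ambiguous while intermediate and unwrapped calls remain reliable.

## Ensemble fitting

The full-pool weight problem is linear, so the primary solver is
exact NNLS on the σ-weighted basis, followed by truncation to the
requested number of members and an exact re-fit; weights below 1% are
dropped from the report. A seeded genetic algorithm (population 50,
100 generations, scale-invariant cost) is retained behind
`method="ga"` for parity with classic ensemble-optimization
workflows; with a 32-member pool it is strictly worse than NNLS and
is judged on fit quality. Members whose profiles differ by less than
the noise (in particular left/right mirror releases) are reported as
degenerate pairs with a warning — weight placed on one could equally
sit on the other.

## Kinetics

Frames are binned in time with inverse-variance weighting (total
inverse variance is conserved; empty bins dropped with a warning).
The kinetic SVD weighs each q-row by its rms uncertainty and counts
components significant when the singular value exceeds 3× the noise
floor (median of the lower half of the spectrum) and both singular
vectors are smooth by the canonical kinetic-SVD autocorrelation
Σᵢvᵢvᵢ₊₁ > 0.6 (no mean removal — the statistic is near 1 for signal
vectors and near 0 for noise).

I(0,t)/R_g(t) traces use the per-frame regularized IFT — either a
full Dmax scan per frame or a fixed generous Dmax (560 Å bounds every
species here), which is faster and equally accurate for I(0). A
Guinier route exists but is biased low for very extended species
because q_min·R_g ≈ 1 at this instrument band; it inflates fitted
rates and is not used for quantitative work.

Exponential fits are weighted least squares of baseline +
ΣAᵢexp(−kᵢt), multi-started over decade-spaced rates (pairs
constrained to ratio > 2 at initialization) and polished by
Levenberg–Marquardt (`lmfit`), with covariance-derived uncertainties.
Model selection accepts two phases only when the reduced χ² improves
by > 15% and the smaller amplitude is > 3 standard errors.

## Synthetic data

The generator's defaults are the study conditions: equilibrium salt
series over 0.2–2.0 M NaCl at 0% and 50% sucrose (each salt mapped to
a documented pool ensemble with the histone core attached to bound
members), and stopped-flow series at 1.88 M after 2:3 mixing with
20 ms framing. Kinetic schemes are sequential first-order chains with
closed-form (Bateman) occupancies and an optional hold:

* **601**: the wrapped-to-J opening completes within the ~5 ms mixing
  dead time, so the first observable species is the J intermediate
  with bound core; it holds for 0.2 s (`lag`) and dissociates at
  0.74 s⁻¹ into free DNA + free octamer.
* **5S**: wrapped → mostly-open with partial core (half the core
  beads bound, half released) at 41.6 s⁻¹, then full dissociation at
  1.13 s⁻¹; no hold.

Composition changes drive I(0,t): dissociated parts scatter
incoherently, so I(0) of the bound complex (ΣW)² exceeds the sum of
squares of the separated parts. Default noise is 2% relative
Gaussian per profile point; detector frames are Poisson-sampled from
flux·exposure·I(q(pixel)). All randomness is seeded and every
generating parameter lands in the returned manifest; downstream
checks read truth from the manifest.

What the generator does **not** emulate: inter-particle interference
at low salt, radiation damage, sequence-dependent DNA mechanics
(601 vs 5S differ only through their kinetic schemes and ensembles),
arm flexibility, hydration-layer contrast, or an atomic octamer.
Passing tests therefore demonstrate the correctness and calibration
of the analysis chain on data that obey its assumptions, not the
instrument systematics of real beamline data.

## Problem sizes

The default test and reproduction runs use 147–149 bp models
(294–302 beads), 200-point q-grids, stopped-flow series of 1500–2000
frames binned to 60 log-spaced bins, and 6–10 seeded repeats per rate
estimate; these sizes put every rate estimate comfortably inside its
quoted uncertainty band while keeping a full run on one CPU in the
minutes range.
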