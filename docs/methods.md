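# Methods

This note records the models behind each analysis stage, the defaults
that matter, what the synthetic-data generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Differential HDX-MS

**Model.** Backbone amide exchange is treated as two-state EX2
kinetics: residue *i* exchanges at `k_ex,i = k_int / PF_i` with a
single base intrinsic rate `k_int` (default 1 s⁻¹ at 22 °C) and a
per-residue protection factor `PF_i ≥ 1`.  Peptide-level relative
deuteration at labelling time *t* averages
`1 − exp(−k_ex,i·t)` over the peptide's exchange-observable residues —
everything except the peptide's first residue (its amide back-exchanges
during digestion) and prolines (no backbone amide).  Values are
plateau-normalized (100 % = full exchange at the buffer D₂O fraction),
matching relative-deuteration reporting without back-exchange
correction; the buffer deuterium fraction `f_D2O` (default 0.754) is a
parameter and only affects absolute-mode output.  Sequence-dependent
intrinsic-rate tables are deliberately out of scope: all downstream
statistics operate on relative differences between states, which are
insensitive to the shared intrinsic rate.

**Time points.** Labelling times are stored as 22 °C-equivalent
seconds.  A labelling pulse on ice exchanges roughly tenfold more
slowly, so a 3 s on-ice point is ingested as exactly 0.3 s
(`io.effective_timepoint`).  The default scheme is 0.3, 3, 30 and
300 s in triplicate.

**Differential analysis.** The stored difference is
`ΔD = D_bound − D_free` (negative = protection).  Reports can flip the
sign for the free-minus-complex convention; keeping one canonical
internal sign avoids ambiguity.  Per peptide, the time point with the
largest |ΔD| is selected (ties to the earliest time), and a peptide
changes significantly when |ΔD| strictly exceeds the 5 % threshold —
boundary equality is not significant.  An optional replicate-aware
criterion (additionally |ΔD| > 2·sd_pooled) is available but off by
default.

**Residue consolidation.** Each residue's ΔD is the weighted mean over
the peptides whose exchange-observable span covers it, each peptide
weighted by 1/N_exch so that shorter, higher-resolution peptides
dominate.  Whether per-residue maps in practice use mean, max or
shortest-peptide rules varies between labs; the weighted mean is this
package's documented choice.  Classes are re-derived from the
consolidated ΔD at the same threshold; uncovered residues are
`no-coverage`.  Intervals are maximal runs of one class with length ≥ 3.

**What the generator does not emulate.** The synthetic peptide map
aligns peptide boundaries with the designed protection blocks (a
peptide may start one residue before a block because the first residue
is unobservable), which makes residue-level attribution well-posed.
Real pepsin maps straddle structural boundaries, so peptide-level
signal bleeds across block edges and residue-level false positives
within a margin of the true boundary are unavoidable.  Passing the
recovery tests therefore demonstrates the correctness of the analysis
chain, not that real data can be localized to single residues.  The
default fixture sequence is proline-free; proline handling is exercised
separately.

## NMR peak-list analyses

Combined amide CSP: `Δδ = √((0.2·Δδ_N)² + Δδ_H²)` in ppm, the standard
¹⁵N down-weighting.  Peak matching pairs assigned peaks by identity
and unassigned peaks greedily by normalized distance inside a
0.05 ppm (¹H) × 0.5 ppm (¹⁵N) box — typical TROSY-HSQC digital
resolution; the matching metric and tolerances are configurable
because no community standard exists.

Height normalization uses four glycine reference peaks (defaults G481,
G533, G549, G574); the scale factor is the mean reference/sample height
ratio, so reference ratios average to 1 after scaling.  Intensity
ratios are sample/reference heights where 1 means equivalent intensity
and 0 a completely absent (unlabelled or broadened-out) peak; with a
molar ratio, K_d and concentration the expected free fraction from the
single-site equilibrium is attached, and peaks attenuated well below it
are flagged as exchange-broadened.

Selective-unlabelling calls use Monte-Carlo confidence thresholds: two
peak heights are drawn as Normal(A, A/snr), their ratio accumulated
(default n_sim = 10⁵, seeded), and the threshold is mean − 3·sd per
S/N class {30, 20, 10, 8}.  The simulation is scale-free in A.  Each
observed peak is judged against the threshold of its S/N class,
assigned by rounding down.  Sharp-peak detection returns sample peaks
inside the random-coil ¹H window (default 7.9–8.6 ppm) that are above
a height quantile of matched peaks and either absent from the
reference or at least twofold intensified, ranked by height.  The
random-coil window replaces sequence-specific random-coil shift
prediction, which is out of scope.

## Primary SAXS

**Guinier.** `I(s) = I(0)·exp(−(s·Rg)²/3)` fitted on ln I vs s² with
an iteratively shrunk window until `s_max·Rg ≤ 1.3`.  A plain linear
fit over the full 1.3 window carries a systematic bias for compact
bodies (≈ +1.8 % in Rg for an ideal sphere, by direct computation), so
the default fit includes an s⁴ curvature term and reports Rg from the
s² coefficient; for data that are truly Gaussian the term vanishes and
the result is identical.  A non-negative low-s slope (aggregation
upturn) is an error.

**P(r).** The indirect transform solves
`I(s) = 4π ∫₀^Dmax P(r)·sin(sr)/(sr) dr` on a uniform 101-point r-grid
with 1/σ² data weighting, a second-difference (Tikhonov) smoothness
penalty, hard endpoint constraints P(0) = P(Dmax) = 0 and a soft
non-negativity penalty (iterative, 4 passes).  `reg_weight="auto"`
selects the penalty at the discrete L-curve corner (maximum curvature
of log-residual vs log-roughness over a 17-point λ grid).  Real-space
I(0) and Rg come from the moments of P(r); conservation
(4π∫P dr = I(0)) holds to ~1 % on noiseless bodies.

**D_max selection.** No standard rule exists; the package scans a
candidate grid, scores each by IFT χ² inflated by penalties for
negative lobes and oscillation, and returns the *smallest* candidate
whose score is within 5 % of the global best — preferring the most
compact support that explains the data.

**Porod.** `Q = ∫ s²I ds` with Guinier completion from 0 to the first
data point and an `I ∝ s⁻⁴` tail beyond the last; `V = 2π²I(0)/Q`.
The tail term can be disabled to demonstrate the truncation bias.

**Dilution series.** Per s-bin weighted linear fit of I/c against c;
the intercept is the interaction-free form factor with propagated
errors.  The generator's concentration effect is a structure factor
linear in c (`S = 1 − b·c·exp(−(s/s₀)²)`), the simplest model the
extrapolation must invert.

**SEC-SAXS NMF.** Frames are scaled per s-bin by 1/σ (exact
error-weighting when σ varies by bin but not by frame), factorized
with scikit-learn NMF under deterministic NNDSVD initialization, and
components returned on the intensity scale.  The component whose
Guinier Rg is closest to the expected value is selected (ties to the
lower index, with a warning); flat buffer-like components have no
Guinier radius and report NaN.  Near-collinear components trigger an
ambiguity warning (rank-deficient mixing).  Buffer handling assumes
frames are buffer-subtracted upstream or that the flat component
absorbs the background.

**Contact restraints.** Protected intervals on the kinase are
translated to "contact the partner" restraints; protected intervals on
the co-chaperone to "contact the partner or another domain of itself",
the reciprocal scheme used when feeding HDX interface information into
rigid-body modelling.  The serialization is a fixed-column text table
(see README).

## ITC

Single-site Wiseman isotherm with perfusion-cell bookkeeping: after
cumulative injected volume dV, `Mt = M₀(1 − dV/2V₀)/(1 + dV/2V₀)` and
`Xt = X₀(dV/V₀)(1 − dV/2V₀)`; the bound concentration is the smaller
root of `B² − B(nMt + Xt + K_d) + nMt·Xt = 0`, and the differential
heat per injection carries the displaced-volume correction.  The fit
floats (n, log₁₀Ka, ΔH) plus a constant heat-of-dilution offset
(blank titrations are often unavailable, so floating it is the safer
default); the first small injection is excluded by convention.  ΔG =
−RT ln Ka and ΔS = (ΔH − ΔG)/T are derived, so thermodynamic
self-consistency holds exactly by construction.  Reliability
diagnostics: (i) a pre-fit signal check — if the heat dynamic range is
within ~15× the injection-to-injection noise the titration carries no
isotherm information; (ii) a saturation check — if the final heats
have not decayed below 40 % of the initial heats the titration never
approached saturation; (iii) the Wiseman c-value n·Ka·[cell] outside
[1, 1000].  Any of these raises a weak-binding warning and marks the
fit unreliable, the expected outcome for millimolar-scale interactions
at tens-of-µM cell concentrations.  The thresholds (15×, 0.4) were
fixed from the clear separation between the weak (c ≈ 0.02) and
fittable (c ≥ 5) regimes in simulation and are not tuned per dataset.

Default reference geometry: 1.458 mL cell, 16.9 µM macromolecule,
211.7 µM titrant, 20 injections (3 µL then 19 × 15 µL), 20 °C.  The
generator's default enthalpy (−9.2 kcal/mol) is a typical exothermic
protein-protein value chosen once for the ground-truth registry.  At
this geometry the designed K_d of 1.8 µM gives c ≈ 9.4; with additive
heat noise of 1 % of the peak injection heat (0.3 µcal) the *median*
K_d recovery error over seeds is below 10 % — per-seed errors up to
~20 % occur and reflect the information content of a c ≈ 9 titration
at that noise, not an estimator defect.

## Thermofluor

Two-state sigmoid with linear pre/post baselines; the apparent melting
temperature is the inflection of the transition.  The default
estimator takes the maximum of a Savitzky-Golay-smoothed dF/dT
(window 7 points, order 2, parabolic sub-grid refinement); a Boltzmann
fit midpoint is available as the alternative and the two agree to grid
resolution on symmetric noiseless curves.  The 7-point window keeps
the seed-to-seed scatter below 0.3 °C at 1 % noise on a 1 °C grid
(a 5-point window does not).  Curves without usable dynamic range
(range < 10× point-to-point noise) are rejected rather than returning
an arbitrary maximum.  Normalization maps each curve onto [0, 1]
between fitted plateaus and reports the normalized fluorescence at
20 °C as a basal-exposure diagnostic (elevated values indicate
hydrophobic exposure in the folded state).

## Occupancy and dose equivalence

Complex occupancy is `100·complex/(complex + free)` band intensity,
invariant to exposure; an optional log-linear standard curve converts
signals to concentrations first (a 4PL model was not needed within the
linear range and is out of scope).  Dose equivalence interpolates the
response level reached at a query dose on curve A onto monotone curve
B; non-monotone responses are rejected rather than silently inverted.

## Determinism and problem sizes

Every stochastic generator takes an explicit seed and is
bit-reproducible; NMF uses deterministic initialization.  The test
suite and the acceptance script use the study-condition sizes
throughout — 20-seed recovery loops for ITC, HDX and T_m, 200-frame
SEC-SAXS mixtures, 10⁵-draw threshold simulations, ~500-point
scattering curves — chosen as the sizes at which the recovery
statistics are stable.

## Known limitations

* No back-exchange correction or sequence-specific intrinsic rates:
  outputs are relative deuteration only and are not comparable across
  experiments with different quench/digestion behaviour.
* Residue-level HDX maps inherit peptide-level resolution; see above.
* The IFT is a straightforward Tikhonov scheme; it does not reproduce
  the perceptual quality criteria of mature indirect-transform
  packages, and D_max selection is this package's own rule.
* The ITC model is strictly 1:n single-site with a constant dilution
  offset; no competitive or multi-site schemes.
* NMF component selection assumes the species of interest has a
  distinguishable Rg; co-eluting species of similar size will merge.
* Gel/ELISA quantitation starts from band intensities; image
  segmentation is out of scope.
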