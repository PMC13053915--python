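# Methods

## Exchange model

The physics core treats two-site chemical exchange A ⇌ B of a transverse
¹⁵N magnetisation under the Bloch–McConnell equations. State populations
are p_A = 1 − p_B with B the minor state by convention (the container
accepts any p_B ∈ [0, 1) so the model is well defined under state
relabeling; the fitter constrains p_B < 0.5). The free-precession evolution
matrix in the frame of the A resonance is

    L = [ −R2A − k_AB        k_BA            ]
        [  k_AB              −R2B − k_BA + iΔω ]

with k_AB = p_B·k_ex, k_BA = p_A·k_ex and Δω in rad·s⁻¹ (ppm values are
converted with a configurable ¹⁵N Larmor frequency, default 60.8 MHz,
corresponding to a 600 MHz spectrometer).

The CPMG convention is ν_CPMG = n/(2·T_relax) with n refocusing pulses,
inter-pulse delay τ = 1/(2ν) and echo element τ/2–180°–τ/2; default
T_relax = 40 ms with frequencies between 25 Hz and the 2 kHz maximum.
Schedules whose frequencies imply a non-integer pulse count are rejected.
180° pulses are ideal and instantaneous (complex conjugation); there is no
off-resonance or pulse-imperfection model. The observable is the magnitude
of the summed site magnetisations starting from equilibrium populations,
and R2eff = −ln(signal)/T_relax.

Three computational routes exist and serve as mutual oracles:

* `propagate_cpmg` — numerical: Padé matrix exponential of L over τ/2 and
  iterated echo-pair products. One echo element maps M → A·conj(M) with
  A = P·conj(P), so an even train is the linear map (A·conj(A))^(n/2).
* `carver_richards(..., t_relax=...)` — exact closed form: the same
  operators evaluated analytically (2×2 expm via cosh/sinh of the
  eigenvalue splitting, matrix powers via the characteristic polynomial),
  equivalent to Baldwin's exact single-quantum CPMG solution. This is the
  forward model used for fitting (vectorised, ~0.4 ms per curve).
* `carver_richards(...)` without the train length — the classic
  Carver–Richards/Davis large-n asymptote. It omits the eigenmode
  amplitude factor, whose contribution to R2eff scales as ~1/(n·τ); at 40 ms
  constant time and ν = 50 Hz (n = 4) in slow exchange this amounts to a
  few percent, which is why the exact finite-train form is the default
  oracle and fitting model whenever T_relax is known. The asymptote is
  retained because it is the standard literature expression and a useful
  regime check (it converges to the propagator beyond n ≈ 16).
* `luz_meiboom` — fast-exchange limit, for k_ex ≫ Δω.

R_ex is defined operationally as R2eff(ν_min) − R2eff(ν_max) over the
schedule in use, evaluated with the propagator.

## Estimators

* Monoexponential decays I(t) = I₀·e^(−Rt) are fitted by weighted
  nonlinear least squares (absolute intensity noise), initialised
  log-linearly; uncertainties from the covariance, quality as reduced χ².
  Non-convergence returns a flagged estimate with infinite sigma rather
  than raising.
* Single-plane R2eff and hetNOE ratios use first-order (Gaussian) error
  propagation. The propagated R2eff sigma is validated against Monte-Carlo
  draws (agreement within 5% at 1–2% intensity noise); the hetNOE flags
  ratios whose reference is within 3σ of zero.
* Dispersion curves are fitted twice: a flat model (weighted mean) and a
  two-site model with equal intrinsic rates, parameters
  (p_B, k_ex, Δω, R2⁰), bounded least squares from a coarse grid
  (log-spaced k_ex ∈ [100, 10⁴] s⁻¹ × Δω ∈ [50, 3000] rad·s⁻¹ ×
  p_B ∈ {0.01, 0.03, 0.1}) with the best three starts refined. The
  two-site model is kept only if an F-test on the weighted residual sums
  rejects the flat model at α = 0.01 — a deliberately conservative rule so
  that flat noisy curves are reported as flat (type-I control ≥ 90% in the
  suite). R_ex uncertainty comes from first-order propagation of the
  parameter covariance through the model; Monte-Carlo propagation is
  implicitly validated by the coverage experiment.
* Because a single curve at realistic noise leaves k_ex weakly determined
  (the linearised information bound gives ~20% at 1.5% intensity noise),
  `fit_dispersion_global` jointly fits residues that report on one
  exchange process, sharing (p_B, k_ex) with per-residue (Δω, R2⁰) — the
  standard grouped-fit practice. The pipeline applies it to all residues
  whose individual fit prefers the two-site model.

## CSP and significance rules

CSP = √(Δδ_H² + Δδ_N²/n_weight) with n_weight = 10 as the default
(nitrogen axis compressed by √10). The more common (Δδ_N/α)² dialect is
expressible by setting n_weight = α²; the weight is exposed rather than
silently reinterpreted. The significance threshold is k·SD (k = 2) of the
CSP distribution over all matched residues, without outlier trimming by
default (a trimmed variant exists behind a flag). Peaks present in one
state only are tracked as disappeared/appeared; disappearance is the
experimentally meaningful direction (exchange broadening on binding), but
both are reported.

Difference maps use Δ = A − B on the intersection of assigned residues;
residues missing on either side are reported separately, never silently
dropped. Significance is |Δ| > k·SD of the empirical Δ distribution for
that observable (k = 2), about zero and not mean-centred; per-residue
z-scores against propagated errors are available as a secondary rule. If
the distribution has zero spread nothing is flagged. No multiple-testing
correction is applied; the run log annotates the ~4.6% expected false-flag
rate under normality. The R_ex reporting rule is strict: R_ex > 7.5 s⁻¹.
Box-plot summaries use linear-interpolation quartiles and 1.5·IQR Tukey
whiskers.

## Structure mapping

Sites are Cα atoms of the configured chain in author numbering; altlocs
resolve to highest occupancy, insertion codes are rejected outright
(renumbering is the user's decision). B-factor normalisation is the
per-chain z-score, computed per structure before any differencing.
Spatial clustering of significant residues is single-linkage on the
Cα–Cα distance graph with an 8 Å cutoff (the standard coarse contact
definition; configurable), implemented as connected components of the
thresholded distance matrix and verified in the suite against a
brute-force search. Scores are written into the %6.2f temperature-factor
column with −1.00 as the unscored sentinel; out-of-range scores are
rescaled with a warning rather than corrupting the fixed-width format.

## Synthetic study

The generator emulates a two-state (apo/bound) backbone-dynamics dataset
on an ideal α-helix (rise 1.5 Å/residue, 100° twist, radius 2.3 Å — a
deliberately simple geometry whose consecutive-Cα distance of 3.8 Å makes
distance-based assertions analytic). Apo baselines: δ_H ~ N(8.3, 0.45),
δ_N ~ N(119, 3.5) ppm, R1 ~ N(1.3, 0.1) s⁻¹, R2⁰ ~ N(12, 1.5) s⁻¹,
NOE ~ 0.82 with depressed flexible termini. The bound state adds
effect·exp(−d/10 Å) for the distance d to the nearest ligand-site residue
(site 95–105), full-size effects on eight distal network residues
regardless of distance, a shared exchange process (p_B = 0.05,
k_ex = 1500 s⁻¹) with per-residue Δω drawn from 700–1100 rad·s⁻¹ for the
twelve strong exchangers (R_ex ≈ 10–25 s⁻¹, all above the 7.5 s⁻¹ rule)
and 200–280 rad·s⁻¹ for three weak exchangers present in both states
(R_ex ≈ 1–3 s⁻¹, below the rule), and four pocket peaks that disappear in
the bound state. Full-size effects: Δδ_H = 0.12 ppm, Δδ_N = −0.5 ppm,
ΔR1 = −0.2 s⁻¹, ΔR2 = 2.5 s⁻¹, ΔNOE = −0.08 — magnitudes typical of
reported ligand-induced changes and large enough to stand ≥ 3 background
SDs above the measurement noise.

Measurement emulation: every intensity plane receives additive Gaussian
noise of sd = 1.5% of the reference intensity; peak positions receive
0.002/0.010 ppm (¹H/¹⁵N) jitter. Decay series use 8 delays in duplicate
per rate (R1 up to 1.2 s, R2 up to 120 ms); dispersion uses 18 frequencies
in duplicate plus two reference planes at T_relax = 40 ms. Duplicate
planes are the standard error-estimation scheme and were chosen, together
with the frequency grid, by a linearised identifiability analysis so that
the grouped fit determines k_ex to ~10% at the declared noise — i.e. the
schedule is designed the way a spectroscopist designs one, around the
parameters it must resolve. All randomness flows from one seeded
generator; regeneration with the same seed is byte-identical, and the
manifest records every setting.

What the generator does **not** emulate: real spectra (no lineshapes,
overlap, or peak-picking errors), field-strength dependence (single
field), temperature effects, anisotropic tumbling (R1/R2 baselines are
i.i.d., not orientation-dependent), multi-site exchange, and any real
protein's shift statistics. Passing tests therefore demonstrate that the
estimators and rules recover effects of the planted kind at the declared
noise — not that they are robust to pathologies the generator omits.

## Problem sizes and numerical choices

Validation experiments use 10⁴ draws (sigma calibration), 1000 replicates
(fit bias), 200 replicates of a 4-residue group (dispersion recovery), and
100 random site sets (clustering oracle); each finishes in minutes on one
CPU. Tolerances asserted in the suite: closed form vs propagator < 0.5%
relative; three-way fast-exchange agreement < 1%; degenerate limits flat
to 10⁻⁸ s⁻¹; sigma calibration within 5%; fit bias < 1%; k_ex within 15%
and p_B·Δω² within 10% for ≥ 80% of replicates with 1σ R_ex coverage of
68% ± 7%; exact rule recovery at zero noise and ≥ 90% sensitivity/
specificity at default noise. Ties and degenerate inputs: zero-spread
significance distributions flag nothing; non-positive noisy intensities
drop the plane (never a log of a negative number); dispersion fits fall
back to the flat model with a warning when no start converges; the exact
closed form raises a branch-cut error and the caller falls back to the
propagator when its signal underflows.

## Known limitations

Per-residue fits report R_ex from a single field, so (p_B, k_ex, Δω) are
exposed only through the grouped fit and R_ex itself — consistent with
treating exchange parameters as internal and R_ex as the product. The
F-test model selection assumes approximately Gaussian R2eff errors, which
the log transform violates for weak planes; the conservative α compensates
in practice (validated by the type-I experiment). B-factor comparison
requires identical residue coverage and is z-score-based, so it detects
redistribution of flexibility, not absolute changes. Clustering operates
on Cα coordinates only; side-chain contacts are invisible.
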