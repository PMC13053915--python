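# nmrdyn

Comparative per-residue NMR dynamics analysis for ligand-binding studies.

When a ligand binds a protein it can change not only local structure but
the motional landscape of residues far from the binding site — dynamic
allostery. Solution NMR sees this residue by residue: chemical-shift
perturbations (CSPs) report changes in average local environment,
longitudinal/transverse relaxation rates (R1, R2) and the steady-state
{¹H}-¹⁵N heteronuclear NOE report ps–ns backbone motion, and
Carr–Purcell–Meiboom–Gill (CPMG) relaxation dispersion reports µs–ms
conformational exchange through its contribution R_ex to transverse
relaxation. `nmrdyn` implements the full comparative workflow for two
ligand states (e.g. apo vs bound): per-residue fitting of each observable
with propagated uncertainties, difference maps with empirical significance
rules, and spatial clustering of affected residues on the structure. A
seeded synthetic-data generator with planted ground truth exercises the
pipeline end to end and quantifies how reliably the rules recover known
effects.

## The models

**Two-site exchange.** A nucleus exchanging between conformations
A ⇌ B (populations p_A = 1 − p_B, exchange rate k_ex, shift difference
Δω) evolves under the Bloch–McConnell equations. In a constant-time CPMG
experiment the effective transverse rate at refocusing frequency ν_CPMG is

    R2eff(ν) = −(1/T_relax) · ln[ I(ν) / I₀ ],

and its dispersion encodes (p_B, k_ex, Δω). Three routes are implemented:
exact numerical propagation of the 2×2 complex evolution matrix through
the pulse train (`propagate_cpmg`); the Carver–Richards closed form, with
an exact finite-pulse-train variant used whenever the constant relaxation
time is known (`carver_richards`); and the Luz–Meiboom fast-exchange limit

    R2eff = R2⁰ + (p_A p_B Δω² / k_ex) · [1 − (4ν/k_ex)·tanh(k_ex/4ν)]

(`luz_meiboom`). The exchange contribution is reported as
R_ex = R2eff(ν_min) − R2eff(ν_max), and residues with R_ex > 7.5 s⁻¹ form
the dispersing set.

**CSP.** For matched amide peaks,
CSP = √(Δδ_H² + Δδ_N²/10) (ppm), with the ¹⁵N weight configurable.
Residues whose CSP exceeds two standard deviations of the CSP
distribution are significant; peaks present in only one state are called
disappeared/appeared.

**Difference maps and clusters.** For each observable, Δ = value(A) −
value(B) on the shared residues; |Δ| beyond two standard deviations of the
empirical Δ distribution is significant. Significant residues are grouped
by single-linkage clustering on the Cα–Cα distance graph (8 Å cutoff), and
per-residue scores are written into the B-factor column of a PDB copy for
visualisation.

## Worked example

```sh
python analysis/01_simulate_study.py --seed 1 --out results/study
python analysis/02_run_pipeline.py  --study results/study/default_noise --out results/pipeline
python analysis/03_score_against_truth.py --seed 1 --study results/study/default_noise --out results/scores
```

The generator plants a ligand site at residues 95–105 of a 120-residue
chain, eight distal "network" residues with full-size effects, twelve
residues with exchange above the R_ex rule, and four peaks that disappear
on binding:

```
  Rex > 7.5 1/s in bound state: [12, 27, 42, 58, 91, 93, 94, 98, 106, 107, 108, 109]
  disappeared on binding: [96, 100, 102, 104]
  2-sigma-significant true CSPs: [12, 20, 27, 35, 42, 50, 58, 66, 95, 97, 98, 99, 101, 103, 105]
```

At the study's default noise (1.5% of the reference intensity) the
pipeline recovers:

```
rex_above_7.5: called 12/12 (sens 100.00%, spec 100.00%)
csp_2sigma: called 16/15 (sens 100.00%, spec 99.01%)
disappeared: called 4/4 (sens 100.00%, spec 100.00%)
planted delta-R1 field correlation: 0.892
planted delta-R2 field correlation: 0.936
```

i.e. every planted dispersing residue and disappeared peak is found, one
borderline residue is additionally flagged by the CSP rule, and the
planted relaxation-difference fields are recovered with correlation ≥ 0.89.
The cluster report separates the pocket-proximal CSP cluster
(94–105, diameter 16.5 Å) from the eight isolated network singletons.

The same stages are available as a CLI (`nmrdyn simulate / csp / fit-relax /
fit-cpmg / compare / cluster / run`); `nmrdyn run --config cfg.yaml` runs
everything from a YAML config.

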