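# Methods

## Scope

`shiftscan` implements the analysis side of a differential scanning
fluorimetry (DSF) compound screen against a purified membrane transporter
(VMAT2 as the motivating system), together with the downstream follow-up
analyses such a screen feeds: fingerprint clustering for candidate
selection, four-parameter logistic (4PL) dose–response fitting, and
post-processing of MD-derived tables (per-residue decomposed energies,
hydrogen-bond occupancies, per-frame enthalpies, RMSD traces). Everything
upstream of the tabular interfaces — instrument control, cell biology,
trajectory generation, implicit-solvent energy evaluation — is out of
scope; those outputs are inputs here.

Because raw instrument exports for such screens are typically not deposited,
the package carries a first-class synthetic-data module that generates every
input it consumes, annotated with the ground truth used in generation, so
that recovery can be tested exactly.

## Synthetic melt curves

A well's fluorescence trace is modeled as a two-state van 't Hoff unfolding
with linear baselines and an optional post-transition signal decay:

    K(T)   = exp((ΔH_vH / R) (1/T_m − 1/T))        (kelvin scale)
    f_u(T) = K / (1 + K)
    F(T)   = [F_N(T)(1 − f_u) + F_U(T) f_u] · D(T) + ε
    D(T)   = exp(−λ · max(0, T − T_m))

with F_N, F_U linear in T and ε i.i.d. Gaussian. The unfolded fraction is
exactly ½ at `tm_true` by construction. The decay term reproduces the
post-peak signal decline seen in thiol-reactive-dye (CPM) melts
(aggregation/quenching); it is the minimal extension of the two-state model
that gives the rise–peak–decline shape of real traces. ΔC_p of unfolding is
fixed at zero: adding it changes nothing tested downstream.

Defaults (the study conditions; all configurable):

| parameter | default | rationale |
| --- | --- | --- |
| grid | 25–95 °C, 0.1 °C step | a 2 °C/min ramp digitized finely |
| ΔH_vH | 150 kcal/mol | ~6 °C 10–90 % transition width, as in detergent-solubilized transporter melts |
| baselines | native (1.0, 0.001), unfolded (3.0, −0.005) AU | ~2 AU transition amplitude |
| decay λ | 0.02 /°C | mild post-peak decline |
| trace noise | 0.002 AU | instrument melt traces are smooth (SNR ~10³); well-to-well variation dominates |
| control Tm | 62.6 ± 0.32 °C | the DMSO-control regime the screen emulates |

Two distinct noise scales matter. Plate-level control scatter (SD 0.32 °C)
is modeled as true well-to-well Tm variation, so the recovered per-plate
control SD matches the regime directly. Separately,
`CALIBRATED_NOISE_SD = 0.03` AU is the trace-noise level at which
fluorescence noise *alone* makes the Tm estimator scatter by ≈ 0.3 °C on
the default grid (calibrated once by a seed sweep); it parameterizes the
estimator-robustness regime, not the plate simulations.

One caveat the synthetic data makes visible: with the decay term active,
the first-derivative peak (the operational Tm) sits ≈ 0.5 °C below the
thermodynamic midpoint. This offset is common to every well on a plate and
cancels exactly in ΔTm; analyses that report absolute control Tm use the
decay-free shape, where peak and midpoint coincide.

What the generator does **not** emulate: plate positional (edge) effects,
dye photochemistry, multi-domain unfolding, compound autofluorescence,
pipetting error structure. Passing recovery tests therefore demonstrate
correctness of the analysis rules under the stated noise model, not
robustness to those real-world artifacts.

## Tm determination

Tm is defined operationally as the location of the global maximum of the
smoothed first derivative of F(T) (equivalently the descending zero
crossing of the second derivative) — the convention under which a
derivative-based screen reports its control Tm. Implementation:

- Savitzky–Golay local-polynomial smoothing, order 2, 2 °C window
  (endpoints by polynomial extension). The derivative is taken directly
  from the local fit (`deriv=1`), which is markedly more noise-robust than
  differencing a smoothed trace.
- The peak search excludes a 2 °C edge margin, where local-fit derivatives
  are unreliable; a maximum at the search boundary is flagged `edge_peak`.
- Sub-grid refinement by the vertex of the parabola through the three grid
  points bracketing the discrete maximum — adequate at 0.1 °C grids and
  cheaper than spline refinement.
- QC flags, never exceptions: `no_transition` (peak height below an
  absolute AU/°C floor), `low_amplitude`, `edge_peak`, `multi_peak` (a
  secondary derivative peak ≥ 50 % of the main one; the tallest peak is
  still reported). The dye convention is configurable (`direction="down"`
  for dyes that lose signal on unfolding).

Measured behavior under the defaults: noise-free flat-baseline curves are
recovered to ≤ 0.03 °C across Tm ∈ [40, 80] °C; at the calibrated noise the
estimator scatters with SD ≈ 0.34 °C and negligible bias; on sloped-baseline
noise-free curves the estimate agrees with the dense-grid argmax of the
analytic dF/dT to well under one grid step.

## Hit calling

Per plate, control statistics are the mean and sample SD (n − 1) of the
QC-ok DMSO wells only — a dead control well is excluded (and recorded)
rather than allowed to inflate every threshold. ΔTm = Tm(compound) −
mean Tm(DMSO). The hit rule is |ΔTm| > k·SD with k = 5; direction labels
stabilizer/destabilizer. A degenerate SD of exactly zero (possible only in
synthetic data) falls back to a configurable absolute floor (0.5 °C) rather
than calling everything a hit.

The cascade is: initial (single-point screen) → primary (the same rule on
the triplicate mean at one high concentration) → validated (8-point
concentration series). Each stage is a subset of the previous on compounds
tested at every stage; a compound absent from a later assay is carried as
untested, never failed, and every exclusion is written to an audit log.

Concentration-dependent validation tests, per concentration, the compound's
replicate Tm values against the plate's control Tm values with a Welch
two-sample test, Holm step-down adjusted across the concentrations. A
concentration counts as significant when its adjusted p < 0.05 **and** its
mean shift exceeds 0.5 °C in magnitude; validation requires ≥ 2 significant
concentrations with a consistent sign. The effect-size condition is a
deliberate design choice: with triplicates, the Welch statistic is
anti-conservative whenever the sample variance is by chance small, and a
pure p-value rule validates null compounds at an unacceptable rate. The
whole rule is pluggable and recorded in the output (`rule_id`).

With 32 controls per 384-well plate (outer two columns), the 5×SD rule is
effectively null-free: across 10⁴ simulated no-effect wells the expected
false-hit count is ≪ 1, while planted shifts of ≥ 2 °C at control SD 0.3 °C
are recalled exactly. "Exactly" has a precise meaning here: the synthetic
truth hit set is defined by applying the same rule to the *drawn* control
sample (not the nominal SD), so recovery is a deterministic identity rather
than a probabilistic statement.

## Fingerprint clustering and selection

Compounds are encoded as path-based binary fingerprints (RDKit linear-path
fingerprint, 1024 bits) — an FP2-like dialect; bit-level identity across
fingerprint dialects is not attempted, since clustering behavior rather
than bit identity is the contract. Distance is 1 − Tanimoto similarity
(defined 0 when both sets are empty); trees are agglomerative with average
linkage (UPGMA) by default and are cut into K = 30 flat clusters.
Unparseable SMILES are quarantined with a reason, never silently dropped.

Candidate selection among validated hits: withdrawn-flagged drugs are
filtered out; known ligands of the target are routed to a controls list;
within each cluster one representative is kept — the largest |ΔTm|, ties
broken by compound id. The representative rule is a declared policy
standing in for expert judgment; both flags are annotation inputs, not
computed from external databases.

## Dose–response analysis

Specific signal is transfected-well signal minus the mean of the paired
control-cell wells (negatives clipped to zero and flagged). The 4PL model
is fitted in log₁₀-concentration space,

    y = bottom + (top − bottom) / (1 + 10^(hill (log₁₀ x − log₁₀ m))),

by bounded least squares (bottom ≥ 0; signals are fluorescence or counts),
initialized from data quantiles with 5 multistarts, best RSS winning;
standard errors come from the Jacobian at the optimum. Statuses rather than
silent numbers: `not_determined` when the fitted span within the tested
range covers ≤ 50 % of the top signal (shallow inhibitors get no midpoint),
`upper_bound` when the midpoint SE exceeds the estimate. Midpoints
(IC50/EC50) are aggregated across independent experiments as mean ± sample
SD of the best-fit values on the linear scale — the conventional reporting,
kept despite the log-normal argument, so aggregated values are directly
comparable to published tables.

Single-point competition data are reported as percent of control
(100 × mean ratio, SD over replicate ratios). Many-to-one significance
against the DMSO group uses one-way ANOVA followed by Dunnett comparisons
(Monte-Carlo p-values, internally seeded for reproducibility). Mutant
binding is normalized per experiment as (counts / band intensity) relative
to wild type before cross-experiment averaging, so batch-to-batch
expression differences cancel.

Measured recovery under the study conditions (10-point half-log dilutions,
triplicates, 5 % CV, 50 seeds per truth): median |relative error| ≈ 7 %
for truths from 37 nM to 5 µM, with no detectable sign bias.

## MD table post-processing

- **Stability**: a trajectory qualifies for end-point analysis when both
  the protein (TM Cα) and ligand RMSD series are stable through the final
  200 ns — windowed range (max − min) ≤ 1.5 Å (protein) / 2.0 Å (ligand).
  The range criterion is transparent and matches the visual judgment such
  analyses use; the tolerances are declared defaults, and stability earlier
  in a run does not qualify a trajectory whose ending is unstable, since
  the terminal stretch is exactly what frame extraction uses.
- **Enthalpy**: mean ± sample SD over the per-frame binding-enthalpy values
  (nominally 1000 frames from the stable window).
- **Main contributors**: residues with decomposed energy strictly below
  −1.0 kcal/mol ("more favorable than" read as strict), sorted ascending so
  the top contributor is listed first; ties by residue number. Residue
  labels are opaque strings with a one-letter + number parse used only for
  tie-breaking.
- **Hot spots**: recurrence counts of residues across systems' contributor
  lists, with per-state (cytoplasm-facing vs lumen-facing) breakdowns.
- **H-bonds**: retained when occupancy is strictly above 50 % of frames.

The package ships a transcribed reference table of contributor lists for 20
ligand:VMAT2 simulation systems (reserpine, tetrabenazine, salmeterol,
ziprasidone; all protonation/stereo states; both transporter states). Only
the residue ordering is known for these systems — energies were published
as ordered lists — so checks against it are ordinal: on this input the
recurrence analysis returns Y342 (10 systems), F335 (10) and V233 (9) as
the most frequent contributors, and I309 (7) confined entirely to
lumen-facing systems.

## Pipeline and reproducibility

A single flat configuration (dataclass, YAML-loadable, unknown keys
rejected) drives simulate → Tm → screen → primary → validate → cluster →
dose–response → MD report. Every stochastic stage derives its seed
deterministically from the global seed and the stage name, so one seed
yields byte-identical summaries across runs. Realized per-plate thresholds
are logged so every hit call is auditable.

The end-to-end demo uses 1280 compounds (four 384-well plates at 352
compounds + 32 controls), 5 % planted binders with |ΔTm| ∈ [2, 12] °C of
both signs, per-compound thermal-shift saturation midpoints of 0.1–10 µM
(medium–high-affinity binders saturate within the screened range), and
IC50 determination for the selected candidates. Problem sizes throughout
(200-seed estimator sweeps, 10⁴ null wells, 50 seeds per IC50 truth, one
1280-compound pipeline) were chosen so the full suite runs in minutes on a
single CPU while keeping Monte-Carlo error far below every asserted margin.

## Known limitations

- The two-state model cannot represent multi-domain or partially reversible
  unfolding; `multi_peak` flags such wells but no deconvolution is done.
- The validation rule (Welch + Holm + effect floor) is a declared stand-in:
  the criterion by which real screens thin primary hits to validated hits
  involves judgment the package does not model.
- Cluster count K = 30 and the representative rule are conventions, not
  optima; selection outcomes depend on them.
- 4PL fits assume independent homoscedastic residuals after background
  subtraction; replicate correlation within plates is not modeled.
- Reference-table checks are ordinal only (no energies were published), and
  synthetic MD tables plant hot spots directly rather than deriving them
  from any structural model.
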