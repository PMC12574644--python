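# Methods

This note records the models behind `phageforge`, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish.

## 1. ssDNA design

### Model

A design is specified by (length *L*, CG fraction *f*, hexamer fraction
*h*, seed). "CG fraction" is defined as the fraction of nucleotides that
belong to deliberately placed CG dinucleotides, *f* = 2*N*/*L* with
*N* = round(*f·L*/2) dimers; at *L* = 1415 and *f* = 0.27 this places 191
dimers. (The alternative reading — mononucleotide C+G content — would not
pin down a dimer count at all; the dimer-based definition is the one under
which the reference conditions are self-consistent.)

Constraints maintained at every stage:

- flanks between dimers contain no CG, do not start with C and do not end
  with G (the boundary rule binds at bare dimers; a hexamer motif shields
  its internal dimer with its own A/T context);
- no repeated 9-mer anywhere (equivalent to "no direct repeat of ≥9 nt");
- no 13-mer whose reverse complement occurs elsewhere in the sequence
  ("no hairpin stem longer than 12 nt"); arms may overlap and no minimum
  loop is imposed, a conservative superset of foldable hairpins;
- hexamer-set motifs (`AACGTT`, `GACGTT`) occur only where deliberately
  inserted — the generator and every repair pass refuse to create one by
  accident, so a motif census equals the number of conversions exactly.

### Generation and repair

The scaffold distributes *N* dimers over *N*+1 gaps, evenly with seeded
jitter of ±25% of the mean gap (exact even spacing would imprint a
periodicity that seeds long repeats). Flank bases are sampled left to
right; among the boundary-legal bases the sampler prefers those that do
not complete a 9-mer already seen, which keeps the nascent scaffold
essentially repeat-free.

Repairs that must preserve composition are A↔T flips at unprotected
positions: they cannot change C/G counts, hence cannot create or destroy a
CG dimer. The flip chosen for a flagged repeat family is found by greedy
descent on the total repeat multiplicity (candidates ordered first
instance first, leftmost first), with a per-position flip budget and
plateau moves. A strictly leftmost rule without the descent criterion is
not convergent in practice: a flip that breaks one window frequently
completes another, and the literal rule ping-pongs between the two.

A↔T flips alone cannot fix every collision: a window whose free positions
carry no A or T is immutable under them. The package therefore performs
*context refinement* at generation time (at the end of scaffolding, and
after hexamer insertion): a greedy local search over full-alphabet
substitutions at unprotected flank positions, with the joint objective
(repeat excess + hairpin-pair count), incremental k-mer-census deltas for
speed, coordinated pair moves, and seeded random kicks with escalating
burst size when the descent stalls (iterated local search). Hairpin pairs
are counted through the identity #pairs = (S − D)/2 with
S = Σ_w cnt(w)·cnt(rc(w)) and D the palindromic diagonal, which gives an
O(k) update per candidate substitution. The A↔T repair passes then run as
the final stage and are verified to be fixpoints on finished designs.

### Hexamer conversion

Conversion replaces the 2-nt dimer by the 6-nt motif (net +4 nt per site),
because converted designs package longer ssDNA and assemble longer phages;
an in-place mode (overwrite the 6-nt window centred on the dimer,
length-preserving) is available behind a flag. Sites are drawn by seeded
permutation while avoiding conversion of two adjacent dimers — two motifs
5 nt apart leave almost no free context between them, the dominant source
of unrepairable windows. Motifs start in alternation and are then
re-chosen per site by a greedy sweep minimizing created repeats. A site
whose left neighbour is C receives an A-starting motif, otherwise the
junction `C|G...` would create an extra CG dimer.

The hardest constraint satisfaction in the package is the CpG40 condition
(76 protected identical motifs among 191 dimers in 1719 nt): the 9-mers
straddling a motif are distinguished only by ~3 free flank bases on either
side, loading the available "codes" to roughly 70-90% of capacity. Beyond
single-base moves, a block-reassignment pass re-samples all free context
bases around a colliding motif jointly (seeded draws, best-of-300) before
the general refinement runs. With all passes combined, the reference
conditions design in about 1-3 s (1415 nt) and under 4 s (6261 nt) on one
CPU, without restarts, for every seed tried; a restart mechanism (fresh
scaffold from a derived seed, up to 5 times) backs the search.

### Tunables

| parameter | default | meaning |
|---|---|---|
| `min_repeat_len` | 9 nt | shortest forbidden direct repeat |
| `min_stem_len` | 13 nt | shortest forbidden inverted-repeat stem |
| `hexamer_set` | AACGTT, GACGTT | canonical murine TLR9 hexamer contexts |
| jitter | ±25% of mean gap | dimer placement randomness |
| flip budget | 6 per position/pass | plateau ping-pong bound |
| restart cap | 5 scaffolds | unresolvable-repair fallback |
| iteration cap | 10·L mutations/pass | hard stop |

## 2. Chromatogram deconvolution

### Model

Within the analysis window the trace is
y(t) = P_wt(t) + P_ag(t) + b₀ + b₁t, each peak a sum of two Gaussians
with closed-form area √(2π)(a₁σ₁ + a₂σ₂); the display ratio is the
antigen peak's area share. The baseline is linear; raw areas are compared
without extinction-coefficient correction between the two pVIII species
(a correction hook exists on the result object — multiply areas before
forming the ratio).

### Identifiability, and the constraints that restore it

The fully free 14-parameter model is not identifiable for the ratio: at
equal residual, any 2+2 regrouping of the four Gaussians into "peaks"
reproduces the same summed curve, and a shoulder-sized component can
absorb the main peak's tail instead of the actual shoulder. Three modeling
choices, defaults in `fit_double_gaussians`, restore a well-posed problem:

1. **Tails trail.** Each peak is a core Gaussian plus a tail Gaussian
   0–0.25 min *after* its core (reversed-phase protein peaks tail; they do
   not front).
2. **Analytes are separated.** The antigen core elutes ≥0.3 min after the
   wild-type core (flag to relax, with post-fit relabeling by
   area-weighted effective center). 0.3 min exceeds the tail bound, so a
   "peak" can never be another peak's tail.
3. **Shared shape.** Both peaks share one shape vector (σ₁, σ₂, tail
   offset, tail area fraction) and differ only in area and retention — the
   analytes are near-identical pVIII variants on one column. This removes
   the ill-conditioned area trade-off in the overlap region. The free
   14-parameter fit remains available (`share_shape=False`).

### Initialization and optimization

Deterministic initializer: robust linear baseline through the window
edges; Savitzky–Golay smoothing; global maximum seeds the main peak with
FWHM/2.355 widths; a resolved secondary local maximum (noise-scaled
prominence) seeds the shoulder, otherwise a single-peak pre-fit is
subtracted and the most prominent residual bump seeds it; failing both,
the shoulder starts at the configured offset (0.6 min) with 2% amplitude
so the fit may drive it to zero. A flat or empty window raises.

Bounded trust-region least squares (`scipy.optimize.least_squares`),
tolerances 1e-12, with multi-start (separation seeds 0.45/0.6/0.9/1.2 min,
then two jittered restarts) triggered only when the first fit's RMSE
exceeds the trace's own noise floor (1.4826·MAD of the high-frequency
component). Non-convergence is reported via `converged=False`.

### Synthetic chromatograms

`SimSpec` defaults emulate the reference separation: wild-type core at
51.3 min, shoulder +0.6 min, both peaks sharing the shape (core σ 0.18
min, tail σ 0.35 min at +0.18 min carrying 35% of the area), total area
100 response-units·min, window [48.3, 55.3] min sampled every 0.01 min,
optional linear drift and Gaussian noise. The generative antigen area
fraction is exact by closed form (verified against quadrature to 1e-6).

Measured estimator performance under these conditions: noiseless recovery
exact to <0.01 pp at every tested ratio including 5% and 90%; shoulder
offsets 0.3/0.6/1.2 min all exact; with noise at 1% of the trace maximum,
mean error over 20 seeds ≈0.1 pp (worst single seed ≈1.5 pp); recovered
ratio is monotone in the generative truth; a zero-antigen trace yields
ratio 0.

What the simulator does not emulate: non-Gaussian peak shapes (exponential
tailing), retention-time drift between runs, wavelength-dependent response
differences between the two species, and co-eluting contaminants. Passing
these tests therefore validates the estimator under the stated peak model,
not the chromatography itself; on real traces the shared-shape assumption
should be checked against the fit RMSE and, if violated, relaxed with
`share_shape=False`.

## 3. Capsid biophysics

Masses use the standard IUPAC average and monoisotopic residue tables
(embedded constants; cross-checked against pyteomics in the test suite to
0.2 Da over the 50-residue coat protein). The chain mass is Σ residues +
one water; linear positive-mode MALDI observes the singly protonated ion,
so the predicted peak is average mass + 1.00728 Da. For the canonical
mature 50-residue wild-type pVIII this gives 5239.05 → 5239 Da. Fusion
pVIII masses require the fusion sequence as input; no signal-peptide
cleavage prediction is attempted.

The length map is a one-parameter line through the origin fitted by least
squares to the four reference pairs (721, 1447, 3241, 6261 nt ↔ 100, 200,
400, 800 nm): slope 0.1274 nm/nt. Calibration residuals (+8, +16, −13,
+2 nm) motivate the documented ±20% accuracy band; predictions outside
700–6300 nt extrapolate.

## 4. Known limitations

- The repeat/hairpin definitions are exact-match; thermodynamic secondary
  structure (mismatches, G·U-like wobbles, bulged stems) is out of scope.
- Design feasibility is empirical, not proven: at substantially higher CG
  or hexamer densities than the reference conditions the constraint system
  can saturate, and the pipeline then surfaces an explicit unresolvable
  error after its restarts rather than degrading the constraints.
- The deconvolution assumes exactly two analytes in the window.
- `in_place` hexamer conversion requires a clear 6-nt window per site and
  skips sites whose context is protected.
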