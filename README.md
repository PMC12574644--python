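# phageforge

Computational toolkit for programmable M13 phage nanovaccines: single-base
design of immunostimulatory packaged ssDNA, double-Gaussian deconvolution of
capsid-protein chromatograms, and small biophysics calculators for
MALDI-TOF peaks and phage filament length.

## The problem

The filamentous phage M13 is an attractive cancer-vaccine chassis: antigen
peptides can be fused to the N-terminus of its major coat protein pVIII, and
the packaged single-stranded DNA is non-coding in a phagemid system, so its
sequence is a free design space. Three particle properties follow directly
from that sequence:

- **Adjuvanticity** — unmethylated CG dinucleotides (CpG motifs) agonize
  TLR9; more CG dimers, and especially CG dimers embedded in the canonical
  murine hexamers `AACGTT`/`GACGTT`, mean stronger innate stimulation.
- **Length** — the filament length is proportional to the packaged ssDNA
  size (≈0.127 nm per nucleotide).
- **Antigen density** — the fraction of antigen-fusion pVIII among all
  pVIII copies, measured by reversed-phase HPLC of the lysed capsid, where
  wild-type pVIII elutes as the main peak (≈51.3 min under the reference
  gradient) and antigen pVIII as a trailing shoulder.

`phageforge` implements the computational layer for all three: the sequence
design engine with its constraint system, the chromatogram simulator and
peak deconvolution that quantify the display ratio, and the mass/length
calculators used to identify capsid species.

## The design rules

A designed ssDNA of length *L* with CG fraction *f* carries
*N* = round(*f·L*/2) CG dimers (so 2*N*/*L* = *f*), evenly spread with
seeded jitter. Three constraints hold everywhere:

1. flanking DNA between CG dimers is drawn from {A,T,C,G} but may not start
   with C or end with G, and contains no incidental CG — the dimer census
   is exact by construction;
2. no direct repeat of 9 bases or longer (any longer repeat contains a
   repeated 9-mer, so scanning 9-mers is sufficient);
3. no hairpin stem: no intra-sequence inverted repeat longer than 12 bases
   (windows of 13 whose reverse complement occurs elsewhere).

Violations are repaired by A↔T point mutations, which cannot change C/G
content and therefore preserve the CG census. A chosen fraction of dimers
can be converted to CpG hexamers (`CG` → `AACGTT`/`GACGTT`, +4 nt per
site); converted motifs are protected so later repairs cannot destroy them.

The display ratio is estimated by fitting the chromatogram window as two
peaks plus a linear baseline, each peak a sum of two Gaussians
(area = √(2π)·(a₁σ₁ + a₂σ₂)):

    ratio = area_antigen / (area_antigen + area_wt)

## Worked example

Design the reference immunostimulatory ssDNA (1415 nt, 27% CG), convert
40% of its dimers to hexamers, and predict the phage that results:

```python
from phageforge import DesignSpec, design, phage_length_from_ssdna, protein_mass
from phageforge.biophysics import WT_PVIII_MATURE

r = design(DesignSpec(length_nt=1415, cg_fraction=0.27,
                      hexamer_fraction=0.4, seed=1))
print(len(r.sequence), r.report.n_cg_dimers, r.report.n_hexamer_embedded,
      round(r.report.hexamer_pct_of_cg, 1), r.report.clean)
print(round(phage_length_from_ssdna(len(r.sequence))))
print(round(protein_mass(WT_PVIII_MATURE).maldi_mz))
```

prints

```
1719 191 76 39.8 True
219
5239
```

— a constraint-clean 1719-nt sequence in which all 191 CG dimers survive
conversion and 76 of them (≈40%) sit inside canonical hexamers; the phage
packaging it is predicted ≈219 nm long (the conversion grows the particle
from ≈200 nm), and wild-type pVIII is expected at 5239 Da in linear
positive-mode MALDI ([M+H]⁺).

Quantify a display ratio from a chromatogram (here a simulated one with a
13.6%-area shoulder):

```python
from phageforge import SimSpec, simulate_chromatogram, fit_double_gaussians

chrom, truth = simulate_chromatogram(SimSpec(antigen_area_fraction=0.136))
fit = fit_double_gaussians(chrom)
print(round(100 * fit.display_ratio, 1), fit.converged)
```

prints `13.6 True`.

The same operations are exposed on the command line:

```bash
phageforge design --length 1415 --cg-fraction 0.27 --hexamer-fraction 0.4 \
    --seed 1 --out out/
phageforge simulate-hplc --truth 0.136 --noise-sd 0 --seed 1 --out sim.csv
phageforge fit-hplc --csv sim.csv --out fit.json
phageforge mass --seq AEGDDPAKAAFNSLQASATEYIGYAWAMVVVIVGATIGIKLFKKFTSKAS
phageforge length --nt 1719
```

Every file-writing invocation drops a `*.manifest.json` (version, resolved
configuration, input digests, outputs) so any run can be reproduced
exactly. All coordinates in reports are 0-based, half-open, 5'→3'.

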