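# fn3kit

A toolkit for the computational side of FN3 monobody phage-display
campaigns — the kind used to engineer paralog-selective binders of
conserved protein-interaction modules such as the tandem PDZ domains of
PSD-95 and its DLG-family paralogs (SAP97, SAP102, PSD-93).

It is written for protein engineers running directed-evolution selections
on the tenth fibronectin type III (10FN3) scaffold and for the biophysics
that follows: it covers everything from designing the degenerate loop
library to fitting the binding constants of the isolated clones and
mapping their epitopes by NMR.

## What it does

**Library design** (`fn3kit.library_design`) — NNK degenerate-codon
expansion and amino-acid statistics, per-length mutagenic oligo sets for
the BC (5–9 codons at 10FN3 position 25) and FG (7–13 codons at position
75) loops, exact big-integer theoretical diversity
(Σ₅⁹ 32^l × Σ₇¹³ 32^m ≈ 10^33.1 DNA variants), stop-free fractions, and a
birthday-model lower confidence bound on realized library size from
colony sequencing.

**Clone triage** (`fn3kit.clone_qc`) — orientation and reading-frame
resolution of Sanger colony reads against the display cassette, exact
screening for the required restriction sites (HindIII/BamHI/NotI/KpnI),
and rejection of clones with stop codons or ambiguous bases inside the
variable loops.

**Clustering** (`fn3kit.clustering`) — Needleman–Wunsch global alignment
of loop peptides, a fraction-identity similarity graph, Markov clustering
(MCL: alternating stochastic-matrix expansion and inflation), and
per-cluster medoid/consensus reports.

**Selection analytics** (`fn3kit.selection`) — phage titers from OD268
(1.0 ⇔ 5×10¹² phage/mL) or colony counts, per-round enrichment ratios
(target elution / control elution), and phage-ELISA specificity indices
with background subtraction.

**Binding fits** (`fn3kit.binding`) — closed-form simulation and global
fitting of 1:1 Langmuir single-cycle SPR kinetics (kon, koff, Rmax with
RI = 0 and tc = 10⁸ fixed), steady-state hyperbola affinity, theoretical
Rmax, the one-set-of-sites (Wiseman) ITC isotherm with
displaced-volume correction (N, K_D, ΔH), depletion-corrected direct
fluorescence-polarization fits, the exact ternary competition equilibrium
(cubic in free receptor) for K_I, Cheng–Prusoff "one site – fit Ki"
analysis of competitive pull-down densitometry, and effective
concentrations C_eff = K_D(A)·K_D(B)/K_D(AB) of tethered bivalent binders.

**Epitope mapping** (`fn3kit.csp`) — combined amide chemical-shift
perturbations Δδ(N,H) = √(0.14·Δδ₁₅N² + Δδ₁HN²) between free and bound
¹⁵N-HSQC spectra, classification at 0.3/0.15 ppm thresholds with
broadened and missing-data classes, and epitope overlap comparison.

**Synthetic fixtures** (`fn3kit.simulate`) — seeded generators for every
input class (96-colony Sanger runs with planted clone families, reverse
reads and base errors; noisy versions of every titration type; shift
tables with planted epitope patches), each with a ground-truth record.

## Worked example

Simulate a 96-colony sequencing run from 11 planted clone families,
triage and cluster it, and fit a simulated ITC isotherm:

```sh
fn3kit simulate --seed 1 --out sim
fn3kit qc --input sim/reads.fasta --scaffold sim/scaffold.json --out qc
fn3kit cluster --input qc --out cluster
fn3kit fit --kind itc --input sim/itc.csv --out fits
```

which prints

```
qc: 96 reads, 89 valid
cluster: 11 clusters over 89 valid clones
fit itc: n=1, kd=6.7e-08, dh_kcal=-10, c_value=417.9
```

Seven reads fail QC (sequencing errors destroyed a required restriction
site), the 89 valid clones cluster back into exactly the 11 planted
families, and the one-set-of-sites fit recovers the planted 67 nM
affinity, unit stoichiometry and −10 kcal/mol enthalpy from the simulated
0.5 µL + 29 × 1 µL injection series (Wiseman c ≈ 418).
`cluster/cluster_summary.tsv` lists one row per cluster with its size,
medoid representative and consensus loop peptide, and `fn3kit report`
aggregates everything into a single HTML page.

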