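# Methods

## Library design and diversity accounting

Degenerate codons are expanded exhaustively with equal per-base weights,
so NNK (N = A/C/G/T, K = G/T) yields 32 codons of probability 1/32 each.
Amino-acid distributions come from translating the expansion with the
standard genetic code (NCBI table 1); the single NNK stop is amber (TAG),
counted as a stop by default because the clone-triage filter treats any
in-loop stop as invalid. Amber suppression (TAG → Gln, supE hosts) is
available behind a flag and is off by default.

Theoretical diversity is computed in exact big-integer arithmetic —
values of order 32²² overflow the integer precision of doubles — with a
log10 companion value. Per loop, per-length variant counts are summed
over the length range and loops multiply; the per-length oligos are
pooled equimolar, so the stop-free fraction averages the per-length
survival probabilities (1 − 1/32)^L with equal weights.

The library-size lower bound treats colony sequencing as uniform draws
from an unknown number D of distinct clones. With zero observed
collisions the exact product P(no collision) = Π_{i<n} (1 − i/D) is
inverted for the smallest D at which the observation is not surprising at
the chosen confidence; with positive collision counts the Poisson
approximation with mean C(n,2)/D is used. How a sequencing run of 96
colonies is best converted into a library-size estimate is genuinely
open — electroporation transformant counts and collision statistics are
both defensible — so the bound is provided as one option and the
transformant count is simply an input the user may prefer.

## Clone triage

Reads are oriented by searching both strands for 18-nt fixed-flank
anchors of each diversified loop, allowing ≤ 2 substitutions (Sanger
phagemid reads are long and low-error); ties resolve deterministically
(fewest mismatches, then leftmost hit, then forward strand). When no
anchor survives, a six-frame protein alignment against the cassette
translation decides orientation and frame. Restriction-site checks are
exact matches on the oriented read — a mutated site is genuinely
non-functional for cloning, so no mismatch tolerance applies. Loops are
the in-frame codons strictly between the anchor flanks; stop codons and
ambiguous bases inside a loop invalidate the clone. All checks run and
accumulate reasons rather than short-circuiting, so a report can show
every defect of a bad read. "Variable regions" are interpreted as the
loops only; screening the whole open reading frame for stops is a flag
(`screen_whole_orf`) because the boundary of the historical rule is not
documented. Base qualities, when present, are carried but unused.

The default display cassette used by the fixtures is a synthetic
construct assembled in code: the wild-type 10FN3 protein back-translated
with one fixed codon per residue, framed by HindIII, a ribosome-binding
spacer, and KpnI/NotI/stop/BamHI elements downstream, with codon
positions following wild-type 10FN3 numbering (PDB 1FNA). The fixed codon
table was chosen so no restriction site of the cassette can arise inside
the coding region.

## Clustering

Needleman–Wunsch is implemented with linear gap penalties and a
deterministic traceback (diagonal over up over left). Identity scoring
(match 1 / mismatch −1 / gap −2) is the default because the compared
sequences are short loop peptides and fraction identity is the quantity
the similarity graph consumes; BLOSUM-style matrices can be passed in.
Fraction identity is matches over alignment length.

The similarity graph zeroes off-diagonal identities below an edge
threshold, default 0.6. The threshold sits well above the ~0.3–0.5
background identity of unrelated random NNK loop pairs (which otherwise
densely connects the graph and causes MCL to absorb small families) and
well below the ≥ 0.9 identity of same-family clones at realistic Sanger
error rates; family recovery on planted fixtures is insensitive to the
exact value across 0.5–0.7.

MCL uses canonical settings (expansion 2, inflation 2.0, prune 1e-5 after
column renormalization, self-loop weight 1, convergence at max-change
< 1e-8 within 100 iterations). Clusters are read from attractor rows;
overlapping attractor supports merge, unclaimed nodes follow their
strongest column, and the result is always a partition. Consensus
sequences are built against the cluster medoid (highest mean identity,
ties to the smallest id) from pairwise alignments — a deliberate
simplification; full progressive multiple alignment is out of scope.

## Selection analytics

Titer conversions are linear: OD268 × 5×10¹² phage/mL × dilution, and
colonies × dilution / plated volume. The enrichment ratio of a panning
round is eluted-target titer over eluted-control titer; a zero control
returns an explicit unbounded sentinel rather than a number. Two round
stringency schedules (100/50/25 nM and 100/20/4 nM) ship as named presets
because both appear in the source protocols; neither is hard-coded as
truth. ELISA signals subtract the per-target blank mean and clip at zero,
which makes the specificity index invariant to any constant offset
applied to a target's wells including its blanks. The binder call
(primary signal > 3 blank standard deviations) is this package's
convention; no quantitative cut-off is documented for the historical
"strong response" language.

## Binding fits

All fits use trust-region least squares (`scipy.optimize.least_squares`)
with 8 deterministic multi-starts: the method-of-moments guess plus
seeded log-space perturbations, so fits are reproducible given data and
seed. Rate and equilibrium constants are fitted in log space.

**SPR single-cycle kinetics.** The 1:1 Langmuir model has the closed-form
piecewise solution R(t) = Req + (R0 − Req)·e^(−(kon·C+koff)·t) during
association (Req = kon·C·Rmax/(kon·C+koff)) and R0·e^(−koff·t) during
dissociation, continuous across the five two-fold-ascending injections
(120 s contact, 70 s inter-injection dissociation, 600 s final). Bulk
refractive index is fixed at 0 and the mass-transfer constant at 10⁸,
i.e. transport is ignored; the two-compartment transport model is out of
scope. K_D ≡ koff/kon holds exactly (it is computed, never fitted
separately). Biphasic sensorgrams — which a 1:1 model cannot describe —
are detected by a Wald–Wolfowitz runs test on the fit residuals (|z| > 3,
gated on a residual norm above 10⁻⁴ of the response scale so that
numerically perfect fits are never flagged) and reported as a flag, not
modelled.

**ITC.** The one-set-of-sites (Wiseman) isotherm solves the quadratic
mass balance θ² − θ(1 + Xr + Kr) + Xr = 0 per injection
(Xr = Xt/(N·Mt), Kr = K_D/(N·Mt)); cumulative heat is N·θ·Mt·V0·ΔH and
per-injection heats are cumulative differences plus the standard midpoint
displaced-volume correction (cell and syringe species diluted by the
cumulative injected volume). An ideal-geometry mode without displacement
(`volume_correction="none"`) exists for limit analysis, where total heat
converges exactly to N·Mt·V0·ΔH at saturation. The 0.5 µL pre-injection
is excluded from fits. Fits return N, K_D, ΔH on heats normalized per
mole of injectant; a Wiseman c value (N·Mt/K_D) outside [0.1, 10⁴] emits
a reliability warning without failing.

**Fluorescence polarization.** Direct titrations use the exact
single-site depletion quadratic for the tracer bound fraction
FB = ((K_D+Lt+Rt) − √((K_D+Lt+Rt)² − 4·Lt·Rt))/(2·Lt), with mP linear in
FB; plateaus are fitted unless supplied. Competition uses the exact
ternary equilibrium: free receptor is the physical root of
R³ + aR² + bR + c = 0 (a = K_L+K_I+Lt+It−Rt,
b = K_L·K_I + K_I(Lt−Rt) + K_L(It−Rt), c = −Rt·K_L·K_I), solved by
companion-matrix root finding with one Newton polish and verified against
an iterative solver to 1e-9 relative. Tracer concentration and tracer K_D
are constrained constants; only K_I and plateaus are fitted. Curves too
flat to constrain K_I return a lower-bound flag.

**Competitive pull-down.** Densitometry normalized to the zero-competitor
lane (100%) is fitted with a four-parameter logistic in log competitor
whose midpoint is tied to K_I by Cheng–Prusoff,
IC50 = K_I(1 + [tracer]/K_D,tracer). Known limitation: Cheng–Prusoff
assumes no ligand depletion, so under the strongly depleting conditions
of a bead pull-down (receptor and tracer near the tracer K_D) the fitted
K_I is biased high — about two-fold against the exact-equilibrium truth
in the synthetic round trips — which is a property of the assay model
itself, not of the optimizer. Normalization to the zero-competitor lane
is a convention; when proteolyzed ligand contaminates the competitor the
correct reference is ambiguous.

**Effective concentration.** C_eff = K_D(A)·K_D(B)/K_D(AB) for two
binding modules A and B tethered into one fusion — the thermodynamic
cycle's measure of the local concentration each module presents to the
other. Typical monobody/peptide module affinities (10⁻⁷–10⁻⁶ M) fused
into subnanomolar binders give C_eff in the tens-of-millimolar range.

## Chemical-shift-perturbation mapping

Δδ(N,H) = √(0.14·Δδ₁₅N² + Δδ₁HN²), with the 0.14 weight multiplying the
squared ¹⁵N shift — the form is implemented exactly as commonly printed;
the also-common variant with the weight inside the square,
(0.14·Δδ₁₅N)², is available behind a flag. Classes are strong
(> 0.3 ppm), moderate (0.15–0.3 ppm) and background, applied globally to
every dataset; peaks broadened out in the bound state are classed
`broadened` regardless of any measurable shift, and residues flagged
missing or ambiguous in either state are `no-data`. The classes are
exhaustive and mutually exclusive. Epitope comparison takes set overlap
and Jaccard on the strong ∪ moderate sets. Shift tables are plain CSV;
peak picking, assignment and exchange-regime analysis are out of scope.

## Synthetic data and what the tests show

The generators define the study conditions: 96 reads from 11 clone
families (every family represented at least once), NNK-consistent loops
with BC 5–9 and FG 7–13 codons, 50% reverse-orientation reads, a 0.3%
per-base substitution rate (about one error per read, typical of trimmed
Sanger traces), and optional planted defects (in-loop stops, destroyed
sites, 5′ truncations) at stated rates. Titration fixtures use the
standard geometries (five two-fold SPR injections; 0.5 µL + 29 × 1 µL ITC
into a 200 µL cell at 28 µM with a 0.30 mM syringe; 50 nM FP tracer;
duplicate pull-down lanes) with Gaussian signal noise, and Poisson noise
for colony counts — matching the physical measurement classes. Shift
tables plant a contiguous 12-residue epitope patch with a smooth
amplitude profile.

What passing tests do **not** show about real data: the read generator
has no chromatogram-level artefacts (miscalls correlated with peak
compression, quality roll-off), the titration noise is homoscedastic
whereas instrument noise often is not, and planted families are
unambiguous by construction, so clustering performance on borderline
real libraries (families separated by one substitution) is not
demonstrated. Biological effects — amber suppression efficiency, display
bias, target avidity on beads — are outside the simulated physics.

Numerical conventions throughout: concentrations SI molar internally
(RU, µcal, mP at I/O boundaries only), seeds propagate to every random
draw through `numpy.random.default_rng`, and degenerate inputs (empty
designs, zero controls, all-equal responses) raise or return sentinels
rather than NaN. Problem sizes in the test suite (for example 20-seed
recovery grids, 12-node planted graphs, 200-pair alignment oracles) were
chosen as the smallest sizes at which the checked property is
statistically meaningful.
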