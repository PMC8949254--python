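# Methods

This note records the models, numerical choices, and deliberate design
decisions behind `gdtandem`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Module catalog and assembly

The catalog ships the printed building blocks: the calmodulin Ca²⁺-loop
metal-binding site M = `DKDGDGTITTKEL` (repurposed for Gd³⁺, whose ionic
radius of 0.99 Å nearly matches Ca²⁺'s 1.00 Å), ELP units with Ser or Tyr
guests (`VPGSG`, `VPGYG`), the F3 nucleolin ligand
`KDEPQRRSARLSAKPAPPKPEPKPKKAPAKK`, the `(G₄S)₂(G₃S)` linker, and the RGD
unit `AVTGRGD(SG)₅GS`. Coordinates are 0-based half-open everywhere; spans
tile the assembled sequence losslessly, with Gly-Ser dipeptides introduced
by restriction-site junctions labelled `junction`.

Two junction policies exist because the exact placement of
restriction-derived Gly-Ser pairs inside oligo-assembled blocks is a
genuinely open design choice: `seamless` (default for the W4 interior,
which is built from annealed oligos rather than tandemized fragments) and
`gly_ser_at_tandem_junctions` (default for the expression constructs, whose
repeated blocks were joined through the BglII/BamHI hybrid site that
encodes Gly-Ser). Both are exposed per recipe; motif counts are identical
under either.

The EmGFP reporter's sequence is not part of the module definitions; the
catalog entry is a clearly-marked synthetic GFP-like placeholder, swappable
via `build_catalog(emgfp_sequence=...)`. Whole-construct properties that
depend on it (total MW, whole-protein pI) are therefore not asserted
anywhere.

ELP content is reported in two conventions because both appear in practice:
`ELP_units` counts non-overlapping `VPGXG` pentapeptides (X ≠ Pro) — the W4
block has 14 — and `ELP_blocks` counts E-type module spans (E(Y), E, Eend) —
the W4 block has 5. RGD counting uses the literal core `AVTGRGD`; the
`(SG)₅GS` tail is linker.

## Physicochemical calculators

GRAVY is the mean Kyte–Doolittle hydropathy per residue (scale imported from
Biopython's published data table). Net charge is a Henderson–Hasselbalch sum
over D/E/C/Y side chains (negative) and H/K/R plus the N-terminus
(positive), using the Bjellqvist pKa set as served by the ExPASy tools,
including its residue-specific terminal pKa values (e.g. N-terminal Gly
7.50, C-terminal Glu 4.75). This specific set is required to reproduce the
reference pI of the F3 peptide (10.77); it is shipped as a named, swappable
`PKaSet`. pI is found by bisection of the charge function on [0, 14] to a
0.01 default tolerance — the termini guarantee a single root because charge
is non-increasing in pH. The independent cross-check in the test suite is
Biopython's `ProteinAnalysis`, which implements the same published
algorithm separately.

Extinction coefficients use the Trp (5500) / Tyr (1490) / cystine (125)
counting rule with all Cys assumed reduced by default — the designed
carriers avoid Cys entirely for folding reasons. The instability index is
the Guruprasad dipeptide-weight sum (DIWV table imported from Biopython's
data module), flagged unstable above 40; the aliphatic index is Ikai's
`100(fA + 2.9 fV + 3.9(fI + fL))`. Molecular weight uses average isotopic
residue masses. N-end-rule half-life estimates for reticulocyte lysate,
yeast, and *E. coli* are a lookup on the N-terminal residue.

Known discrepancy: reconstructing the four-site metal core from the printed
modules alone gives GRAVY ≈ −0.43 and pI ≈ 4.2, not the −0.469 / 4.28
quoted for the original 4MBS domain; the exact boundary residues of that
domain are not recoverable from the module definitions. The balanced-design
ordering (acidic core < W4 block < cationic F3) is asserted instead of the
absolute values.

## CDS design

Reverse translation draws from an *E. coli* K-12 codon-usage table shipped
inline (fractions per amino acid). Non-diversified residues always take the
most frequent codon compatible with the nucleotide alphabet; Ser/Thr/Leu
(the configurable `diversify_residues`) are sampled frequency-weighted among
codons with usage ≥ 0.1. The A/C-restricted mode reproduces the 15 nt
initiation insert `ACCACCCCACAACAC` for Thr-Thr-Pro-Gln-His by
frequency tie-breaking within the {A,C} alphabet (ACC > ACA, CCA > CCC,
CAA and CAC forced).

Repeat breaking is greedy re-sampling: while the longest perfect direct
repeat exceeds `max_repeat_len` (default 12 nt), the codon nearest the
repeat's midpoint is resampled to a different synonym, up to a bounded
iteration count (default 500). The floor is set by runs of non-diversifiable
codons (e.g. `DKDGDG` inside the metal site is 18 fixed nucleotides when
only S/T/L vary), so heavily repetitive constructs converge to ~14–40 nt
rather than the nominal 12; the mode-codon baseline for the same W8 dimer
is > 500 nt. Direct repeats only are scored (the in-vivo instability
mechanism of interest); the scorer is a sorted suffix array with Kasai's
adjacent-LCP argument, validated against a brute-force substring
enumeration. Forbidden-site avoidance rescans both strands after every
repair and resamples a codon overlapping any hit; infeasibility (a residue
with no compatible codon) is reported with the residue and constraint.

GC content is advisory only (warning outside 30–70% per 100 nt window), as
no hard bounds are part of the design rules.

Oligo splitting caps every synthesis oligo at 63 nt — the practical limit
beyond which single-nucleotide deletions from incomplete phosphoramidite
coupling accumulate — tiling the top strand exactly and shifting
bottom-strand windows by the overlap (default 12 nt) so every junction on
one strand is bridged by paired bases on the other.

## Cloning simulation

The duplex model stores the full top strand plus typed end descriptors
(5′/3′/blunt, overhang written 5′→3′ on the protruding strand). A 5′
overhang protrudes on the top strand at a left end and on the bottom strand
at a right end (mirrored for 3′ overhangs), which makes top strands
concatenate exactly under ligation and keeps nucleotide count conserved
through digest/ligate round trips. The registry ships BamHI (G^GATCC),
BglII (A^GATCT), EcoRI (G^AATTC), NcoI (C^CATGG), PstI (CTGCA^G) with
standard cut offsets; all five have palindromic recognition sites.

Ligation enumerates circular products combinatorially, each fragment used
at most once per product in either orientation, capped at 4 fragments by
default (tandemization beyond the cap is represented by the fixpoint
characterization, not exhaustive enumeration). Junctions are classified by
their 6 bp seam context: homologous seams regenerate the parent site;
BglII×BamHI seams form the hybrids `GGATCT`/`AGATCC`, cleavable by neither
enzyme and encoding Gly-Ser in frame 0. Dephosphorylation is a boolean: two
dephosphorylated ends cannot ligate, which is how vector self-closure is
suppressed in staged protocols.

The one-tube cycle models orientation selection, not kinetics. Cleavable
junctions that touch the vector are reversible — cutting them merely
relinearizes material that religates into the same class, and the intended
product deliberately keeps its flanking sites for the next cloning round —
so persistence is decided by insert-derived junctions: a circular product
survives iff no insert–insert junction regenerates a site of the pair.
Head-to-tail insert pairs form only hybrids and persist; head-to-head and
tail-to-tail pairs regenerate BglII or BamHI sites and are destroyed. The
test oracle rebuilds every orientation combination by plain string
concatenation and filters on recognition-site positions, independently of
the engine's junction metadata.

Because the chemistry cannot distinguish the orientation of a *single*
insert (both orientations leave one reversible vector junction), the screen
for co-directed insertion is PCR with a single primer: annealing is an
exact match of the primer's 3′-terminal 12 nt (configurable), and a product
forms only for a convergent (+,−) site pair — present exactly when a
duplication is inverted, absent for direct tandems. Thermodynamics are
deliberately not modelled; exact-suffix matching suffices for orientation
logic. Amplicons span the outermost primer 5′ ends.

## Binding analytics

All binding is modelled as n identical, independent per-site 1:1 equilibria
(cooperativity deliberately omitted — the carriers show per-site 1:1
stoichiometry and site-proportional capacity). The dialysis forward model
couples the per-site isotherm to two-chamber mass balance (free ligand
equilibrates across the membrane; complex is confined to the inner volume).
The residual in free Gd³⁺ is strictly monotone, so Brent bracketing on
[0, Gd_total·v_in/(v_in+v_out)] is globally convergent; tolerance 1e-12 µM
absolute, mass conserved to ~1e-12 relative. Default volumes are 2 mL in
both chambers and the default scenario uses the equimolar 492.6 µM per-site
condition of the reference dialysis experiment. The inverse estimator
reconstructs complex and free sites from one measured free-Gd value; a
measurement equal to pure dilution raises a no-binding error rather than
dividing by zero, and replicates are combined as a geometric mean (the mKd
convention). Monte-Carlo tests recover Kd ∈ {0.05, 0.21, 1, 10} µM within
5% noiseless and 15% median at 5% measurement noise (3 replicates,
500 draws).

Job titrations fix the total of ligand plus per-site protein (default
50 µM, the Gd–XO working concentration) and solve the closed-form 1:1
quadratic at each mole fraction; the grid argmax is refined by a parabola
through the peak and neighbours. The per-site convention puts the 1:1
maximum at x = 0.5; counted per n-site molecule the maximum moves to
n/(n+1), which the tests verify against brute-force grid search for
n = 1..4. The x-axis convention is configurable because either can appear
in practice.

Xylenol-orange displacement solves the three-species competition (Gd shared
between XO and protein sites) by the same bracketed-residual method; the
Gd–XO Kd is a configuration parameter (no reliable universal value exists
for the buffer conditions of interest), so all XO behaviour is asserted
relatively: binary-equilibrium limit at zero protein, complete-displacement
limit, monotonicity, and half-displacement ordering with the affinity
ratio.

## Relaxometry

The inversion-recovery signal equation (flip angle f, default 180°) is the
canonical IR spin-echo form; at f = 180° and TR ≫ T1 it reduces to
k(1 − 2e^(−TI/T1)) with its null point at TI = T1·ln 2. The printed form
of this equation in the source literature has lost its exponent grouping
typographically; the canonical reading is adopted, f is configurable, and
every fitting test is self-consistency or parameter-recovery based rather
than anchored to a transcribed formula. Fitting is nonlinear least squares
multi-started over a log-spaced T1 grid (10–5000 ms default) because the IR
objective has a well-known spurious minimum near the null crossing; a
magnitude mode (fit |SI|) handles MRI magnitude data. Flat signals raise a
non-identifiability error. The default TI grid is the nine-point
acquisition schedule (50–1980 ms) with TR 16000 ms, TE 7.1 ms.

Relaxivity r1 is the OLS slope of 1/T1 in s⁻¹ on concentration in mM, with
µM inputs auto-converted when declared; the intercept is the buffer rate.
End-to-end simulations (IR forward model at 1% noise → per-concentration T1
fit → regression over 10 concentrations spanning 10–100 µM, buffer rate
0.38 s⁻¹) recover slopes of 4.43–6.84 mM⁻¹s⁻¹ within 2% as the median over
replicate series; a single noisy series occasionally deviates slightly
beyond 2%, which is why the tests assert the median.

## Synthetic data: what it shows and what it does not

Fixture vectors are random circular sequences scrubbed of all registry
enzyme sites except those requested (each exactly once), so digestion and
ligation outcomes are fully determined by design; they are synthetic
stand-ins, not reconstructions of any commercial backbone. Noise is
Gaussian and homoscedastic with a percentage parameter throughout, since no
empirical noise model is available. Passing tests therefore demonstrate the
correctness of the algorithms and estimators under controlled conditions —
they do not certify performance on real chromatograms, real absorbance
drift, correlated MRI noise, or sequence-dependent synthesis and cloning
artefacts. Problem sizes in the suite (600–3000 bp vectors, ≤ 3 insert
copies, 500-draw Monte-Carlo, 20 diversification seeds) were chosen as the
smallest sets that exercise every code path and give stable statistics.

## Known limitations

- No structure prediction, expression modelling, or pKa context effects;
  property calculators are sequence-only.
- PCR is orientation logic, not thermodynamics: no melting temperatures,
  mispriming energetics, or polymerase kinetics.
- The one-tube cycle is an equilibrium-selection argument; enzyme/ligase
  kinetics and copy-number distributions over time are out of scope.
- Binding assumes independent identical sites; negative or positive
  cooperativity would bias the estimators.
- mRNA 5′-UTR secondary structure is not modelled; the A/C initiation-tag
  designer reproduces the constrained reverse-translation step only.
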