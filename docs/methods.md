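# Methods

`pdxl` identifies zero-length peptide–DNA photo-crosslinks from paired
tandem-MS runs (UV-irradiated sample vs non-irradiated control), localizes
the crosslinked residue from DNA-shifted fragment ions, controls confidence
by target-decoy FDR, and validates contact sites against protein–DNA
structures. This note documents the model, the defaults, the numerical
choices, and what the synthetic benchmark does and does not show.

## The crosslink model

A UV photo-crosslink is treated as strictly zero-length: a covalent bond
between an amino-acid side chain and a nucleotide that adds no spacer mass.
After nuclease digestion the peptide retains a mono- to tetranucleotide
remnant, so the precursor of a crosslinked peptide satisfies

    M_obs = M(peptide + modifications) + M(adduct)

where the adduct is a multiset of deoxynucleotides (composition only —
base order is not observable at the precursor level) condensed with one
water loss per phosphodiester bond, plus one terminal variant from
{intact, −H2O, −HPO3, −H3PO4, +HPO3}. The single-nucleotide adduct is the
deoxynucleoside-5′-monophosphate free acid. For the default four bases,
lengths 1–4 and five variants the search space has 69 compositions and
345 (composition, variant) entries. −H3PO4 is kept as a variant distinct
from −HPO3 even though it is mass-identical to −HPO3 −H2O on a longer
chain's sibling entry; `isobaric_groups` reports which entries a precursor
cannot distinguish.

## Mass bookkeeping

Element monoisotopic masses (CODATA/NIST, ≥ 6 decimals) and elemental
compositions of residues and nucleotides ship as plain-text resources;
all residue/nucleotide masses are derived from compositions at load, so a
single table backs both the search and the per-atom consistency checks.
m/z arithmetic uses the electron-corrected proton mass (1.007276 Da); the
dehydrated-deoxyribose oxocarbenium after CO loss then computes to
m/z 89.06, matching the instrument scale.

Modification profiles:

* `invitro` — Met oxidation (+15.9949), Cys trioxidation to cysteic acid
  (+47.9847, modeled as +3O), Lys/N-terminal carbamylation (+43.0058), all
  variable. Cysteic acid carries diagnostic neutral losses of H2SO3 and
  H2O2; oxidized Met loses CH4SO.
* `exvivo` — Met oxidation variable; Cys carbamidomethylation (+57.0215)
  static.

Whether carbamylation may sit on the peptide N-terminus in addition to Lys
side chains is flag-controlled (`nterm_carbamyl`, default on): the
protocol's chemistry (urea-derived cyanate) attacks both, and allowing both
is the conservative search-space choice.

## Control subtraction

Runs are aligned on retention time using anchor precursors observed in
both conditions (mass match within the precursor tolerance, closest-RT
pairing). The alignment is a robust Theil–Sen straight line; with fewer
than 10 anchors, or a non-monotone fit, it falls back to the identity map
with a warning. An irradiated precursor is removed when any control
precursor matches within the precursor tolerance (default 10 ppm) and the
aligned RT window (default ±120 s; deliberately wide — a lost true
crosslink is more costly than a few extra candidates, which downstream
curation removes).

## Fragment annotation

Theoretical ions for a candidate comprise the unshifted a/b/y series
(fragment charges 1–2 by default), the same series shifted by every
non-empty sub-composition of the adduct crossed with the incremental
vocabulary in fixed precedence order — nucleotide, nucleotide −H3PO4,
−HPO3, −H2O, nucleobase, nucleobase −NH3, nucleobase −CO (thymine only) —
plus plain H2O/NH3 losses, modification-specific losses, a residual +CO
variant (the adduct a dissociated deoxyribose leaves behind), immonium
ions with optional nucleotide/nucleoside/nucleobase shifts, per-base
low-mass marker ions (protonated base, base −NH3, nucleoside −H2O,
nucleoside, nucleotide, oxocarbenium, oxocarbenium −CO), a C1 ion when
residue 2 is Asn/Gln, precursor-derived species, and (second pass)
internal b/a-type fragments. Immonium shifts are generated at all three
mass levels because reported marker ions use the nucleoside level while
backbone shifts are nucleotide-level; both are searched and reported.

Matching assigns each ion to every peak within the fragment tolerance
(default 20 ppm); each peak then keeps the single best ion by
(precedence rank, |Δppm|), so no peak is annotated twice. Coverage is
matched backbone bonds (a/b/y, shifted or unshifted) over length − 1 —
the standard operationalization of "amino-acid coverage" — and shifted
ions count toward it (flag to disable is deliberately absent: the
shifted ions are the evidence of interest). Internal ions and the
full-length y species are excluded from coverage.

## Localization

Constraint propagation over candidate positions:

1. unshifted b_i ⇒ site > i; unshifted y_j ⇒ site ≤ L − j (contradictory
   unshifted evidence, which only noise can produce, voids the bounds);
2. each DNA-shifted b_i (site ≤ i) or y_j (site ≥ L − j + 1) constraint is
   intersected one at a time; a constraint that would empty the interval
   is skipped as a coincidental match rather than allowed to void the
   consistent evidence;
3. shifted immonium ions restrict the interval to residues of that amino
   acid;
4. a C-terminal Lys/Arg is dropped from a tied interval (a crosslink
   there would have blocked tryptic cleavage).

The crosslinked base is trivial for single-base compositions; for mixed
compositions it is called only when base-specific shifted ions agree on
one base (marker ions alone may call it only if they single one out,
since markers prove adduct content, not linkage).

## Scoring, curation, FDR

The candidate score is −log10 of the binomial survival probability of
observing ≥ k matched peaks among N, with per-peak probability p equal to
the fraction of the observed m/z span covered by the theoretical
tolerance windows. It is deterministic and monotone in the matched count;
no claim of calibration across spectra is made — it exists to rank
candidates and to order target/decoy hits.

Curation (all four must pass):
(i) assigned charge and monoisotopic-peak consistency — the observed
neutral mass must match the theoretical one within the precursor
tolerance, an off-by-one-neutron precursor fails; (ii) coverage > 0.40;
(iii) for adducts of ≥ 2 nucleotides, ≥ 1 matched marker ion below
m/z 500; (iv) every peak above 10 % of the base peak annotated, with
+1/+2-neutron satellites of annotated peaks allowed. The 10 % threshold
and the isotope allowance make an inherently manual judgment explicit and
configurable; both are policy fields.

Decoys are full-protein reversals, one per target. q-values are the
classic target-decoy estimate q(s) = min over thresholds t ≤ s of
#decoys(score ≥ t) / #targets(score ≥ t), with tied scores handled as one
threshold block. FDR is controlled at the crosslinked-PSM level; the
final report deduplicates by (peptide, site, composition) keeping the
best score. Default report cutoff q ≤ 0.01.

## Synthetic benchmark

The generator emulates what the pipeline observes, not the physics:
5 random 300-residue proteins whose middle third is the designated
DNA-binding region; crosslinks implanted on tryptic peptides inside it;
adduct lengths weighted (0.50, 0.30, 0.15, 0.05) for 1–4 nucleotides;
crosslinked-base weights favoring pyrimidines (T 0.50, C 0.34, A 0.08,
G 0.08), matching the strong pyrimidine bias of observed photo-crosslink
base distributions; charges 2–4 at (0.5, 0.4, 0.1); precursor/fragment
m/z jitter 2/3 ppm (1 σ ≈ a third of the stated value, well inside the
search tolerances); shifted-fragment intensity at 0.5 of unshifted;
optional uniform-m/z noise peaks with exponential intensity; a shared
background population present in both runs with configurable RT
distortion of the control. Identical configs give identical output.

What it does not emulate: isotope envelopes, realistic chromatographic
peak shapes, co-isolation/chimeric spectra, intensity heteroscedasticity,
or sequence-dependent fragmentation propensities. Recovery results on it
therefore demonstrate the correctness of the search/annotation/curation
logic under its stated conditions, not expected sensitivity on real
instrument data.

Benchmark sizes used by the test suite and the acceptance script:
50 implanted crosslinks (8 proteins) for the noiseless recovery check,
and 50 (suite) / 20 (script) independent small simulations (5 implants,
15 background precursors each) for the empirical-FDR check.

## Structure validation

Structures load through gemmi (PDB or mmCIF; first model; highest-
occupancy altloc; hydrogens removed). The contact distance is the minimum
over side-chain heavy atoms of the residue × all heavy atoms of the
nucleotide (scopes `all` and `cbeta` available); ≤ 16 Å classifies as a
direct contact, beyond that as a flexibility candidate, with the boundary
counted direct. Author numbering is used throughout and a user-supplied
map reconciles report numbering with structure numbering. Distances to
published structures depend on the exact atom scope; comparisons are made
at ±0.5 Å and the realizing atom pair is always recorded. The reference
structures themselves are not distributed with the package; place them
under `data/structures/` (lower-case PDB id, `.cif`/`.pdb`) to enable
the reference-distance tests and the corresponding acceptance outputs.

## Known limitations

* Composition-level adduct identity only; base order of di- to
  tetranucleotides is not inferred.
* HCD a/b/y chemistry only (no ETD c/z support beyond the special C1 ion).
* The score is a ranking statistic, not a calibrated p-value.
* Control subtraction is precursor-based; no XIC/feature-level matching.
* I/L are not distinguished; semi-tryptic and non-specific cleavage are
  out of scope.
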