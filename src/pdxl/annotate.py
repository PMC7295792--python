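"""HCD fragment-ion annotation and crosslink-site localization.

For a peptide + DNA-adduct candidate the theoretical ion set contains:

* unshifted a/b/y series (fragment charges 1..max);
* the same series shifted by every non-empty sub-composition of the
  adduct, each crossed with the incremental shift vocabulary applied in
  fixed precedence order: nucleotide, nucleotide -H3PO4, -HPO3, -H2O,
  nucleobase, nucleobase -NH3, and nucleobase -CO (thymine only);
* modification-specific neutral losses (H2SO3 / H2O2 from cysteic acid,
  CH4SO from oxidized methionine) and plain H2O/NH3 losses;
* immonium ions per residue, optionally shifted by nucleotide,
  nucleoside or nucleobase masses;
* low-mass marker ions per adduct base (protonated base, base -NH3,
  nucleoside -H2O, nucleotide, deoxyribose oxocarbenium and its -CO
  product);
* a C1 ion when the second residue is Asn or Gln;
* precursor-derived species and (second pass) internal fragments.

Matched shifted ions localize the crosslink: unshifted b/y ions bound
the site interval from both termini, shifted ions must cover it, and
shifted immonium ions restrict it to residues of the matching amino
acid.  Scoring is a binomial-tail surprise measure of the matched peak
count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from . import chem
from .adducts import AdductComposition
from .proteolysis import ModifiedPeptide
from .spectra_io import Spectrum

# precedence rank of a shift class; lower wins when one peak is hit by
# several theoretical ions
_PRECEDENCE = {
    "none": 0,
    "nucleotide": 1,
    "nucleotide-H3PO4": 2,
    "nucleotide-HPO3": 3,
    "nucleotide-H2O": 4,
    "nucleobase": 5,
    "nucleobase-NH3": 6,
    "nucleobase-CO": 7,
    "modloss": 8,
    "loss": 9,
    "immonium": 10,
    "marker": 11,
    "precursor": 12,
    "internal": 13,
}

BACKBONE_SERIES = ("a", "b", "y")


@dataclass(frozen=True)
class FragmentIon:
    series: str            # a | b | y | c1 | immonium | internal | marker | precursor
    index: int | str       # ordinal for backbone/internal, residue or label otherwise
    charge: int
    shift: str             # "" for unshifted; e.g. "+TT-HPO3", "+T'", "-H2SO3"
    shift_class: str       # key of _PRECEDENCE
    mz: float
    shift_bases: str = ""  # canonical bases involved in a DNA shift, "" otherwise

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("ion m/z must be positive")
        if self.shift_class not in _PRECEDENCE:
            raise ValueError(f"unknown shift class {self.shift_class!r}")

    @property
    def precedence(self) -> int:
        return _PRECEDENCE[self.shift_class]

    @property
    def is_dna_shifted(self) -> bool:
        return self.shift_class.startswith(("nucleotide", "nucleobase")) or (
            self.shift_class == "immonium" and bool(self.shift_bases)
        )

    @property
    def label(self) -> str:
        core = (
            f"{self.series}{self.index}"
            if self.series in BACKBONE_SERIES + ("internal", "c1")
            else f"{self.series}-{self.index}"
        )
        z = f"^{self.charge}+" if self.charge > 1 else ""
        return f"{core}{self.shift}{z}"


@dataclass
class AnnotatedSpectrum:
    spectrum: Spectrum
    peptide: ModifiedPeptide
    adduct: AdductComposition | None
    matches: list[tuple[int, FragmentIon]]  # (peak index, ion)
    coverage: float
    explained_intensity: float
    markers_found: frozenset[str]  # bases with >=1 matched marker ion
    score: float = 0.0

    @property
    def matched_ions(self) -> list[FragmentIon]:
        return [ion for _, ion in self.matches]


@dataclass(frozen=True)
class LocalizationResult:
    interval: tuple[int, ...]       # admissible 1-based positions, ascending
    site: int | None                # resolved single residue, if any
    base_call: str                  # A|C|G|T or ""
    supporting: tuple[str, ...]     # labels of the ions that constrained it
    unlocalized: bool = False


def _dna_shift_set(adduct: AdductComposition) -> list[tuple[str, str, float, str]]:
    """(label, shift_class, mass delta, bases) for every DNA shift variant.

    Chain-level shifts come from every non-empty sub-composition (and
    the full adduct with its terminal variant); base-level shifts from
    each distinct base present.
    """
    shifts: dict[str, tuple[str, str, float, str]] = {}
    h2o = chem.NEUTRAL_LOSSES["H2O"]
    hpo3 = chem.NEUTRAL_LOSSES["HPO3"]
    h3po4 = chem.NEUTRAL_LOSSES["H3PO4"]
    chains = adduct.sub_adducts()
    if adduct.variant:
        chains.append(adduct)
    for sub in chains:
        m = sub.mass
        b = sub.bases
        for suffix, cls, delta in (
            ("", "nucleotide", 0.0),
            ("-H3PO4", "nucleotide-H3PO4", -h3po4),
            ("-HPO3", "nucleotide-HPO3", -hpo3),
            ("-H2O", "nucleotide-H2O", -h2o),
        ):
            label = f"+{sub.label}{suffix}"
            shifts.setdefault(label, (label, cls, m + delta, b))
    for base, _ in adduct.counts:
        spec = chem.NUCLEOTIDES[base]
        label = f"+{base}'"
        shifts.setdefault(label, (label, "nucleobase", spec.nucleobase_mass, base))
        for loss, lmass in spec.base_neutral_losses:
            cls = "nucleobase-CO" if loss == "CO" else "nucleobase-NH3"
            label = f"+{base}'-{loss}"
            shifts.setdefault(label, (label, cls, spec.nucleobase_mass - lmass, base))
    return list(shifts.values())


def _prefix_suffix_masses(peptide: ModifiedPeptide) -> tuple[list[float], list[float]]:
    """Neutral b-fragment and y-fragment masses for indices 1..L-1."""
    seq = peptide.sequence
    L = len(seq)
    mod_delta = [0.0] * (L + 1)
    for pos, spec in peptide.placements:
        mod_delta[pos] += spec.delta_mass
    b = []
    acc = mod_delta[0]  # N-terminal mods ride on b ions
    for i in range(1, L):
        acc += chem.RESIDUE_MASSES[seq[i - 1]] + mod_delta[i]
        b.append(acc)
    y = []
    acc = chem.WATER
    for j in range(1, L):
        acc += chem.RESIDUE_MASSES[seq[L - j]] + mod_delta[L - j + 1]
        y.append(acc)
    return b, y


def _mod_losses(peptide: ModifiedPeptide) -> list[tuple[int, str, float]]:
    """(position, loss label, loss mass) for modification-specific losses."""
    out = []
    for pos, spec in peptide.placements:
        for loss, lmass in spec.neutral_losses:
            out.append((pos, f"-{loss}", lmass))
    return out


def theoretical_ions(
    peptide: ModifiedPeptide,
    adduct: AdductComposition | None = None,
    max_fragment_charge: int = 2,
    precursor_charge: int | None = None,
    include_internal: bool = False,
) -> list[FragmentIon]:
    """Generate the full theoretical ion set for one candidate."""
    seq = peptide.sequence
    L = len(seq)
    co = chem.NEUTRAL_LOSSES["CO"]
    nh3 = chem.NEUTRAL_LOSSES["NH3"]
    h2o = chem.NEUTRAL_LOSSES["H2O"]
    ions: list[FragmentIon] = []

    b_masses, y_masses = _prefix_suffix_masses(peptide)
    dna_shifts = _dna_shift_set(adduct) if adduct is not None else []
    mod_losses = _mod_losses(peptide)

    def add(series, index, charge, shift, cls, neutral, bases=""):
        mz = chem.mz_from_mass(neutral, charge) if neutral > 0 else -1.0
        if mz > 0:
            ions.append(
                FragmentIon(
                    series=series, index=index, charge=charge, shift=shift,
                    shift_class=cls, mz=mz, shift_bases=bases,
                )
            )

    for z in range(1, max_fragment_charge + 1):
        for i in range(1, L):
            frag = {
                "b": b_masses[i - 1],
                "a": b_masses[i - 1] - co,
                "y": y_masses[i - 1],
            }
            for series, neutral in frag.items():
                add(series, i, z, "", "none", neutral)
                # plain small losses
                add(series, i, z, "-H2O", "loss", neutral - h2o)
                add(series, i, z, "-NH3", "loss", neutral - nh3)
                if adduct is not None:
                    # residual CO adduct left by a dissociated
                    # deoxyribose crosslink (a second, labile site)
                    add(series, i, z, "+CO", "loss", neutral + co)
                # modification-specific losses, only on fragments that
                # actually contain the modified residue
                for pos, loss, lmass in mod_losses:
                    contains = pos <= i if series in ("a", "b") else pos > L - i
                    if pos == 0:
                        contains = series in ("a", "b")
                    if contains:
                        add(series, i, z, loss, "modloss", neutral - lmass)
                # DNA-shifted variants
                for label, cls, smass, bases in dna_shifts:
                    add(series, i, z, label, cls, neutral + smass, bases)

    # full-length y ion (intact peptide as a y-type species); carries
    # no localization information but is annotated when observed
    full = peptide.mass
    for z in range(1, max_fragment_charge + 1):
        add("y", L, z, "", "none", full)
        for pos, loss, lmass in mod_losses:
            add("y", L, z, loss, "modloss", full - lmass)
        for label, cls, smass, bases in dna_shifts:
            add("y", L, z, label, cls, full + smass, bases)
        if adduct is not None:
            add("y", L, z, "+CO", "loss", full + co)

    # C1 ion (b1 + NH3), seen with Asn/Gln in second position
    if L >= 2 and seq[1] in "NQ":
        add("c1", 1, 1, "", "none", b_masses[0] + nh3)

    # immonium ions (residue - CO, as a cation), with optional DNA shifts
    seen_imm: set[str] = set()
    for pos, aa in enumerate(seq, start=1):
        if aa in seen_imm:
            continue
        seen_imm.add(aa)
        imm_neutral = chem.RESIDUE_MASSES[aa] - co  # protonated via add()
        add("immonium", aa, 1, "", "immonium", imm_neutral)
        if adduct is not None:
            for base, _ in adduct.counts:
                spec = chem.NUCLEOTIDES[base]
                for label, smass in (
                    (f"+{base}p", spec.dnmp_mass),       # nucleotide
                    (f"+d{base}", spec.nucleoside_mass),  # nucleoside
                    (f"+{base}'", spec.nucleobase_mass),  # nucleobase
                ):
                    add("immonium", aa, 1, label, "immonium",
                        imm_neutral + smass, base)

    # low-mass marker ions per adduct base
    if adduct is not None:
        seen_markers: set[str] = set()
        for base, _ in adduct.counts:
            for label, mz in chem.NUCLEOTIDES[base].marker_ions:
                if label in seen_markers:
                    continue
                seen_markers.add(label)
                bases = "" if label.startswith("sugar") else base
                ions.append(
                    FragmentIon(
                        series="marker", index=label, charge=1, shift="",
                        shift_class="marker", mz=mz, shift_bases=bases,
                    )
                )

    # precursor-derived species
    if precursor_charge is not None and precursor_charge >= 1:
        pmass = peptide.mass + (adduct.mass if adduct is not None else 0.0)
        for z in range(1, precursor_charge + 1):
            add("precursor", "M", z, "", "precursor", pmass)
            add("precursor", "M", z, "-H2O", "precursor", pmass - h2o)
            add("precursor", "M", z, "-NH3", "precursor", pmass - nh3)
            for label, cls, smass, bases in dna_shifts:
                # loss of the DNA piece from the precursor
                add("precursor", "M", z, f"-({label[1:]})", "precursor",
                    pmass - smass)

    # internal fragments (second-pass explanation; excluded from coverage)
    if include_internal:
        for start in range(1, L - 1):
            for end in range(start + 2, L):
                sub = seq[start:end]
                neutral = sum(chem.RESIDUE_MASSES[c] for c in sub)
                add("internal", sub, 1, "", "internal", neutral)
                add("internal", sub, 1, "-CO", "internal", neutral - co)

    # dedupe identical (series,index,charge,shift) keeping first
    seen: set[tuple] = set()
    unique = []
    for ion in ions:
        key = (ion.series, ion.index, ion.charge, ion.shift)
        if key in seen:
            continue
        seen.add(key)
        unique.append(ion)
    return unique


def match_fragments(
    spectrum: Spectrum,
    ions: Sequence[FragmentIon],
    ppm_tol: float = 20.0,
    peptide: ModifiedPeptide | None = None,
    adduct: AdductComposition | None = None,
) -> AnnotatedSpectrum:
    """Assign peaks to theoretical ions within the fragment tolerance.

    Every ion is paired with its nearest peak in tolerance; each peak
    then keeps the single best ion by (precedence, |Δppm|).  Coverage
    counts matched backbone bonds (a/b/y, shifted or unshifted) over
    peptide length - 1; explained intensity is the matched share of the
    total ion current.
    """
    if ppm_tol <= 0:
        raise ValueError("tolerance must be positive")
    mz = spectrum.mz
    best_for_peak: dict[int, tuple[int, float, FragmentIon]] = {}
    for ion in ions:
        tol = ppm_tol * 1e-6 * ion.mz
        lo = np.searchsorted(mz, ion.mz - tol, side="left")
        hi = np.searchsorted(mz, ion.mz + tol, side="right")
        for k in range(int(lo), int(hi)):
            err = abs(mz[k] - ion.mz) / ion.mz
            cur = best_for_peak.get(k)
            cand = (ion.precedence, err, ion)
            if cur is None or (cand[0], cand[1]) < (cur[0], cur[1]):
                best_for_peak[k] = cand
    matches = sorted(
        ((k, ion) for k, (_, _, ion) in best_for_peak.items()),
        key=lambda t: t[0],
    )

    pep = peptide
    L = len(pep.sequence) if pep is not None else 0
    bonds: set[int] = set()
    markers: set[str] = set()
    for _, ion in matches:
        if ion.series in BACKBONE_SERIES and isinstance(ion.index, int) and L:
            bond = ion.index if ion.series in ("a", "b") else L - ion.index
            if 1 <= bond <= L - 1:
                bonds.add(bond)
        if ion.series == "marker" and ion.shift_bases:
            markers.add(ion.shift_bases)
    coverage = len(bonds) / (L - 1) if L > 1 else 0.0
    tic = spectrum.total_ion_current
    explained = (
        float(sum(spectrum.intensity[k] for k, _ in matches)) / tic if tic else 0.0
    )
    annotated = AnnotatedSpectrum(
        spectrum=spectrum,
        peptide=pep,
        adduct=adduct,
        matches=matches,
        coverage=coverage,
        explained_intensity=explained,
        markers_found=frozenset(markers),
    )
    annotated.score = score(annotated, n_theoretical=len(ions), ppm_tol=ppm_tol)
    return annotated


def score(
    annotated: AnnotatedSpectrum,
    n_theoretical: int,
    ppm_tol: float = 20.0,
) -> float:
    """-log10 binomial survival probability of the matched peak count.

    With N peaks and per-peak match probability p — the fraction of the
    observed m/z range covered by the theoretical tolerance windows —
    the score is -log10 P(X >= k), X ~ Binomial(N, p).  Zero matches
    score 0; the score is monotone in k at fixed N and p.
    """
    n_peaks = len(annotated.spectrum.mz)
    k = len(annotated.matches)
    if k == 0 or n_peaks == 0:
        return 0.0
    lo, hi = float(annotated.spectrum.mz[0]), float(annotated.spectrum.mz[-1])
    span = max(hi - lo, 1.0)
    mean_mz = (lo + hi) / 2.0
    window = 2.0 * ppm_tol * 1e-6 * mean_mz
    p = min(0.99, max(n_theoretical * window / span, 1e-12))
    sf = stats.binom.sf(k - 1, n_peaks, p)
    if sf <= 0:
        return 300.0  # beyond double-precision tail
    return float(-math.log10(sf))


def localize(annotated: AnnotatedSpectrum) -> LocalizationResult:
    """Constrain the crosslink site from shifted/unshifted ion evidence.

    Interval = positions C-terminal of the largest unshifted b ion,
    N-terminal of the largest unshifted y ion, intersected with the
    positions covered by every matched DNA-shifted backbone ion.
    Shifted immonium ions restrict to residues of that amino acid; a
    C-terminal K/R is deprioritized on ties (steric interference with
    tryptic cleavage makes a crosslinked C-terminal K/R unlikely).
    """
    pep = annotated.peptide
    seq = pep.sequence
    L = len(seq)
    if annotated.adduct is None:
        return LocalizationResult(
            interval=tuple(range(1, L + 1)), site=None, base_call="",
            supporting=(), unlocalized=True,
        )

    supporting: list[str] = []
    shifted_seen = False
    # base-call evidence tiers: base-specific shifted ions beat marker
    # ions, which merely prove a nucleotide is part of the adduct
    shift_votes: set[str] = set()
    marker_votes: set[str] = set()

    # stage 1: bounds from unshifted backbone ions (full-length y
    # carries no bond information and is excluded)
    lo, hi = 1, L
    for _, ion in annotated.matches:
        if (
            ion.series in BACKBONE_SERIES
            and isinstance(ion.index, int)
            and 1 <= ion.index <= L - 1
            and not ion.is_dna_shifted
        ):
            i = ion.index
            if ion.series in ("a", "b"):
                lo = max(lo, i + 1)      # first i residues unmodified
            else:
                hi = min(hi, L - i)      # last i residues unmodified
            supporting.append(ion.label)
    if lo > hi:  # contradictory unshifted evidence (noise): no bound usable
        lo, hi = 1, L

    # stage 2: intersect with shifted-ion coverage, one constraint at a
    # time; a stray coincidental match that would empty the interval is
    # skipped rather than allowed to void the consistent evidence
    for _, ion in annotated.matches:
        if (
            ion.series in BACKBONE_SERIES
            and isinstance(ion.index, int)
            and 1 <= ion.index <= L - 1
            and ion.is_dna_shifted
        ):
            shifted_seen = True
            i = ion.index
            new_lo, new_hi = lo, hi
            if ion.series in ("a", "b"):
                new_hi = min(hi, i)          # site within first i residues
            else:
                new_lo = max(lo, L - i + 1)  # site within last i residues
            if new_lo <= new_hi:
                lo, hi = new_lo, new_hi
                supporting.append(ion.label)
                if len(set(ion.shift_bases)) == 1:
                    shift_votes.add(ion.shift_bases[0])
    for _, ion in annotated.matches:
        if ion.series == "marker" and ion.shift_bases:
            marker_votes.add(ion.shift_bases)
            supporting.append(ion.label)

    interval = list(range(lo, hi + 1))

    # shifted immonium ions pin the residue type
    imm_residues = {
        ion.index
        for _, ion in annotated.matches
        if ion.series == "immonium" and ion.shift_bases
    }
    if imm_residues:
        narrowed = [p for p in interval if seq[p - 1] in imm_residues]
        if narrowed:
            interval = narrowed
            supporting.extend(
                ion.label
                for _, ion in annotated.matches
                if ion.series == "immonium" and ion.shift_bases
            )
            for _, ion in annotated.matches:
                if ion.series == "immonium" and ion.shift_bases:
                    shift_votes.add(ion.shift_bases)

    # tryptic-steric rule: drop a C-terminal K/R when alternatives remain
    if len(interval) > 1 and interval[-1] == L and seq[-1] in "KR":
        interval = interval[:-1]

    # crosslinked base: trivial for a single-base composition; otherwise
    # decided by base-specific shifted ions, with marker ions only as a
    # fallback when they single out one base
    distinct_bases = {b for b, _ in annotated.adduct.counts}
    if len(distinct_bases) == 1:
        base_call = next(iter(distinct_bases))
    elif len(shift_votes) == 1:
        base_call = next(iter(shift_votes))
    elif not shift_votes and len(marker_votes) == 1:
        base_call = next(iter(marker_votes))
    else:
        base_call = ""
    site = interval[0] if len(interval) == 1 else None
    return LocalizationResult(
        interval=tuple(interval),
        site=site,
        base_call=base_call,
        supporting=tuple(dict.fromkeys(supporting)),
        unlocalized=not shifted_seen,
    )


def annotate_candidate(
    spectrum: Spectrum,
    peptide: ModifiedPeptide,
    adduct: AdductComposition | None,
    ppm_tol: float = 20.0,
    max_fragment_charge: int = 2,
    include_internal: bool = True,
) -> AnnotatedSpectrum:
    """Convenience wrapper: generate ions, match, and score one candidate."""
    ions = theoretical_ions(
        peptide,
        adduct,
        max_fragment_charge=max_fragment_charge,
        precursor_charge=spectrum.precursor_charge or None,
        include_internal=include_internal,
    )
    return match_fragments(spectrum, ions, ppm_tol, peptide=peptide, adduct=adduct)
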