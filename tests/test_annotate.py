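"""Theoretical ion generation, fragment matching, localization, scoring."""

import itertools
import math

import numpy as np
import pytest
from pyteomics import mass as pytmass
from scipy import stats

from pdxl import chem
from pdxl.adducts import AdductComposition
from pdxl.annotate import (
    annotate_candidate,
    localize,
    match_fragments,
    theoretical_ions,
)
from pdxl.spectra_io import Spectrum

from conftest import make_modified, synthetic_spectrum


def ions_by_label(ions):
    return {ion.label: ion for ion in ions}


class TestTheoreticalIons:
    def test_by_series_match_pyteomics_oracle(self):
        pep = make_modified("GKLMNR")
        ions = ions_by_label(theoretical_ions(pep, None, max_fragment_charge=1))
        seq = pep.sequence
        for i in range(1, len(seq)):
            b_oracle = pytmass.fast_mass(seq[:i], ion_type="b", charge=1)
            y_oracle = pytmass.fast_mass(seq[i:], ion_type="y", charge=1)
            assert ions[f"b{i}"].mz == pytest.approx(b_oracle, abs=1e-4)
            assert ions[f"y{len(seq) - i}"].mz == pytest.approx(y_oracle, abs=1e-4)

    def test_arginine_immonium_and_thymidine_shift(self):
        pep = make_modified("RIDCLR")
        adduct = AdductComposition.from_bases("TT")
        ions = ions_by_label(theoretical_ions(pep, adduct))
        assert ions["immonium-R"].mz == pytest.approx(129.1135, abs=1e-3)
        shifted = ions["immonium-R+dT"]
        assert shifted.mz == pytest.approx(
            129.1135 + chem.NUCLEOTIDES["T"].nucleoside_mass, abs=1e-3
        )

    def test_nucleobase_co_loss_only_for_thymine(self):
        pep = make_modified("GKLR")
        for bases, expect_co in [("T", True), ("A", False), ("C", False), ("G", False)]:
            ions = theoretical_ions(pep, AdductComposition.from_bases(bases))
            co_shifts = [i for i in ions if i.shift.endswith("'-CO")]
            assert bool(co_shifts) == expect_co, bases

    def test_c1_ion_requires_asn_or_gln_second(self):
        no_c1 = theoretical_ions(make_modified("HLKKAK"), None)
        assert not [i for i in no_c1 if i.series == "c1"]
        with_c1 = theoretical_ions(make_modified("ANKLR"), None)
        c1 = [i for i in with_c1 if i.series == "c1"]
        assert len(c1) == 1
        expected = chem.RESIDUE_MASSES["A"] + chem.NEUTRAL_LOSSES["NH3"] + chem.PROTON
        assert c1[0].mz == pytest.approx(expected, abs=1e-4)

    def test_trioxidized_cys_losses_only_on_containing_fragments(self):
        pep = make_modified("APGCVK", [(4, chem.TRIOXIDATION_C)])
        ions = ions_by_label(theoretical_ions(pep, None, max_fragment_charge=1))
        assert "b4-H2SO3" in ions and "b4-H2O2" in ions
        assert "b3-H2SO3" not in ions  # prefix without the Cys
        assert "y3-H2SO3" in ions and "y2-H2SO3" not in ions

    def test_full_adduct_with_variant_in_shift_set(self):
        pep = make_modified("IQNMVGSCDVK", [(8, chem.TRIOXIDATION_C)])
        adduct = AdductComposition.from_bases("TT", "-HPO3")
        ions = ions_by_label(theoretical_ions(pep, adduct, max_fragment_charge=1))
        y8 = ions["y8+TT-HPO3"]
        assert y8.mz == pytest.approx(ions["y8"].mz + adduct.mass, abs=1e-4)

    def test_marker_ions_present(self):
        ions = theoretical_ions(make_modified("GKLR"), AdductComposition.from_bases("C"))
        markers = {i.index for i in ions if i.series == "marker"}
        assert {"C'", "C'-NH3", "dC", "dC-H2O", "Cp", "sugar", "sugar-CO"} <= markers


class TestMatchFragments:
    def test_empty_spectrum(self):
        pep = make_modified("GKLMNR")
        s = Spectrum(
            run_id="r", scan_id="s", precursor_mz=500.0, precursor_charge=2,
            rt=0.0, mz=np.empty(0), intensity=np.empty(0),
        )
        ann = match_fragments(s, theoretical_ions(pep, None), peptide=pep)
        assert ann.coverage == 0.0 and ann.explained_intensity == 0.0
        assert ann.score == 0.0

    def test_full_by_series_coverage_one(self):
        pep = make_modified("ACDEFGHIKL")
        s = synthetic_spectrum(pep, None, site=None)
        ann = annotate_candidate(s, pep, None)
        assert ann.coverage == pytest.approx(1.0)
        assert ann.explained_intensity == pytest.approx(1.0)

    def test_co_shifted_y_series_matched(self):
        # y ions carrying a +27.995 Da residual CO adduct are annotated
        pep = make_modified("LDLKTIALR")
        adduct = AdductComposition.from_bases("C")
        co = chem.NEUTRAL_LOSSES["CO"]
        assert round(co, 3) == 27.995
        peaks = []
        for j in (6, 7, 8, 9):
            y = chem.peptide_mass(pep.sequence[len(pep.sequence) - j:]) + co
            peaks.append((chem.mz_from_mass(y, 1), 1e5))
        s = Spectrum(
            run_id="r", scan_id="s",
            precursor_mz=chem.mz_from_mass(pep.mass + adduct.mass, 2),
            precursor_charge=2, rt=0.0,
            mz=np.array(sorted(p[0] for p in peaks)),
            intensity=np.array([p[1] for p in peaks]),
        )
        ann = annotate_candidate(s, pep, adduct)
        labels = {ion.label for ion in ann.matched_ions}
        assert {"y6+CO", "y7+CO", "y8+CO", "y9+CO"} <= labels

    def test_one_ion_per_peak_precedence(self):
        pep = make_modified("GKLMNR")
        ions = theoretical_ions(pep, AdductComposition.from_bases("T"))
        s = synthetic_spectrum(pep, None, site=None)
        ann = match_fragments(s, ions, peptide=pep)
        peaks = [k for k, _ in ann.matches]
        assert len(peaks) == len(set(peaks))

    def test_shift_vocabulary_raises_explained_intensity_only_when_crosslinked(self):
        pep = make_modified("ACDEFGHIKL")
        adduct = AdductComposition.from_bases("T")
        plain = synthetic_spectrum(pep, None, site=None)
        linked = synthetic_spectrum(pep, adduct, site=5)
        for s, expect_gain in [(plain, False), (linked, True)]:
            with_dna = match_fragments(
                s, theoretical_ions(pep, adduct), peptide=pep, adduct=adduct
            )
            without = match_fragments(
                s, theoretical_ions(pep, None), peptide=pep
            )
            gain = with_dna.explained_intensity - without.explained_intensity
            assert (gain > 0.01) == expect_gain


class TestScore:
    def test_zero_matches_zero_score(self):
        pep = make_modified("GKLMNR")
        s = Spectrum(
            run_id="r", scan_id="s", precursor_mz=500.0, precursor_charge=2,
            rt=0.0, mz=np.array([3000.0]), intensity=np.array([1.0]),
        )
        ann = match_fragments(s, theoretical_ions(pep, None), peptide=pep)
        assert ann.score == 0.0

    def test_monotone_in_matches(self):
        pep = make_modified("ACDEFGHIKL")
        full = synthetic_spectrum(pep, None, site=None)
        partial = synthetic_spectrum(pep, None, site=None, b_range=range(1, 4),
                                     y_range=range(0))
        # pad the partial spectrum with unmatched junk so peak counts match
        n_pad = len(full.mz) - len(partial.mz)
        pad_mz = np.linspace(2500, 2600, n_pad)
        partial = Spectrum(
            run_id="r", scan_id="p", precursor_mz=full.precursor_mz,
            precursor_charge=2, rt=0.0,
            mz=np.concatenate([partial.mz, pad_mz]),
            intensity=np.concatenate([partial.intensity, np.ones(n_pad)]),
        )
        s_full = annotate_candidate(full, pep, None).score
        s_partial = annotate_candidate(partial, pep, None).score
        assert s_full > s_partial > 0

    def test_binomial_tail_closed_form(self):
        pep = make_modified("GKLMNR")
        ions = theoretical_ions(pep, None, max_fragment_charge=1)
        s = synthetic_spectrum(pep, None, site=None)
        ann = match_fragments(s, ions, ppm_tol=20.0, peptide=pep)
        n_peaks = len(s.mz)
        k = len(ann.matches)
        span = max(float(s.mz[-1] - s.mz[0]), 1.0)
        window = 2 * 20e-6 * float(s.mz[0] + s.mz[-1]) / 2
        p = min(0.99, max(len(ions) * window / span, 1e-12))
        expected = -math.log10(stats.binom.sf(k - 1, n_peaks, p))
        assert ann.score == pytest.approx(expected, rel=1e-9)


def localization_oracle(L, unshifted_b, unshifted_y, shifted_b, shifted_y):
    """Brute-force constraint propagation over candidate positions."""
    admissible = set(range(1, L + 1))
    if unshifted_b:
        bmax = max(unshifted_b)
        admissible &= set(range(bmax + 1, L + 1))
    if unshifted_y:
        ymax = max(unshifted_y)
        admissible &= set(range(1, L - ymax + 1))
    for i in sorted(shifted_b):
        new = admissible & set(range(1, i + 1))
        if new:
            admissible = new
    for j in sorted(shifted_y):
        new = admissible & set(range(L - j + 1, L + 1))
        if new:
            admissible = new
    return admissible or set(range(1, L + 1))


class TestLocalize:
    def test_unmodified_candidate_flagged(self):
        pep = make_modified("GKLMNR")
        s = synthetic_spectrum(pep, None, site=None)
        ann = annotate_candidate(s, pep, None)
        loc = localize(ann)
        assert loc.unlocalized and loc.interval == tuple(range(1, 7))

    def test_thymidine_immonium_pins_nterminal_arginine(self):
        # dinucleotide-TT peptide with a thymidine-shifted Arg immonium:
        # the C-terminal Arg is deprioritized, leaving R at position 1
        pep = make_modified("RIDCLR")
        adduct = AdductComposition.from_bases("TT")
        imm = chem.RESIDUE_MASSES["R"] - chem.NEUTRAL_LOSSES["CO"]
        imm_shift = chem.mz_from_mass(
            imm + chem.NUCLEOTIDES["T"].nucleoside_mass, 1
        )
        s = synthetic_spectrum(
            pep, adduct, site=1, extra_peaks=[(imm_shift, 5e4)],
            b_range=range(0), y_range=range(1, 6),
        )
        ann = annotate_candidate(s, pep, adduct)
        loc = localize(ann)
        assert loc.interval == (1,)
        assert loc.site == 1
        assert loc.base_call == "T"

    def test_tbp_style_interval_two_residues(self):
        # shifted y9/y10 with unshifted y ions up to y7: the site narrows
        # to positions 3-4 of the 11-mer (either of two adjacent residues)
        pep = make_modified("IQNMVGSCDVK", [(8, chem.TRIOXIDATION_C)])
        adduct = AdductComposition.from_bases("TT", "-HPO3")
        s = synthetic_spectrum(
            pep, adduct, site=3,
            b_range=range(0), y_range={1, 2, 3, 4, 5, 6, 7, 9, 10},
        )
        ann = annotate_candidate(s, pep, adduct)
        loc = localize(ann)
        assert loc.interval == (3, 4)
        assert loc.site is None

    def test_all_y_shifted_points_to_cterm(self):
        pep = make_modified("GLDAV")
        adduct = AdductComposition.from_bases("C")
        s = synthetic_spectrum(pep, adduct, site=5)
        ann = annotate_candidate(s, pep, adduct)
        loc = localize(ann)
        assert loc.interval == (5,) and loc.site == 5

    def test_matches_constraint_propagation_oracle(self):
        # enumerate toy evidence patterns on a 6-mer without K/R (so the
        # steric rule stays out of play) and without shifted immonium
        pep = make_modified("GLDAVS")
        adduct = AdductComposition.from_bases("T")
        L = 6
        for site in range(1, L + 1):
            for b_emit, y_emit in itertools.product(
                [set(), {1, 2}, set(range(1, L))],
                [set(), {1, 2, 3}, set(range(1, L))],
            ):
                s = synthetic_spectrum(
                    pep, adduct, site=site, b_range=b_emit or range(0),
                    y_range=y_emit or range(0),
                )
                ann = annotate_candidate(s, pep, adduct)
                loc = localize(ann)
                unshifted_b = {i for i in b_emit if i < site}
                shifted_b = {i for i in b_emit if i >= site}
                unshifted_y = {j for j in y_emit if j <= L - site}
                shifted_y = {j for j in y_emit if j > L - site}
                expected = localization_oracle(
                    L, unshifted_b, unshifted_y, shifted_b, shifted_y
                )
                assert set(loc.interval) == expected, (site, b_emit, y_emit)

    def test_noiseless_interval_always_contains_site(self):
        rng = np.random.default_rng(123)
        aa = list("ACDEFGHILMNPQSTVWY")  # no K/R: steric rule not triggered
        for _ in range(500):
            L = int(rng.integers(6, 15))
            seq = "".join(rng.choice(aa, size=L))
            pep = make_modified(seq)
            adduct = AdductComposition.from_bases(
                "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            )
            site = int(rng.integers(1, L + 1))
            emit_b = {i for i in range(1, L) if rng.random() < 0.7}
            emit_y = {j for j in range(1, L) if rng.random() < 0.7}
            s = synthetic_spectrum(pep, adduct, site=site,
                                   b_range=emit_b or range(0),
                                   y_range=emit_y or range(0))
            ann = annotate_candidate(s, pep, adduct)
            loc = localize(ann)
            assert site in loc.interval, (seq, site, emit_b, emit_y)
            # flanking evidence on both sides pins the site exactly
            if (site - 1 in emit_b or site == 1) and site in emit_b and \
               (L - site in emit_y or site == L) and L - site + 1 in emit_y:
                assert loc.site == site, (seq, site)
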