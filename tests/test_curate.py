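"""Curation rules, target-decoy q-values, report summaries."""

import math

import numpy as np
import pytest

from pdxl import chem, curate
from pdxl.adducts import AdductComposition
from pdxl.annotate import annotate_candidate
from pdxl.curate import (
    NEUTRON,
    CrosslinkID,
    CurationPolicy,
    apply_rules,
    estimate_fdr,
    final_report,
    make_crosslink_id,
    summarize,
)
from pdxl.spectra_io import Spectrum

from conftest import make_modified, synthetic_spectrum


def _annotated(pep_seq="ACDEFGHIKL", bases="T", site=5, charge=2,
               mass_offset=0.0, extra_peaks=None, b_range=None, y_range=None):
    pep = make_modified(pep_seq)
    adduct = AdductComposition.from_bases(bases)
    s = synthetic_spectrum(pep, adduct, site=site, charge=charge,
                           extra_peaks=extra_peaks,
                           b_range=b_range, y_range=y_range)
    theo = pep.mass + adduct.mass
    if mass_offset:
        s = Spectrum(
            run_id=s.run_id, scan_id=s.scan_id,
            precursor_mz=chem.mz_from_mass(theo + mass_offset, charge),
            precursor_charge=charge, rt=s.rt, mz=s.mz, intensity=s.intensity,
        )
    ann = annotate_candidate(s, pep, adduct)
    return ann, theo


class TestRules:
    def test_clean_candidate_passes_all(self):
        ann, theo = _annotated()
        flags = apply_rules(ann, theo, CurationPolicy())
        assert all(flags.values())

    def test_coverage_rule_five_of_nine_bonds(self):
        # 5 matched bonds on a 10-mer = 0.56 > 0.40 -> pass
        ann, theo = _annotated(b_range={1, 2, 3, 4, 5}, y_range=range(0))
        assert ann.coverage == pytest.approx(5 / 9)
        assert apply_rules(ann, theo, CurationPolicy())["coverage"]
        # 3 of 9 bonds fails
        ann2, theo2 = _annotated(b_range={1, 2, 3}, y_range=range(0))
        assert not apply_rules(ann2, theo2, CurationPolicy())["coverage"]

    def test_dinucleotide_without_marker_fails_rule_iii(self):
        pep = make_modified("ACDEFGHIKL")
        adduct = AdductComposition.from_bases("TT")
        s = synthetic_spectrum(pep, adduct, site=5)  # b/y only, no markers
        ann = annotate_candidate(s, pep, adduct)
        flags = apply_rules(ann, pep.mass + adduct.mass, CurationPolicy())
        assert not flags["marker_ions"]
        # mononucleotide is exempt from the marker requirement
        ann1, theo1 = _annotated(bases="T")
        assert apply_rules(ann1, theo1, CurationPolicy())["marker_ions"]

    def test_dinucleotide_with_marker_passes_rule_iii(self):
        pep = make_modified("ACDEFGHIKL")
        adduct = AdductComposition.from_bases("TT")
        marker = chem.NUCLEOTIDES["T"].marker_ions[0]  # protonated thymine
        s = synthetic_spectrum(pep, adduct, site=5, extra_peaks=[(marker[1], 1e4)])
        ann = annotate_candidate(s, pep, adduct)
        assert apply_rules(ann, pep.mass + adduct.mass, CurationPolicy())["marker_ions"]

    def test_unexplained_high_peak_fails_rule_iv(self):
        # junk peak at 50% of base-peak intensity, not near any ion
        ann, theo = _annotated(extra_peaks=[(1987.6543, 5e4)])
        flags = apply_rules(ann, theo, CurationPolicy())
        assert not flags["peaks_explained"]
        # the same peak below the 10% threshold is tolerated
        ann2, theo2 = _annotated(extra_peaks=[(1987.6543, 5e3)])
        assert apply_rules(ann2, theo2, CurationPolicy())["peaks_explained"]

    def test_isotope_satellite_allowed_by_rule_iv(self):
        pep = make_modified("ACDEFGHIKL")
        adduct = AdductComposition.from_bases("T")
        s0 = synthetic_spectrum(pep, adduct, site=5)
        satellite = (float(s0.mz[3]) + NEUTRON, 5e4)  # +1 isotope of a real peak
        s = synthetic_spectrum(pep, adduct, site=5, extra_peaks=[satellite])
        ann = annotate_candidate(s, pep, adduct)
        assert apply_rules(ann, pep.mass + adduct.mass, CurationPolicy())["peaks_explained"]

    def test_off_by_one_neutron_fails_rule_i(self):
        ann, theo = _annotated(mass_offset=NEUTRON)
        flags = apply_rules(ann, theo, CurationPolicy())
        assert not flags["charge_and_monoisotope"]
        # re-evaluated at the corrected monoisotopic mass it passes
        ann_ok, theo_ok = _annotated()
        assert apply_rules(ann_ok, theo_ok, CurationPolicy())["charge_and_monoisotope"]

    def test_rule_relaxation_is_monotone(self):
        # disabling rule (iv) can only grow the pass set
        strict = CurationPolicy()
        lax = CurationPolicy(high_intensity_fraction=1.0)  # effectively off
        cases = [
            _annotated(),
            _annotated(extra_peaks=[(1987.6543, 5e4)]),
            _annotated(b_range={1, 2, 3}, y_range=range(0)),
        ]
        for ann, theo in cases:
            f_strict = apply_rules(ann, theo, strict)
            f_lax = apply_rules(ann, theo, lax)
            if all(f_strict.values()):
                assert all(f_lax.values())


def _id(score, decoy=False, base="T", seq="PEPTIDEK", site="3"):
    from pdxl.annotate import LocalizationResult

    return CrosslinkID(
        accessions=("REV_P1",) if decoy else ("P1",),
        peptide_label=seq, sequence=seq,
        localization=LocalizationResult(
            interval=(int(site),), site=int(site), base_call=base,
            supporting=(), unlocalized=False,
        ),
        adduct_label="T", adduct_length=1, base_call=base, charge=2,
        precursor_mz=500.0, delta_ppm=0.0, score=score, is_decoy=decoy,
        rule_flags={r: True for r in curate.RULE_NAMES},
    )


class TestFdr:
    def test_no_decoys_requires_flag(self):
        ids = [_id(10.0), _id(5.0)]
        with pytest.raises(ValueError):
            estimate_fdr(ids)
        estimate_fdr(ids, allow_no_decoys=True)
        assert all(x.q_value == 0.0 for x in ids)

    def test_zero_decoy_hits_all_q_zero(self):
        ids = [_id(10.0), _id(8.0), _id(1.0, decoy=True)]
        estimate_fdr(ids)
        targets = [x for x in ids if not x.is_decoy]
        assert all(x.q_value == 0.0 for x in targets)

    def test_interleaved_equal_scores_q_near_one(self):
        ids = []
        for i in range(50):
            ids.append(_id(5.0, decoy=False, seq=f"T{i}AK"))
            ids.append(_id(5.0, decoy=True, seq=f"D{i}AK"))
        estimate_fdr(ids)
        assert all(x.q_value > 0.9 for x in ids)

    def test_q_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(0)
        ids = [
            _id(float(rng.uniform(0, 30)), decoy=bool(rng.random() < 0.5),
                seq=f"S{i}K")
            for i in range(200)
        ]
        estimate_fdr(ids)
        ordered = sorted(ids, key=lambda x: -x.score)
        qs = [x.q_value for x in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_null_simulation_controls_fdr(self):
        # scores drawn from one null for targets and decoys: the decoy
        # estimate must not systematically understate the false rate
        false_calls, total_calls = 0, 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ids = [
                _id(float(rng.standard_exponential()), decoy=bool(i % 2),
                    seq=f"S{i}K")
                for i in range(400)
            ]
            estimate_fdr(ids)
            accepted = [x for x in ids if not x.is_decoy and x.q_value <= 0.05]
            # every target here is a false positive by construction
            false_calls += len(accepted)
            total_calls += len([x for x in ids if not x.is_decoy])
        assert false_calls / total_calls <= 0.05 + 3 * math.sqrt(
            0.05 * 0.95 / total_calls
        )


class TestReport:
    def test_final_report_dedupes_keeping_best(self):
        a = _id(10.0)
        b = _id(20.0)
        ids = estimate_fdr([a, b, _id(1.0, decoy=True)], allow_no_decoys=False)
        report = final_report(ids)
        assert len(report) == 1 and report[0].score == 20.0

    def test_summarize_counts_and_permutation_invariance(self):
        ids = [
            _id(10.0, base="T", seq="AAAK"),
            _id(9.0, base="T", seq="CCCK", site="2"),
            _id(8.0, base="C", seq="DDDK"),
        ]
        s1 = summarize(ids)
        s2 = summarize(list(reversed(ids)))
        assert s1 == s2
        assert s1["base_counts"]["T"] == 2 and s1["base_counts"]["C"] == 1
        assert s1["per_protein"]["P1"]["unique_peptides"] == 3

    def test_empty_summary(self):
        s = summarize([])
        assert s["n_crosslinks"] == 0
        assert all(v == 0 for v in s["base_counts"].values())
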