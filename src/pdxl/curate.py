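"""Curation rules, target-decoy FDR, and the final crosslink report.

Four curation rules are applied to every annotated candidate:

(i)   precursor charge assigned and the monoisotopic peak consistent —
      the observed neutral mass must sit within tolerance of the
      theoretical mass and not one neutron off;
(ii)  backbone coverage (a/b/y, shifted or unshifted) above 40 %;
(iii) for adducts of two or more nucleotides, at least one low-mass
      (m/z < 500) nucleotide/nucleobase marker ion matched;
(iv)  every peak above a relative-intensity threshold annotated
      (shifted/unshifted backbone, marker, immonium, internal, neutral
      loss, precursor-derived, or an isotope satellite of one of these).

Confidence is controlled by target-decoy FDR on the candidate score;
decoys are excluded from the final report, which is deduplicated by
(peptide, site, composition) keeping the best-scoring spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedSpectrum, LocalizationResult, localize

NEUTRON = 1.0033548378  # C12->C13 spacing, the isotope-error unit in Da

RULE_NAMES = ("charge_and_monoisotope", "coverage", "marker_ions", "peaks_explained")


@dataclass(frozen=True)
class CurationPolicy:
    coverage_threshold: float = 0.40
    marker_min_adduct_length: int = 2      # rule (iii) applies from this length
    marker_max_mz: float = 500.0
    high_intensity_fraction: float = 0.10  # of base peak, rule (iv)
    precursor_ppm_tol: float = 10.0
    isotope_check_da: float = 0.02         # window around +-1 neutron
    fdr_cutoff: float = 0.01

    def __post_init__(self) -> None:
        for name in ("coverage_threshold", "high_intensity_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class CrosslinkID:
    accessions: tuple[str, ...]
    peptide_label: str
    sequence: str
    localization: LocalizationResult
    adduct_label: str
    adduct_length: int
    base_call: str
    charge: int
    precursor_mz: float
    delta_ppm: float
    score: float
    q_value: float = math.nan
    is_decoy: bool = False
    rule_flags: dict[str, bool] = field(default_factory=dict)
    spectrum_id: str = ""

    @property
    def passes_curation(self) -> bool:
        return all(self.rule_flags.get(r, False) for r in RULE_NAMES)

    @property
    def site_string(self) -> str:
        if self.localization.site is not None:
            return str(self.localization.site)
        iv = self.localization.interval
        return f"{iv[0]}-{iv[-1]}" if iv else ""


def _rule_charge_monoisotope(
    annotated: AnnotatedSpectrum, theoretical_mass: float, policy: CurationPolicy
) -> bool:
    s = annotated.spectrum
    if s.precursor_charge < 1:
        return False
    obs = s.neutral_mass
    tol = policy.precursor_ppm_tol * 1e-6 * theoretical_mass
    # pass only when the monoisotopic mass itself matches; an observed
    # mass sitting a neutron off (wrong isotope picked) fails here and
    # is re-evaluated upstream at the corrected mass
    return abs(obs - theoretical_mass) <= tol


def _rule_coverage(annotated: AnnotatedSpectrum, policy: CurationPolicy) -> bool:
    return annotated.coverage > policy.coverage_threshold


def _rule_markers(annotated: AnnotatedSpectrum, policy: CurationPolicy) -> bool:
    if annotated.adduct is None or annotated.adduct.length < policy.marker_min_adduct_length:
        return True
    low_mass_markers = [
        ion
        for _, ion in annotated.matches
        if ion.series == "marker" and ion.mz < policy.marker_max_mz
    ]
    return len(low_mass_markers) > 0


def _rule_peaks_explained(annotated: AnnotatedSpectrum, policy: CurationPolicy) -> bool:
    s = annotated.spectrum
    if len(s.mz) == 0:
        return True
    threshold = policy.high_intensity_fraction * s.base_peak_intensity
    matched_idx = {k for k, _ in annotated.matches}
    matched_mz = s.mz[sorted(matched_idx)] if matched_idx else np.empty(0)
    for k in range(len(s.mz)):
        if s.intensity[k] < threshold or k in matched_idx:
            continue
        # allowance: isotope satellites (+1/+2 neutron, any charge 1-2)
        # of an annotated peak
        explained = False
        for z in (1, 2):
            for n in (1, 2):
                target = s.mz[k] - n * NEUTRON / z
                if matched_mz.size and np.min(np.abs(matched_mz - target)) < policy.isotope_check_da:
                    explained = True
                    break
            if explained:
                break
        if not explained:
            return False
    return True


def apply_rules(
    annotated: AnnotatedSpectrum, theoretical_mass: float, policy: CurationPolicy
) -> dict[str, bool]:
    return {
        "charge_and_monoisotope": _rule_charge_monoisotope(annotated, theoretical_mass, policy),
        "coverage": _rule_coverage(annotated, policy),
        "marker_ions": _rule_markers(annotated, policy),
        "peaks_explained": _rule_peaks_explained(annotated, policy),
    }


def make_crosslink_id(
    annotated: AnnotatedSpectrum,
    theoretical_mass: float,
    policy: CurationPolicy,
) -> CrosslinkID:
    """Curate one annotated candidate into a reportable record."""
    loc = localize(annotated)
    s = annotated.spectrum
    obs = s.neutral_mass
    pep = annotated.peptide
    return CrosslinkID(
        accessions=pep.peptide.parents,
        peptide_label=pep.label,
        sequence=pep.sequence,
        localization=loc,
        adduct_label=annotated.adduct.label if annotated.adduct else "",
        adduct_length=annotated.adduct.length if annotated.adduct else 0,
        base_call=loc.base_call,
        charge=s.precursor_charge,
        precursor_mz=s.precursor_mz,
        delta_ppm=(obs - theoretical_mass) / theoretical_mass * 1e6,
        score=annotated.score,
        is_decoy=pep.is_decoy,
        rule_flags=apply_rules(annotated, theoretical_mass, policy),
        spectrum_id=s.scan_id,
    )


def apply_curation(
    annotated_results: Sequence[tuple[AnnotatedSpectrum, float]],
    policy: CurationPolicy | None = None,
) -> list[CrosslinkID]:
    """Curate a batch of (annotated spectrum, theoretical mass) pairs."""
    policy = policy or CurationPolicy()
    return [make_crosslink_id(a, m, policy) for a, m in annotated_results]


def estimate_fdr(ids: Sequence[CrosslinkID], allow_no_decoys: bool = False) -> list[CrosslinkID]:
    """Assign target-decoy q-values in place and return the list.

    q(s) = min over score thresholds t <= s of #decoy(score >= t) /
    #target(score >= t); monotone non-increasing in score.  Requires
    decoy provenance unless ``allow_no_decoys`` (then all q = 0).
    """
    if not ids:
        return []
    if not any(x.is_decoy for x in ids):
        if not allow_no_decoys:
            raise ValueError(
                "no decoy hits present; search against a target-decoy database "
                "or pass allow_no_decoys=True"
            )
        for x in ids:
            x.q_value = 0.0
        return list(ids)
    ordered = sorted(ids, key=lambda x: -x.score)
    n_decoy = 0
    n_target = 0
    raw = []
    i = 0
    while i < len(ordered):
        # tied scores form one threshold: count the whole block first
        j = i
        while j < len(ordered) and ordered[j].score == ordered[i].score:
            if ordered[j].is_decoy:
                n_decoy += 1
            else:
                n_target += 1
            j += 1
        raw.extend([n_decoy / max(n_target, 1)] * (j - i))
        i = j
    # enforce monotonicity: q = min of raw FDP at any lower-score threshold
    q = raw[:]
    for i in range(len(q) - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    for x, qi in zip(ordered, q):
        x.q_value = min(qi, 1.0)
    return list(ids)


def final_report(
    ids: Sequence[CrosslinkID],
    policy: CurationPolicy | None = None,
    require_rules: bool = True,
) -> list[CrosslinkID]:
    """Filter to curated, confident targets; dedupe by (peptide, site, adduct)."""
    policy = policy or CurationPolicy()
    best: dict[tuple, CrosslinkID] = {}
    for x in ids:
        if x.is_decoy:
            continue
        if require_rules and not x.passes_curation:
            continue
        if not math.isnan(x.q_value) and x.q_value > policy.fdr_cutoff:
            continue
        key = (x.peptide_label, x.site_string, x.adduct_label)
        if key not in best or x.score > best[key].score:
            best[key] = x
    return sorted(best.values(), key=lambda x: (-x.score, x.peptide_label))


def summarize(ids: Sequence[CrosslinkID]) -> dict:
    """Base-distribution and per-protein summary of a crosslink report."""
    base_counts = {b: 0 for b in "ACGT"}
    per_protein: dict[str, dict[str, set]] = {}
    for x in ids:
        if x.base_call in base_counts:
            base_counts[x.base_call] += 1
        for acc in x.accessions:
            entry = per_protein.setdefault(acc, {"peptides": set(), "sites": set()})
            entry["peptides"].add(x.sequence)
            entry["sites"].add((x.sequence, x.site_string))
    return {
        "n_crosslinks": len(ids),
        "base_counts": base_counts,
        "per_protein": {
            acc: {
                "unique_peptides": len(e["peptides"]),
                "unique_sites": len(e["sites"]),
            }
            for acc, e in sorted(per_protein.items())
        },
    }


def report_table(ids: Sequence[CrosslinkID]) -> pd.DataFrame:
    """Final report as a DataFrame mirroring the per-crosslink columns."""
    rows = []
    for x in ids:
        rows.append(
            {
                "protein": ";".join(x.accessions),
                "peptide": x.peptide_label,
                "site": x.site_string,
                "composition": x.adduct_label,
                "base": x.base_call or "?",
                "charge": x.charge,
                "mz": round(x.precursor_mz, 4),
                "delta_ppm": round(x.delta_ppm, 2),
                "score": round(x.score, 2),
                "q_value": round(x.q_value, 4) if not math.isnan(x.q_value) else "",
                **{f"rule_{r}": x.rule_flags.get(r, False) for r in RULE_NAMES},
            }
        )
    columns = [
        "protein", "peptide", "site", "composition", "base", "charge",
        "mz", "delta_ppm", "score", "q_value",
        *[f"rule_{r}" for r in RULE_NAMES],
    ]
    return pd.DataFrame(rows, columns=columns)
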