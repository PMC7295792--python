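"""Control-run subtraction and precursor-level candidate matching.

Crosslink-specific species are isolated by comparing the irradiated run
against a non-irradiated control: the two runs are aligned on retention
time using precursors observed in both, and every irradiated precursor
that also appears in the control (same mass within tolerance, aligned
RT within a window) is removed before searching.  The survivors are
matched against the peptide-variant x adduct-composition candidate
space on neutral precursor mass.
"""

from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .adducts import AdductComposition
from .proteolysis import ModifiedPeptide
from .spectra_io import Spectrum, SpectrumRun, UNKNOWN_CHARGE

logger = logging.getLogger(__name__)

MIN_ANCHORS = 10


@dataclass(frozen=True)
class AlignmentModel:
    """Monotone map from control RT to irradiated RT.

    A robust (Theil-Sen) straight line fitted on anchor precursor
    pairs; identity with zero residuals when no reliable anchors exist.
    """

    slope: float
    intercept: float
    anchor_count: int
    residual_mad: float  # median absolute residual of anchors, seconds

    def __call__(self, rt_control: float) -> float:
        return self.slope * rt_control + self.intercept

    @classmethod
    def identity(cls, anchor_count: int = 0) -> "AlignmentModel":
        return cls(slope=1.0, intercept=0.0, anchor_count=anchor_count,
                   residual_mad=0.0)


@dataclass(frozen=True)
class PrecursorMatch:
    spectrum: Spectrum
    peptide: ModifiedPeptide
    adduct: AdductComposition | None
    theoretical_mass: float
    observed_mass: float
    charge: int

    @property
    def delta_ppm(self) -> float:
        return (self.observed_mass - self.theoretical_mass) / self.theoretical_mass * 1e6


def _anchor_pairs(
    irradiated: SpectrumRun, control: SpectrumRun, ppm_tol: float
) -> list[tuple[float, float]]:
    """(control RT, irradiated RT) pairs of precursors shared between runs.

    Each control precursor is paired with the irradiated precursor of
    closest RT among those matching within the mass tolerance.
    """
    irr = sorted(
        (s.neutral_mass, s.rt) for s in irradiated if s.precursor_charge != UNKNOWN_CHARGE
    )
    if not irr:
        return []
    masses = [m for m, _ in irr]
    pairs = []
    for s in control:
        if s.precursor_charge == UNKNOWN_CHARGE:
            continue
        m = s.neutral_mass
        tol = ppm_tol * 1e-6 * m
        lo = bisect.bisect_left(masses, m - tol)
        hi = bisect.bisect_right(masses, m + tol)
        if lo == hi:
            continue
        rt_irr = min((irr[k][1] for k in range(lo, hi)), key=lambda t: abs(t - s.rt))
        pairs.append((s.rt, rt_irr))
    return pairs


def align_runs(
    irradiated: SpectrumRun, control: SpectrumRun, ppm_tol: float = 10.0
) -> AlignmentModel:
    """Fit the control->irradiated RT map on shared-precursor anchors.

    Falls back to the identity map (with a warning) when fewer than
    ten anchors are available or the robust fit is non-monotone.
    """
    if len(irradiated) == 0 or len(control) == 0:
        raise ValueError("both runs must be non-empty")
    pairs = _anchor_pairs(irradiated, control, ppm_tol)
    if len(pairs) < MIN_ANCHORS:
        warnings.warn(
            f"only {len(pairs)} RT anchors; falling back to identity alignment",
            stacklevel=2,
        )
        return AlignmentModel.identity(anchor_count=len(pairs))
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:  # all anchors at one RT: only an offset is identifiable
        slope, intercept = 1.0, float(np.median(y - x))
    else:
        slope, intercept, _, _ = stats.theilslopes(y, x)
    if slope <= 0:
        warnings.warn("non-monotone RT fit; falling back to identity", stacklevel=2)
        return AlignmentModel.identity(anchor_count=len(pairs))
    resid = np.abs(y - (slope * x + intercept))
    return AlignmentModel(
        slope=float(slope),
        intercept=float(intercept),
        anchor_count=len(pairs),
        residual_mad=float(np.median(resid)),
    )


def subtract_control(
    irradiated: SpectrumRun,
    control: SpectrumRun,
    model: AlignmentModel | None = None,
    ppm_tol: float = 10.0,
    rt_tol: float = 120.0,
) -> SpectrumRun:
    """Remove irradiated precursors that are also present in the control.

    A spectrum is removed when any control precursor matches its
    neutral mass within ``ppm_tol`` and its aligned RT within
    ``rt_tol`` seconds.  Unknown-charge spectra are compared on m/z.
    """
    if ppm_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    if model is None:
        model = AlignmentModel.identity()

    ctrl = sorted(
        (
            s.neutral_mass if s.precursor_charge != UNKNOWN_CHARGE else s.precursor_mz,
            model(s.rt),
            s.precursor_charge,
        )
        for s in control
    )
    keys = [c[0] for c in ctrl]

    kept = []
    removed = 0
    for s in irradiated:
        known = s.precursor_charge != UNKNOWN_CHARGE
        key = s.neutral_mass if known else s.precursor_mz
        tol = ppm_tol * 1e-6 * key
        lo = bisect.bisect_left(keys, key - tol)
        hi = bisect.bisect_right(keys, key + tol)
        hit = any(
            abs(ctrl[k][1] - s.rt) <= rt_tol
            and (ctrl[k][2] == s.precursor_charge or not known or ctrl[k][2] == UNKNOWN_CHARGE)
            for k in range(lo, hi)
        )
        if hit:
            removed += 1
        else:
            kept.append(s)
    logger.info(
        "control subtraction: removed %d of %d spectra", removed, len(irradiated)
    )
    return SpectrumRun(
        run_id=irradiated.run_id,
        condition=irradiated.condition,
        spectra=kept,
        source_path=irradiated.source_path,
    )


Candidate = tuple[ModifiedPeptide, "AdductComposition | None"]


def build_candidates(
    peptide_variants: Sequence[ModifiedPeptide],
    adduct_space: Sequence[AdductComposition],
    include_unmodified: bool = False,
) -> list[tuple[float, Candidate]]:
    """Precompute the sorted (mass, candidate) list for precursor lookup.

    Candidate precursor mass = peptide (with mods) + adduct; the
    crosslink itself is zero-length and adds no extra mass.
    ``include_unmodified`` also adds adduct-free peptides (useful for
    alignment diagnostics, not for the crosslink report).
    """
    out: list[tuple[float, Candidate]] = []
    for pep in peptide_variants:
        pmass = pep.mass
        if include_unmodified:
            out.append((pmass, (pep, None)))
        for adduct in adduct_space:
            out.append((pmass + adduct.mass, (pep, adduct)))
    out.sort(key=lambda t: t[0])
    return out


def match_precursors(
    run: SpectrumRun,
    candidates: Sequence[tuple[float, Candidate]],
    ppm_tol: float = 10.0,
) -> list[PrecursorMatch]:
    """All (spectrum, candidate) pairs within the precursor tolerance.

    ``candidates`` must be sorted by mass (see :func:`build_candidates`).
    A spectrum may match several isobaric candidates; all are returned
    and MS2 annotation ranks them downstream.
    """
    if ppm_tol <= 0:
        raise ValueError("tolerance must be positive")
    masses = [m for m, _ in candidates]
    matches = []
    for s in run:
        if s.precursor_charge == UNKNOWN_CHARGE:
            continue
        obs = s.neutral_mass
        tol = ppm_tol * 1e-6 * obs
        lo = bisect.bisect_left(masses, obs - tol)
        hi = bisect.bisect_right(masses, obs + tol)
        for k in range(lo, hi):
            theo, (pep, adduct) = candidates[k]
            matches.append(
                PrecursorMatch(
                    spectrum=s,
                    peptide=pep,
                    adduct=adduct,
                    theoretical_mass=theo,
                    observed_mass=obs,
                    charge=s.precursor_charge,
                )
            )
    return matches
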