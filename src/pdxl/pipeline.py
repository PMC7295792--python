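"""End-to-end orchestration: config, search pipeline, structure check.

``run_search`` wires the full chain — FASTA + decoys, digestion,
variable-modification expansion, adduct-space enumeration, control
subtraction, precursor matching, fragment annotation, curation,
target-decoy FDR — and writes the crosslink report plus audit tables.
Outputs are deterministic given config and inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__, adducts, annotate, curate, proteolysis, search, spectra_io, structmap

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str = ""
    irradiated: list[str] = field(default_factory=list)
    control: list[str] = field(default_factory=list)
    output_dir: str = "pdxl_out"
    # tolerances
    precursor_ppm: float = 10.0
    fragment_ppm: float = 20.0
    rt_tol_seconds: float = 120.0
    # search space
    mod_profile: str = "invitro"
    max_variable_mods: int = 3
    nterm_carbamyl: bool = True
    max_missed_cleavages: int = 2
    peptide_min_length: int = 6
    peptide_max_length: int = 40
    adduct_max_length: int = 4
    adduct_bases: str = "ACGT"
    adduct_variants: list[str] = field(
        default_factory=lambda: list(adducts.TERMINAL_VARIANTS)
    )
    charge_min: int = 2
    charge_max: int = 6
    max_fragment_charge: int = 2
    # curation / FDR
    coverage_threshold: float = 0.40
    high_intensity_fraction: float = 0.10
    fdr_cutoff: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("precursor_ppm", "fragment_ppm", "rt_tol_seconds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def curation_policy(self) -> curate.CurationPolicy:
        return curate.CurationPolicy(
            coverage_threshold=self.coverage_threshold,
            high_intensity_fraction=self.high_intensity_fraction,
            precursor_ppm_tol=self.precursor_ppm,
            fdr_cutoff=self.fdr_cutoff,
        )


def search_runs(
    irradiated: spectra_io.SpectrumRun,
    control: spectra_io.SpectrumRun | None,
    database: Sequence[proteolysis.ProteinRecord],
    config: PipelineConfig | None = None,
) -> tuple[list[curate.CrosslinkID], list[curate.CrosslinkID]]:
    """Search one run pair; returns (final report, all scored PSMs).

    The database is target-only; decoys are generated here.  For each
    spectrum the best-scoring annotated candidate is kept as its PSM;
    q-values are estimated over all PSMs and the final report keeps
    curated targets under the FDR cutoff, deduplicated by
    (peptide, site, composition).
    """
    config = config or PipelineConfig()
    full_db = proteolysis.with_decoys(list(database))
    peptides = proteolysis.digest_database(
        full_db,
        max_missed=config.max_missed_cleavages,
        min_length=config.peptide_min_length,
        max_length=config.peptide_max_length,
    )
    variants = []
    for pep in peptides:
        variants.extend(
            proteolysis.expand_modifications(
                pep,
                profile=config.mod_profile,
                max_variable=config.max_variable_mods,
                nterm_carbamyl=config.nterm_carbamyl,
            )
        )
    space = adducts.enumerate_adducts(
        config.adduct_max_length, config.adduct_bases, config.adduct_variants
    )
    candidates = search.build_candidates(variants, space)
    logger.info(
        "search space: %d peptides, %d variants, %d adducts, %d candidates",
        len(peptides), len(variants), len(space), len(candidates),
    )

    run = spectra_io.filter_precursors(irradiated, config.charge_min, config.charge_max)
    if control is not None and len(control) > 0 and len(run) > 0:
        model = search.align_runs(run, control, config.precursor_ppm)
        run = search.subtract_control(
            run, control, model, config.precursor_ppm, config.rt_tol_seconds
        )

    matches = search.match_precursors(run, candidates, config.precursor_ppm)
    policy = config.curation_policy()

    best_per_spectrum: dict[str, tuple[annotate.AnnotatedSpectrum, float]] = {}
    for m in matches:
        ann = annotate.annotate_candidate(
            m.spectrum, m.peptide, m.adduct,
            ppm_tol=config.fragment_ppm,
            max_fragment_charge=config.max_fragment_charge,
        )
        key = m.spectrum.scan_id
        if key not in best_per_spectrum or ann.score > best_per_spectrum[key][0].score:
            best_per_spectrum[key] = (ann, m.theoretical_mass)

    psms = curate.apply_curation(list(best_per_spectrum.values()), policy)
    if psms:
        curate.estimate_fdr(psms, allow_no_decoys=True)
    report = curate.final_report(psms, policy)
    return report, psms


def run_search(config: PipelineConfig) -> Path:
    """File-level entry point: read inputs, search, write the report tree."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not Path(config.fasta).exists():
        raise FileNotFoundError(f"FASTA database not found: {config.fasta}")
    database = proteolysis.read_fasta(config.fasta)

    all_reports: list[curate.CrosslinkID] = []
    all_psms: list[curate.CrosslinkID] = []
    controls = list(config.control)
    for i, irr_path in enumerate(config.irradiated):
        irr = spectra_io.read_spectra(irr_path, "irradiated")
        ctrl = (
            spectra_io.read_spectra(controls[i], "control")
            if i < len(controls)
            else None
        )
        report, psms = search_runs(irr, ctrl, database, config)
        all_reports.extend(report)
        all_psms.extend(psms)

    # merge pairs: dedupe by (peptide, site, composition), keep best score
    merged: dict[tuple, curate.CrosslinkID] = {}
    for x in all_reports:
        key = (x.peptide_label, x.site_string, x.adduct_label)
        if key not in merged or x.score > merged[key].score:
            merged[key] = x
    report = sorted(merged.values(), key=lambda x: (-x.score, x.peptide_label))

    curate.report_table(report).to_csv(out / "crosslinks.tsv", sep="\t", index=False)
    curate.report_table(all_psms).to_csv(out / "psms.tsv", sep="\t", index=False)
    space = adducts.enumerate_adducts(
        config.adduct_max_length, config.adduct_bases, config.adduct_variants
    )
    adducts.adduct_table(space).to_csv(out / "adduct_space.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(curate.summarize(report), fh, indent=2)
    with open(out / "run_config.json", "w") as fh:
        json.dump(
            {"pdxl_version": __version__, **dataclasses.asdict(config)}, fh, indent=2
        )
    logger.info("wrote %d crosslinks to %s", len(report), out)
    return out


def run_structcheck(
    report: Sequence[curate.CrosslinkID],
    structure_path: str | Path,
    site_map: dict[str, tuple[str, int]],
    nucleotide_map: dict[str, tuple[str, int]] | None = None,
    atom_scope: str = "sidechain",
    threshold: float = structmap.DIRECT_THRESHOLD,
) -> tuple[list[structmap.StructureContact], list[str]]:
    """Measure contact distances for every resolvable reported site.

    ``site_map`` reconciles report numbering with author numbering:
    "<peptide>:<site>" -> (chain, residue number).  ``nucleotide_map``
    optionally pins each site to a specific nucleotide; otherwise the
    nearest nucleotide of the called base (or any base) is used.
    Unresolvable sites are returned as warnings, not dropped silently.
    """
    structure = structmap.load_structure(structure_path)
    contacts: list[structmap.StructureContact] = []
    warnings_out: list[str] = []
    resname = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
    for x in report:
        key = f"{x.sequence}:{x.site_string}"
        if key not in site_map:
            warnings_out.append(f"site {key} not in structure numbering map")
            continue
        chain, seqid = site_map[key]
        try:
            if nucleotide_map and key in nucleotide_map:
                nchain, nseq = nucleotide_map[key]
                contact = structmap.min_distance(
                    structure, chain, seqid, nchain, nseq,
                    atom_scope=atom_scope, threshold=threshold,
                )
            else:
                wanted = {resname[x.base_call]} if x.base_call else None
                contact = structmap.nearest_nucleotide(
                    structure, chain, seqid, wanted,
                    atom_scope=atom_scope, threshold=threshold,
                )
        except ValueError as exc:
            warnings_out.append(f"site {key}: {exc}")
            continue
        contacts.append(contact)
    return contacts, warnings_out
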