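# pdxl — peptide–DNA crosslink identification from tandem MS

UV irradiation of a protein–DNA complex forms **zero-length crosslinks**:
direct covalent bonds between amino-acid side chains and nucleotides, with
no spacer mass. After nuclease and tryptic (trypsin + Lys-C) digestion, a
crosslinked peptide carries a mono- to tetranucleotide remnant, and its
MS1 precursor is shifted by exactly the adduct mass:

    M_obs = M(peptide + modifications) + M(adduct)

where the adduct is a multiset of 1–4 deoxynucleotides, condensed with one
water per phosphodiester bond, plus a terminal variant from
{intact, −H2O, −HPO3, −H3PO4, +HPO3} — 345 candidate species over ACGT.
In MS2, backbone fragments spanning the crosslinked residue appear shifted
by the adduct (or by nucleotide −H3PO4/−HPO3/−H2O, nucleobase,
nucleobase −NH3, nucleobase −CO for thymine), and low-mass marker ions
(protonated base, base −NH3, nucleoside −H2O, nucleotide, the deoxyribose
oxocarbenium at m/z 117.055 and its −CO product at m/z 89.06) betray the
bases present. `pdxl` turns these signatures into identified, localized,
FDR-controlled crosslink sites:

1. **Control subtraction** — retention-time alignment (robust Theil–Sen)
   of an irradiated run against a non-irradiated control, removal of
   precursors present in both (the crosslink signal is
   irradiation-specific).
2. **Open adduct search** — precursor matching (10 ppm) against digested
   peptides × variable modifications × the 345-entry adduct space, with
   reversed-protein decoys.
3. **Annotation & localization** — theoretical shifted/unshifted ion sets
   matched at 20 ppm; the crosslink site is bounded by the largest
   unshifted b/y ions, covered shifted ions, and shifted immonium ions,
   with a steric veto on C-terminal K/R.
4. **Curation & FDR** — four explicit rules (charge/monoisotope
   consistency, >40 % backbone coverage, marker ions for ≥2-nt adducts,
   all high-intensity peaks explained) plus target-decoy q-values.
5. **Structure validation** — minimum side-chain–to–nucleotide heavy-atom
   distances in PDB/mmCIF structures; ≤16 Å is consistent with a direct
   contact, larger distances flag conformational flexibility.

It is a library first (`pdxl.chem`, `.adducts`, `.proteolysis`,
`.spectra_io`, `.search`, `.annotate`, `.curate`, `.structmap`,
`.simulate`, `.pipeline`) with a thin `pdxl` CLI
(`search`, `structcheck`, `simulate`, `fixtures`, `summarize`).
Intended users: mass-spectrometrists and structural biologists mapping
DNA-binding domains and residue-level protein–DNA contacts.

## Worked example

Simulate a paired irradiated/control run with five implanted crosslinks,
then search it:

```python
import numpy as np
from pdxl import simulate, pipeline
from pdxl.curate import report_table

cfg = simulate.SimulationConfig(seed=42, n_crosslinks=5, n_background=30)
proteins = simulate.random_proteins(np.random.default_rng(cfg.seed), cfg)
irr, ctrl, truth = simulate.simulate_pair(cfg, proteins)

report, psms = pipeline.search_runs(
    irr, ctrl, proteins,
    pipeline.PipelineConfig(mod_profile="none", max_fragment_charge=1),
)
print(report_table(report)[["peptide", "site", "composition", "base",
                            "charge", "mz", "delta_ppm", "score",
                            "q_value"]].to_string(index=False))
m = simulate.evaluate(report, truth)
print(f"recall={m['recall']:.2f} precision={m['precision']:.2f} "
      f"exact_site={m['site_exact_fraction']:.2f}")
```

prints

```
        peptide site composition base  charge        mz  delta_ppm  score  q_value
TMYPGSKMDDNEYVR   14         CCT    T       2 1353.4701       0.14  70.02      0.0
SIWPHAQFSMLEREK    7           T    T       3  727.6664       0.52  69.73      0.0
 SWSMLFNDWTDSDR    7    CCT-HPO3    ?       2 1290.4646       0.32  67.03      0.0
QVPQGFKVMHSVWGR   10      T-HPO3    T       2  999.5049       0.56  66.88      0.0
 ENWWISPLDIQYAR    8     G-H3PO4    G       2 1020.4896      -0.19  64.58      0.0
recall=1.00 precision=1.00 exact_site=1.00
```

Each row is one unique crosslink: the peptide, the localized residue
position within it, the adduct composition label (e.g. `CCT-HPO3` = a
CCT trinucleotide lacking one HPO3), the crosslinked base called from
base-specific shifted ions (`?` when the MS2 evidence cannot single out
one base of a mixed composition), charge, precursor m/z, precursor mass
error in ppm, the binomial-tail annotation score, and the target-decoy
q-value. All five implants are recovered at their exact sites with no
false positives.

The same search runs from files (FASTA + MGF/mzML) via the CLI:

```bash
pdxl fixtures --out-dir demo          # writes database.fasta + run pair
pdxl search config.yaml               # crosslinks.tsv, psms.tsv, summary.json
```

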