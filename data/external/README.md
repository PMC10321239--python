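# External inputs (not redistributed)

Four tests in `tests/test_acceptance.py` reproduce per-accession numbers
from the primary literature on the TsaC/Sua5 family and therefore need
deposited data that this repository does not redistribute. Place the files
below here and re-run the suite; everything else is fully offline.

Coordinate files (PDB format, `<ID>.pdb`, or mmCIF as `<ID>.cif`), from the
Protein Data Bank:

- `6F87` — Pa-Sua5 with threonine and pyrophosphate
- `2EQA`, `3AJE`, `4E1B` — St-Sua5 entries (the ligand-bearing ones are
  auto-detected by het content)
- `3VEZ` — TobZ (TsaC-like domain with carbamoyl phosphate)
- `3TTC` — HypF (TsaC-like domain with ADP)

Sequences (single-record FASTA under `uniprot/<ACC>.fasta`), from UniProt:

- `D2RFV3` (Ap-Sua5), `F2KMZ1` (Av-Sua5), `O29477` (Af-Sua5)
- `A_sulfaticallidus_sua5` — the archetypal Archaeoglobus sulfaticallidus
  Sua5 used as the erosion reference
- `D8TKZ3`, `A0A162WET7` — the worked HGT identity pair

Census input: `census_prokaryotes.fasta` — the prokaryotic one-per-genus
accession set of the family survey (deposited accession list; fetch the
sequences from UniProt).
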