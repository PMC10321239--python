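# Methods

## The model

The TsaC/Sua5 family of TC-AMP synthetases is treated as a two-variant
protein family distinguished by domain architecture and a single signature
alignment column. All per-residue statements are made in one of two fixed
reference numberings: the two-domain **Sua5 numbering** ("Pa-Sua5", 340
positions: catalytic domain 1–215, interdomain loop 216–240, SUA5 domain
241–340) and the single-domain **TsaC numbering** ("Ec-TsaC", 190
positions). A query is never scanned for motifs; it is globally aligned to
both reference chains, the higher-scoring alignment anchors the numbering,
and each annotated residue is read off the mapped column. This
reference-anchored read-out is what makes residue-level claims comparable
across homologs of different lengths.

### Annotation layout

The shipped annotation (`sua5kit/data/reference_annotation.json`, version
1.0, checksummed into every pipeline log) records: the catalytic tetrad
K56/R58 + Ser-x-Asn, the threonine-site residues T33/S181/R195, the six
Sua5-specific residues (P59, N62, H67, P142, H157, D161), the interface
motifs KPSPT ((K/R)149–T153) and GVE (G178–E180, the hydrophobic middle
position accepting V/I/L), the loop motifs PGM (228–230) and HY (234–235),
the SUA5-domain arginines R301/R328, and the signature position (143 ↔
138 across the two numberings).

One layout decision was forced: the classical numbering places both the
tetrad serine and the signature proline at position 143, which a single
chain cannot satisfy. The annotation keeps the signature at 143 (anchored
by the 143↔138 correspondence between the two numberings, the stronger
constraint) and places the tetrad Ser-x-Asn pair at 139/141. Both are
plain data in the JSON file and can be overridden.

### Synthetic reference templates

Real database sequences are not redistributed with the package. The two
reference chains are **synthetic templates**: every annotated residue is
planted at its annotated coordinate and all remaining positions are drawn
once from a fixed seeded stream. The TsaC template is derived from the
catalytic domain of the Sua5 template by a five-residue deletion (so that
Sua5 position 143 aligns to TsaC position 138, as in nature) plus
replacement of every Sua5-specific residue, including the natural
Asn62→Lys substitution. Consequences a user should keep in mind:

- classification, erosion and mapping behave exactly as documented on any
  query that is recognizably homologous to the templates;
- analyses of *real* family sequences against these synthetic anchors are
  meaningful only through the motif/signature logic, not through raw
  identity values;
- the acceptance-style tests that reproduce printed per-accession numbers
  require the real deposited entries (see `data/external/README.md`) and
  fail with a clear message without them.

## Classification rules

A sequence is a family member iff its length is within [100, 400] aa and
the mapped tetrad reads exactly K, R, S, N (a lenient mode accepting
K↔R and S↔T swaps exists, off by default). Members split as:

- **Sua5** — SUA5-domain evidence present and signature Pro;
- **atypical_sua5** — SUA5-domain evidence present but signature Thr/Ser,
  or the loop motifs (PGM/HY) lost;
- **TsaC** — no SUA5-domain evidence. A Pro-signature TsaC is kept as TsaC
  with a `proline_tsac` flag (the known natural exceptions are exactly
  such sequences).

"SUA5-domain evidence" is ≥ 2 of the 4 markers {KPSPT, GVE, R301, R328}.
The threshold is an operationalization choice: one marker can survive in a
TsaC by chance or convergence, two independent interface markers
practically cannot. A length-only fallback (≥ 290 aa suggests a
two-domain chain) is available in the lenient configuration but is never
used by default.

## Alignment

BLOSUM62 throughout; affine gaps in the BLAST cost convention (a gap of
length L costs open + L·extend), 10/0.5 for global and 11/1 for local
alignment — the community defaults, since no published parameter set
exists for this family. `X` is a wildcard scoring 0; selenocysteine is
mapped to Cys with a warning. Percent identity is identities over all
alignment columns including gap columns (the BLASTp convention), one
decimal. Co-optimal tracebacks are resolved deterministically (the
aligner's first traceback), so outputs are bit-stable. The
reference-anchored star alignment aligns each query to the reference
independently and indexes rows by reference column; insertions relative to
the reference are retained per query but not mutually aligned — sufficient
for column read-out, which is its only consumer.

## Trees and the HGT screen

Distances are 1 − identity-fraction from global alignment. Neighbor
joining is the canonical Saitou–Nei agglomeration with Q-criterion ties
broken by the lowest index pair and negative branch-length estimates
clamped to zero (logged). On additive inputs the true tree is recovered
exactly; the test suite verifies this against a brute-force least-squares
topology search and against an independent library implementation.
Bootstrap supports resample reference columns with replacement (100
replicates by default, seed mandatory); an alignment of identical rows has
no conflicting signal and gets support 100 by convention. Neighbor joining
here is a deliberate, documented stand-in for likelihood-based inference,
which is out of scope; the transfer screen only needs *a* reasonable tree
because its signal is placement incongruence, not branch-length accuracy.

The screen has two stages:

1. **Best-hit outliers.** For every record, the maximum-identity non-self
   record is found; the record is a candidate when the two taxonomies
   first diverge at or above the rank threshold (default: phylum;
   domain-level divergences are inherently reported by their rank). The
   stage is symmetric: a near-verbatim transfer makes donor and recipient
   each other's best hits, so both are flagged.
2. **Placement confirmation.** The candidate's nearest other leaves by
   patristic distance vote on its origin, excluding near-copies of the
   candidate itself (patristic distance ≤ 0.05): the transfer counterpart
   carries no information about the *direction* of the transfer, but its
   neighborhood does. Starting from two witnesses and extending on ties
   (up to six), the candidate is confirmed iff a strict majority carries a
   foreign label at the threshold rank. A grafted recipient sits among the
   donor's relatives and is confirmed; the donor keeps its own relatives
   and is not. Exact ties stay unconfirmed (conservative).

The nearest-witness formulation replaces a naive "smallest enclosing
clade" walk, which breaks when a donor–recipient cherry attaches at the
arbitrary root of the unrooted tree.

## Erosion

Erosion is measured on archetype coordinates: the query is globally
aligned to the archetype and a span's missing fraction is the percentage
of archetype span positions opposite gaps — i.e. "the query lacks N% of
the loop/domain", matching how such losses are described. Reported to one
decimal. The staging order is total missing fraction, then number of lost
motifs, with ties broken by length ascending (shorter = more eroded).
Span defaults come from the reference annotation (loop 216–240, SUA5
domain 241–340) and can be overridden per archetype.

## Structure contacts

Hydrogen bonds use a heavy-atom donor/acceptor distance criterion only
(N/O pairs, default cutoff 3.5 Å, no angle term): crystal structures lack
hydrogens, and the literature distances being reproduced are bare
donor–acceptor distances. Salt bridges pair Arg NH1/NH2/NE or Lys NZ with
Asp OD1/OD2 or Glu OE1/OE2 at 4.0 Å. Intra-residue pairs are excluded;
both tables are sorted by distance; distances are stored at full precision
and reported at 0.1 Å. Author numbering is authoritative; any mapping to
reference numbering goes through an explicit alignment-based residue map.
Ligands are identified by a het-code whitelist (PPI/POP, CP, ADP, THR,
TCA) with per-call override; where several related entries exist the
ligand-bearing one is auto-detected by het content. Altlocs resolve to the
highest-occupancy conformer; only the first model of multi-model files is
read.

## The synthetic-data generator

The generator defines the study conditions for every closure test:

- **Templates** as above (two-domain 340 aa — near the family's 331-aa
  average — and single-domain 190 aa).
- **Evolution along a known tree**: balanced (default) or random
  topology; per-branch per-site substitution probability 0.05 and
  per-branch indel probability 0.1 by default (one geometric-length indel
  event, ≤ 8 residues); annotated positions are immune to mutation — a
  deliberate conserved-site simplification so classifier accuracy is
  testable independently of divergence (`preserve_annotation=False` is a
  stress mode). Leaf taxonomies derive from the first three tree splits
  (domain/phylum/class), so phylogeny and taxonomy agree by construction.
  The true tree, variant labels and per-leaf column maps are recorded.
- **HGT injection**: recipients get a near-copy (≤ 2% substitution noise)
  of a donor from a different group at the divergence rank; taxonomy
  labels stay unchanged (that *is* the signal); donors are distinct across
  events and never themselves recipients, so each event has an
  unambiguous (recipient, donor) truth pair. Default screen conditions:
  32 taxa, 4 events (≈ 12% of leaves) — comparable transfer density to
  the worked screens this mirrors, at desk scale.
- **Erosion**: contiguous-biased deletions (geometric segment lengths,
  mimicking the natural indel pattern) removing the requested fraction of
  each span; the SUA5-domain arginine anchors are never deleted (their
  natural retention). Deletion patterns are rejection-sampled until the
  implied pairwise alignment is unambiguous — a gap flanked by an
  identical residue can slide across a span boundary in a co-optimal
  alignment, which would make the planted fractions ill-defined. The
  optional mutation set (signature Pro→Thr, Asn62→Lys, His67→Val)
  reproduces the natural atypical-Sua5 pattern.
- **Toy structures**: each requested contact is an isolated residue pair
  on a 50 Å grid, so planted distances are exact and nothing unrequested
  falls under any default cutoff.

All generators are bit-reproducible under a fixed seed.

### What the generator does not emulate

Rate heterogeneity across sites and lineages, realistic substitution
matrices (LG/WAG), motif decay in genuine homologs, compositional bias,
alignment uncertainty at high divergence, paralogy (e.g. the inactive
TsaC paralog YciO), and incomplete or chimeric database sequences. Passing
closure tests therefore demonstrates the *internal* correctness of each
method under its stated model, not its error rate on real survey data;
the per-accession literature checks (external data required) are the
bridge to real inputs.

## Numerical and degenerate-input conventions

Empty sequences, empty alignments, empty query sets, non-symmetric
distance matrices, duplicate ids, overlapping structure spans, zero
bootstrap replicates and out-of-range rates/fractions are rejected with
typed input errors. Local alignments with no positive-scoring pair return
an empty alignment with score 0. Tie-breaks are deterministic everywhere
(alignment traceback, NJ pair choice by lowest index, the two-reference
anchor tie toward the longer Sua5 reference, witness ordering by distance
then name). Pipeline outputs are pure functions of (inputs, config, seed):
rows sorted, floats fixed-format, and the annotation checksum logged so
every call table is traceable to an annotation version.

## Known limitations

- Identity values against the synthetic templates are not comparable to
  identities against real reference proteins; only motif logic transfers.
- The erosion spans are calibrated on the template layout; for a real
  archetype the spans must be supplied in that archetype's numbering.
- The HGT screen's witness vote assumes the tree's local neighborhoods
  are taxonomically coherent; at very high transfer density (donor groups
  depleted by multiple simultaneous events) recall degrades, which the
  default simulation conditions avoid by construction.
- Neighbor joining underestimates support for short internal edges
  relative to likelihood methods; supports here are column-bootstrap NJ
  supports and should be read as such.
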