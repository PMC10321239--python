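# sua5kit

Comparative sequence and structure analysis of the universal **TsaC/Sua5
family** of TC-AMP synthetases — the enzymes that catalyze the first step of
N6-threonyl-carbamoyl-adenosine (t6A) synthesis, one of the few tRNA
modifications conserved across all cellular life.

The family comes in two isofunctional variants. **TsaC** is a single-domain
protein (~190 aa). **Sua5** carries the same catalytic TsaC-like domain plus
an interdomain loop (~20 residues) and a SUA5 domain (~100 residues,
atypical Rossmann fold), for ~330–340 aa in total. sua5kit implements the
comparative analyses that distinguish, relate, and track these variants:

- **Variant classification** by reference-anchored residue read-out: family
  membership requires the catalytic tetrad K56-x-R58 / S-x-N (Pa-Sua5
  numbering) and a 100–400 aa length window; the variants are separated by
  SUA5-domain evidence (the interface motifs (K/R)149-P150-S151-P152-T153
  "KPSPT" and G178-Hyd-E180 "GVE", and the domain arginines Arg301/Arg328)
  together with the single **signature residue**: Pro143 in Sua5 versus
  Thr/Ser138 (Ec-TsaC numbering) in TsaC.
- **SUA5-domain erosion**: the fraction of interdomain-loop and SUA5-domain
  positions of an archetype Sua5 that a query has lost (aligned to gaps),
  plus lost loop motifs (P228-G229-M230, H234-Y235) — the "atypical Sua5"
  syndrome of proteins caught mid-way between the two variants.
- **Horizontal gene transfer screening** in two stages: a maximum-identity
  best-hit screen flags sequences whose nearest neighbor belongs to a taxon
  diverging at or above a rank threshold; candidates are confirmed by
  incongruent placement on a neighbor-joining tree (nearest-witness vote).
- **Interdomain contacts** on atomic coordinates (PDB/mmCIF): hydrogen
  bonds as heavy-atom N/O donor–acceptor pairs (default 3.5 Å) and salt
  bridges as Arg/Lys–Asp/Glu charged-group pairs (default 4.0 Å), with
  author-to-reference numbering maps obtained by alignment, never by
  offset arithmetic.
- A **synthetic-data generator** producing ground-truthed inputs for every
  stage: motif-bearing sequences evolved along a known tree (annotated
  sites conserved), injected cross-clade transfers, erosion series, and toy
  coordinate files with contacts at exactly known distances.

Trees are built with an in-repo neighbor-joining implementation
(deterministic tie-breaking, column-bootstrap supports); it is a documented
stand-in for maximum-likelihood inference, which is out of scope — the
screen's logic (incongruent placement) is method-agnostic.

The shipped reference pair is a pair of *synthetic template chains* that
carry every annotated motif at the canonical coordinates (real database
sequences are not redistributed); see `docs/methods.md`.

## Worked example

Generate a ground-truthed dataset (16 Sua5 sequences on a balanced tree,
two cross-phylum transfers injected), then run the whole pipeline:

```sh
$ sua5kit simulate sim --n-taxa 16 --seed 42 --hgt-events 2
$ cat > config.yaml <<EOF
fasta: sim/sequences.fasta
taxonomy: sim/taxonomy.tsv
outdir: out
seed: 42
EOF
$ sua5kit run-all config.yaml
```

`out/calls.tsv` holds one classification per sequence, with the evidence
columns (tetrad completeness, signature state and position, anchoring
reference, number of SUA5-domain markers found):

```text
id    call  length  length_ok  tetrad_complete  signature  signature_position  anchor_ref  sua5_evidence
t000  Sua5  340     True       True             P          143                 Pa-Sua5     4
t001  Sua5  340     True       True             P          143                 Pa-Sua5     4
...
```

`out/hgt_candidates.tsv` is the two-stage HGT screen. The generator planted
transfers into `t007` and `t010`; the best-hit stage flags both members of
each near-identical pair (the screen is symmetric: a copy cannot tell donor
from recipient), and the tree-placement stage confirms exactly the true
recipients, naming the donor clade:

```text
id    neighbor  identity_pct  rank_of_divergence  confirmed  sister_clade
t000  t010      97.6          0                   False
t003  t007      98.2          1                   False
t007  t003      98.2          1                   True       phy00
t010  t000      97.6          0                   True       phy00
```

`out/census.tsv` is the signature-residue census per variant class — here
all 16 sequences are Sua5 and all carry the signature proline:

```text
variant  P      T    S    other  n
Sua5     100.0  0.0  0.0  0.0    16
```

Contact detection on a toy structure with one hydrogen bond planted at
2.4 Å and one salt bridge at 3.0 Å:

```text
$ sua5kit contacts toy.pdb
kind         chain_a  res_a  atom_a  chain_b  res_b  atom_b  distance_A
salt_bridge  A        ARG2   NH1     B        ASP2   OD1     3.0
hbond        A        ASN1   ND2     B        SER1   OG      2.4
hbond        A        ARG2   NH1     B        ASP2   OD1     3.0
```

(the salt bridge reappears in the hydrogen-bond table: a charged pair at
3.0 Å is also a donor–acceptor pair, which is chemically accurate).

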