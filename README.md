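# cblscreen

Structural screening of CBL-type Ca²⁺ sensors and CIPK-type kinases in
predicted proteomes.

## What it does, and for whom

Calcineurin B-like proteins (CBLs) and CBL-interacting protein kinases
(CIPKs) form a two-component calcium-signalling module spread across plants
and many protist lineages.  Unlike most protein families, both partners are
recognizable from hard sequence-level hallmarks rather than overall
similarity:

- four EF-hand Ca²⁺-binding loops, with the six coordinating positions
  X, Y, Z, −Y, −X, −Z of each loop (−Z the terminal glutamate anchor);
- a diagnostic *first* EF-hand: canonical 12 residues with D at X in
  CaM/CNB/NCS proteins, but extended in CBLs — 14 residues with **S** at X
  (plants and relatives), 15 residues with **L** at X plus an inserted G and
  a Q-[HN]-E motif (stramenopiles), 19 residues
  (Aphanomyces/Saprolegnia clade), or a degenerate variant with **A** at X;
- an invariant F after the −Z position (L in CaMs);
- in land plants, an invariant 23-residue EF1–EF2 spacer, an N-terminal
  MGXXXS/T myristoylation motif and/or a palmitoylatable Cys-3, and a
  C-terminal FPSF phosphorylation motif;
- in CIPKs, the 21-residue NAF domain with its invariant Asn-Ala-Phe
  tripeptide, which a closely related class of kinases lacks.

`cblscreen` implements those hallmarks as a reusable pipeline for anyone
doing comparative surveys of Ca²⁺-decoding proteins: a Smith–Waterman
prefilter (in place of a BLASTp prescreen), an additive-scoring EF-hand
scanner over all four loop templates, a rule-based family classifier with
evidence strings, a PSSM-based NAF detector gated by the invariant
tripeptide, neighbor-joining grouping of the pooled CBLs with an
intraspecific-amplification (paralog-expansion) flag, and a per-species
CBL/CIPK census.  A synthetic-proteome generator with machine-readable
ground truth makes the whole pipeline testable end to end without any
downloads.  See `docs/methods.md` for the model details and limitations.

## Worked example

Simulate a two-species bundle — species A carries one plant-type CBL and a
CIPK; species B carries four non-plant CBL paralogs, a CIPK and a NAF-less
kinase, each proteome padded with decoys — then screen it:

```python
from cblscreen.synthetic_data import two_species_bundle
from cblscreen.screen import run_screen

proteomes, truth = two_species_bundle("bundle", seed=0)
result = run_screen(proteomes, out_dir="bundle/out")
for row in result.inventory:
    print(row["species"], row["n_CBL_total"], row["n_CIPK"],
          row["n_KINASE_NO_NAF"], row["amplification"])
```

prints

```
speciesA 1 1 0 False
speciesB 4 1 1 True
```

i.e. the census recovers one plant CBL and one CIPK for species A, and for
species B the four CBL paralogs (flagged as an intraspecific amplification
because they form a monospecific clade on the NJ tree of all pooled CBLs),
one CIPK and one kinase with a catalytic core but no NAF domain.
`bundle/out/` contains the per-protein annotation table, the census, the
newick tree of the pooled CBLs, the amplification report and a run log,
all stamped with the seed and config hash; reruns are byte-identical.

The same things are available from the shell:

```bash
cblscreen simulate --family CBL_PLANT --count 1 --n-decoys 5 --seed 1 --out sim/
cblscreen scan sim/proteome.fasta --out hits.tsv
cblscreen screen --proteome speciesA=bundle/speciesA.fasta \
                 --proteome speciesB=bundle/speciesB.fasta --out out/
```

Inspecting a single archetype shows the structural constants directly:

```python
from cblscreen import scan_ef_hands, compute_spacers
from cblscreen.synthetic_data import ArchetypeSpec, generate_archetype

record, _ = generate_archetype(ArchetypeSpec(family="CBL_PLANT", seed=1))
hits = scan_ef_hands(record)
print(len(hits))                                  # 4 EF-hands
print(hits[0].loop_end - hits[0].loop_start)      # 14  (extended first loop)
print(hits[0].x_res, hits[0].post_minus_z_res)    # S F
print(compute_spacers(hits)[0])                   # 23  (plant EF1-EF2 spacer)
```

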