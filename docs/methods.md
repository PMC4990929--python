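# Methods

## The screening problem

CBL-type calcium sensors (calcineurin B-like proteins) and their partner
CIPK kinases (CBL-interacting protein kinases) form a two-component Ca²⁺
signalling module found across plant and many protist lineages.  Both
families are defined by sequence-level structural hallmarks rather than by
overall similarity, which makes a rule-based structural screen both
feasible and informative:

- All the relevant sensor families (CaM, CNB/NCS, CBL) carry four EF-hands,
  helix-loop-helix Ca²⁺-binding motifs whose loop canonically spans 12
  residues with six coordinating positions labelled X, Y, Z, −Y, −X, −Z
  (X the first loop residue, −Z the terminal, usually bidentate, glutamate).
- CBL-type sensors are set apart by an *extended first loop*: insertions
  between the X and Y coordinates yield a 14-residue loop (serine at X) in
  plants and their closest relatives, a 15-residue loop (leucine at X, an
  inserted glycine, and a Q-[HN]-E motif in the loop middle) in
  stramenopiles, and a 19-residue loop in the Aphanomyces/Saprolegnia
  clade.  A degenerate variant carries alanine at X with a single-residue
  insertion.
- The residue immediately after −Z is an invariant phenylalanine in CBL,
  CNB and NCS proteins but a leucine in CaMs.
- Land-plant CBLs show an invariant 23-residue spacer between the first and
  second EF-hand loops (19–24 residues elsewhere), an N-terminal
  membrane-targeting signal (the MGXXXS/T N-myristoylation motif and/or a
  palmitoylatable cysteine at position 3) and a C-terminal FPSF
  phosphorylation motif.
- CIPKs are defined by the 21-residue NAF domain with its invariant
  Asn-Ala-Phe tripeptide; a closely related kinase without the NAF domain
  is a distinct, non-interacting class.

The package turns these hallmarks into a reproducible pipeline:
local-alignment prefilter → EF-hand scanner → family classifier (sensor
arm), kinase-core check → NAF detector (kinase arm), then distance-based
grouping of the pooled CBLs, an intraspecific-amplification flag, and a
per-species census.

## EF-hand scoring

The literature names the informative residues but prescribes no scoring
scheme, so the scanner uses a small additive model per loop window:

| term | values |
|---|---|
| −Z anchor | E +3.0, D +1.5, otherwise −5.0 |
| X | D/S +2.0, N +1.0, otherwise −2.0; on 15-residue windows additionally A +1.0, L +1.5 |
| Y, Z | +1.0 each if in {D,N,S,T,E,G,Q} |
| −X | +0.5 if in {D,N,S,T,E,G} |
| −Y | 0 (coordinates through the backbone carbonyl; any residue) |
| L15 bonuses | +1.0 for a G between X and Y, +1.0 for Q-[HN]-E starting at window offsets 4–8 |

The ambiguity code X contributes 0 at every position (draft proteomes
contain X runs; neutrality avoids both spurious hits and spurious misses).
The acceptance threshold is 4.0: an archetypal loop scores 7.5–9.0, and no
window can reach the threshold without an acidic −Z anchor *and* a
favourable X, so the weights encode the two hallmarks that the families
never lose.  The A/L bonuses at X are restricted to 15-residue windows
because that is the only loop length at which those exchanges are an
attested family signature (stramenopile and degenerate variants); on other
templates they would only add noise.  A consequence is that the 19-residue
extended-loop archetype keeps the ancestral serine at X — with leucine
there an L19 window could not clear the fixed threshold — and the
classifier assigns the extended family on loop length alone.

Candidate windows (all four templates, every start) are resolved to a
non-overlapping set greedily by score (descending), then start (ascending),
then loop length (ascending), capped at 6 hits per protein.  Spacers are
counted as residues strictly between consecutive loops, so the invariant
post-loop phenylalanine belongs to the spacer; the generator adopts the
same convention, making the plant spacer exactly 23.

At the default threshold the per-window false-positive probability on
uniform-composition random sequence is about 1% (measured over 1000
300-mers, >10⁶ windows).  Because a 300-residue protein offers ~1100
windows, almost every random protein contains *some* window hit; the
screen therefore never relies on a lone window but on the conjunction of
four hands, loop template, X identity, spacer and motifs — and, upstream,
on the prefilter.

## NAF detection

The Pfam NAF model is re-implemented as a 21×20 log-odds PSSM against a
uniform background, `entry(p,a) = log2((count+pc)/(n+20·pc)) + log2(20)`
with pseudocount 0.1: the family's discriminative signal is the invariant
tripeptide plus per-column conservation, so insert/delete states add
nothing at this scale.  The tripeptide is a hard constraint — a window
without a contiguous N-A-F at window offsets 6–12 is rejected regardless
of score — mirroring the biology, where deleting the NAF domain abolishes
sensor binding outright.  The default seed alignment is generated at run
time from twelve synthetic CIPK archetypes at substitution rate 0.1 (fixed
internal seeds); users screening real proteomes should supply a real seed
alignment (`read_seed_alignment`), one 21-mer per line or aligned FASTA.
The score threshold is 0 bits: better than background is enough once the
tripeptide constraint holds.  The kinase-core gate (HRD then DFG separated
by 10–60 residues) is deliberately crude — it distinguishes kinases from
sensors and decoys; it is not a kinase annotator.

## Classification rules

Ordered rules on the first four hits (these families have exactly four
EF-hands; later hits are reported but ignored): fewer than two hands →
unclassified; L12 with D at X → CaM-like (post-−Z L) or CNB/NCS-like
(post-−Z F, or low-confidence otherwise); L14 with S at X → plant CBL when
spacer = 23 *and* a membrane-targeting motif is present, else non-plant
CBL; L15 with L at X and the G-insertion or Q-[HN]-E evidence →
stramenopile CBL; L19 → extended CBL; L14/L15 with A at X → degenerate
CBL; otherwise a low-confidence non-plant call for four-hand proteins with
the post-−Z F, else unclassified.  Plant status requires both the spacer
and a lipid motif because both are stated to jointly distinguish plant
CBLs; the low-confidence fallbacks keep the screen sensitive to divergent
proteins that real surveys still list.  Window sizes "close to the
C-terminus" (40 residues, FPSF) and "N-terminal domain" (30 residues,
cysteine count) are package choices; no published values exist.

## Alignment, distances, trees

Pairwise alignment is Needleman–Wunsch (global, for distances) and
Smith–Waterman (local, for the prefilter) with BLOSUM62 and affine gaps
(a gap of length *k* costs 11 + *k*), via Biopython's PairwiseAligner;
an independently hand-coded Gotoh DP in the test suite cross-checks both.
Distance is 1 − identity with identity counted over all alignment columns,
so gap columns penalize the length heterogeneity that the loop-insertion
biology itself creates; a Poisson correction (−ln identity) is available
behind a config flag but off by default to keep distances bounded.
Neighbor joining is implemented in-repo: Saitou–Nei with negative limb
lengths clamped to zero (deficit moved to the sibling limb) and ties in
the Q criterion broken by the lexicographically smallest pair of cluster
representatives, making the topology independent of input order.  NJ is
exact on additive matrices, which the tests verify against simulated
trees.  Amplification detection asks, per species with ≥2 pooled CBLs,
whether some edge of the unrooted tree isolates exactly that species'
leaves — an unrooted monospecific-clade test that assumes no outgroup.
This is a proxy for amplification claims that in the literature rest on
posterior support values; it flags candidate expansions, it does not
re-derive support.

## The prefilter

The sensor arm's prescreen retains proteins whose best local-alignment
score against a CBL query (default: the zero-noise plant-CBL archetype)
reaches 0.25 × the query self-score — a self-score fraction rather than an
E-value because no database-size model is in scope.  The kinase arm runs
on the whole proteome: kinases do not resemble the sensor query.  For real
proteomes the query and fraction must be considered tunables.

## The synthetic-data generator

The generator is the package's test bed, not a sequence-evolution
simulator.  Each family is a fixed canonical blueprint: structural anchors
(coordinating residues, post-loop residue, lipid/FPSF/QHE/G anchors,
HRD/DFG, the N-A-F tripeptide) hand-placed, filler drawn once from a fixed
internal seed so that members of one family — and, through a shared
scaffold, members of related families — are genuine homologs with high
pairwise identity, as real paralogs are.  The per-record seed drives
everything record-specific: the non-plant EF1–EF2 spacer draw (uniform on
19–24; plants fixed at 23), decoy composition and length (uniform residues,
200–400 by default), and the substitution-noise process, which replaces
each *unconstrained* position with probability `substitution_rate` by a
uniformly chosen different residue.  Constrained anchors are never mutated:
noise therefore degrades context (prefilter similarity, classifier motifs
that happen to be unconstrained) but cannot destroy a planted loop's score,
and planted-loop recovery stays at 1.0 across the tested noise range —
the monotone-degradation check holds as equality.

Scaffold filler is restricted to motif-inert residues (I,K,L,V,W,Y: no
acidic anchors, no motif letters, no HRD/DFG constituents) so that at zero
noise the ground truth is exact by construction and every zero-noise
round-trip test is deterministic rather than probabilistic.  This is the
main idealization: real proteins have full residue composition everywhere,
real families differ by indels and domain rearrangements, and real decoys
contain EF-hand-like windows.  Passing tests therefore demonstrate the
correctness and determinism of the machinery — scanning, scoring,
classification, tree logic, orchestration — not field performance on real
proteomes, where thresholds (prefilter fraction, scan threshold, NAF seed
alignment) need calibration against curated examples.

## Determinism and numerical choices

Everything is deterministic given (inputs, config, seed): RNGs are
numpy `default_rng` seeded per record; greedy resolutions have total
tie-break orders; the screen sorts species before iteration and stamps
every output with the seed and a SHA-256 hash of the full config, so
identical runs are byte-identical.  Record ids are sequential SHA-1 hashes
of (proteome seed, index) and carry no family information; labels live
only in the ground-truth table.  Degenerate inputs are contracts, not
crashes: empty FASTA, duplicate ids and alphabet violations raise typed
errors with positions; per-species failures inside a multi-proteome screen
are logged and isolated rather than fatal.

## Problem sizes

The shipped tests and the acceptance script run on synthetic material
sized for a single CPU: archetypes of 160–190 residues, 1000 decoy
300-mers for the false-positive measurement, 100 seeds per family for the
confusion matrix, 50 seeds per noise level for the degradation curve, 100
random additive matrices (4–8 taxa) for NJ exactness, and a two-species
bundle (~24 proteins) for the end-to-end screen.  The whole suite runs in
a few seconds.

## Known limitations

- The EF-hand weights are a package invention; only their qualitative
  structure (anchor dominance, X identity, family bonuses) is anchored in
  the literature.
- The exact intra-loop position of the Q-[HN]-E motif is not published;
  offsets 4–10 of the L15 window are a package choice, configurable.
- The NAF tripeptide's exact offset within the 21-mer is likewise not
  published in machine-readable form; the permissive 6–12 default must be
  narrowed with a real seed alignment for real screens.
- The amplification flag is topology-only (no support values).
- The degenerate rule accepts either a 14- or a 15-residue first loop with
  A at X; published descriptions do not pin the loop length of that
  variant exactly.
- No indel noise, no domain shuffling, no evolution along trees in the
  generator.
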