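# Methods

## Data model and coordinate conventions

A mitogenome is a circular DNA sequence with features drawn from a
closed vocabulary of 38 keys: 13 protein-coding genes (PCGs), 22
tRNAs, 2 rRNAs and the control region (CR). The two leucine and two
serine tRNA isoacceptors are distinguished strictly by anticodon
(trnL1 = Leu-CUN/uag, trnL2 = Leu-UUR/uaa, trnS1 = Ser-AGN/gcu,
trnS2 = Ser-UCN/uga); a leucine or serine tRNA annotated without an
anticodon or codon-family suffix is left unmapped rather than guessed.

Coordinates are 0-based half-open internally; the 1-based inclusive
GenBank convention is converted only at the I/O boundary. A feature
may wrap the replication origin, in which case it carries two spans
(sequence tail, then head). The J ("majority") strand is defined as
the strand encoding cox1: records deposited with cox1 on the minus
strand have all strand labels flipped, which makes a genome and its
reverse-complemented twin indistinguishable downstream.

Duplicate annotations for one gene are an error by default (mirroring
the practice of discarding truncated/duplicated genes during curation)
but can be demoted to keep-first-with-warning. IUPAC ambiguity codes
are preserved in sequences and excluded from all composition counts.

## Gene-order comparison

Orders are circular signed permutations. Canonical form rotates an
anchor gene to the front in J orientation; the anchor is the first
present gene of (cox1, cob, rrnL), falling back to the
lexicographically smallest gene. cox1 is a safe default anchor because
it is present in essentially every published mitogenome and is the
most conserved PCG.

Given query and reference orders:

1. Deletions/insertions come from the gene-set difference. The CR is
   never reported as deleted: it is frequently real but unannotatable.
2. Both orders are reduced to the common gene set (at least 3 genes,
   otherwise the comparison is rejected as uninformative) and
   re-canonicalized on a common anchor.
3. A dynamic program finds the longest common subsequence (LCS) of
   signed elements, scoring first by length and second by the number
   of PCG + rRNA genes kept (large genes move rarely, so when two
   explanations are equally parsimonious the one that keeps them in
   place is preferred). Among remaining ties the lexicographically
   smallest displaced set is chosen; the DP tracks all optimal kept
   sets, capped at 64 variants per cell (real mitogenome comparisons
   stay far below the cap, where the tie-break is exact).
4. Displaced genes with flipped strand are inversions, the rest
   translocations. Breakpoints count reference adjacencies (signed,
   circular, orientation-symmetric) absent from the query.

Because both orders are permutations of the common gene set, deleting
the complement of any common subsequence makes them identical, and
conversely; so the number of displaced genes equals the true minimum
removal set with the anchor held fixed. The test suite checks this
equivalence exhaustively against a brute-force oracle on random signed
circular orders of up to 8 genes, and checks exact gene-for-gene
recovery of random scripts of up to 4 pairwise non-adjacent edits on
the full 38-gene order. Adjacent or interacting edits can be merged
into a cheaper explanation by any parsimony method; that limitation is
inherent to the problem, not to the implementation.

A note on genuinely ambiguous cases: when two genes are translocated
into adjacent positions such that more than one minimal displaced set
exists (e.g. inserting trnS2+trnQ between CR and trnI, where {trnS2,
trnQ} and {trnS2, trnI} both explain the order), the deterministic
tie-break decides; the displaced-set *size* is always exact.

## Model catalog and classification

The built-in catalog holds fifteen named springtail gene-order models.
Six are fully specified signed arrangements: the ancestral Pancrustacea
order (the reference), Tetrodontophora, Sminthurinus, GO A, GO D and
the Seira sp. 3 model. Two of these encode interpretations that are
flagged in the catalog notes: the Tetrodontophora destinations (trnS2
then trnQ between CR and trnI) and the Sminthurinus "inversion between
trnA and trnR" read as inversion of the two-gene block. The remaining
nine models (Podura, Pseudachorutes, GO B, GO C, Sminthurus, Allacma,
Lipothrix, Trogolaphysa, Seira paraibensis) are described in the
literature only by their edits — often with unknown destination
positions — and carry an *edit signature* (expected deleted / inverted
/ translocated sets relative to the base model, with alternatives
where the description is disjunctive, e.g. Podura's trnY "lost or
translocated"). Pseudachorutes names no gene set at all and is never
matched automatically.

Classification proceeds: **exact** (equal to a fully specified model up
to rotation; a query lacking only the CR still matches exactly) →
**compatible** (query genes are a subset of a model's and deleting the
missing genes from the model reproduces the query; fewest missing
genes wins, ties to the base model then catalog order) → **signature**
(the query's rearrangement report against the base model equals a
catalog signature) → **novel**. The `signature` outcome is an
extension of the exact/compatible/novel scheme, needed because a
signature-described model has no full arrangement to be exactly equal
to.

Genes absent from an annotation are treated as *missing* (feeding the
compatible logic), not as biological deletions — the cautious reading
used when assigning incomplete genomes to known models.

## Site classes and skews

Each annotated PCG is read codon-wise in mRNA sense. First- and
second-position bases accumulate into (J|N)1 and (J|N)2 by gene
strand; third-position bases go to 2(J|N)3 or 4(J|N)3 according to
the size of the codon's third-position synonymous family under the
invertebrate mitochondrial code (table 5): the nine four-fold prefixes
are CT, GT, TC, CC, AC, GC, CG, GG and AG (AGN is four-fold because
AGA/AGG encode serine in this code), all other sense codons are
two-fold. Stop codons (TAA/TAG only; TGA is tryptophan) and codons
containing ambiguity characters are excluded entirely — none of their
three bases is counted — and incomplete trailing codons are skipped,
so every coding base is either assigned to exactly one class or
explicitly excluded.

Counts are pooled across genes before the ratio is taken (one skew per
genome per class), not averaged per gene; with per-gene codon counts
spanning an order of magnitude, pooling weighs bases rather than
genes and keeps small genes from dominating the variance.

Skews are AT-skew = (A−T)/(A+T) and CG-skew = (C−G)/(C+G). A zero
denominator yields an undefined skew, encoded as missing and excluded
from outlier analysis — never imputed as 0, which would be an actual
skew value.

Skews here are computed alignment-free from annotated CDS. A survey
that computes them from an aligned, block-filtered supermatrix will
print slightly different numeric ranges because filtering removes
hypervariable columns; the qualitative structure (dispersion ordering
4JN3 > 2JN3 > JN2 > JN1 and the J/N asymmetry) is unaffected.

## Outlier rule

Per class and metric across a genome set: Q1 and Q3 by linear
interpolation between order statistics (the common default; the choice
of quartile method is not prescribed by the convention the rule comes
from), IQR = Q3 − Q1, fences at Q1 − k·IQR and Q3 + k·IQR with k = 3
("far out" in Tukey's terms). A value exactly on a fence is *not*
flagged — the rule reads "beyond". Fewer than 4 finite values: no
outlier analysis, with a warning.

## Synthetic genome generator

The generator emulates the features of real springtail mitogenomes the
analyses actually consume: a circular molecule with the 37 genes + CR
in any (possibly edited) signed order; per-strand, per-codon-position,
degeneracy-stratified base composition; canonical and alternative
start codons; complete and partial stop codons; planned intergenic
spacers and overlaps; and an arbitrary rotation of the deposited
origin (to exercise origin-wrapping features).

Defaults define the study conditions: realistic PCG codon counts
(3720 codons total across the 13 genes, cox1 = 512 … atp8 = 53), 65 bp
tRNAs, 1250/780 bp rRNAs, 600 bp control region, 2 bp default
intergenic gap, ATG starts, TAA stops, and class composition targets
that are AT-rich (~66–78% AT per class) with mild positive skews on
the J strand, negative on the N strand, and third-position classes the
most skewed — echoing the compositional structure reported for
springtails. A convenience map (at_fraction, AT-skew, CG-skew) →
(pA, pC, pG, pT) builds targets directly from skew space.

PCG internal codons draw position-1 and position-2 bases from the
class targets; the third base comes from the four-fold target when the
prefix is four-fold, otherwise from the two-fold target. TA-prefixed
codons (Tyr) can only carry C/T at the third position (TAA/TAG are
stops), which would bias the realized two-fold marginal; the non-TA
two-fold codons therefore draw from a compensated distribution such
that the mixture reproduces the two-fold target exactly. This makes
per-class skew recovery unbiased: the measured skews differ from the
targets only by multinomial sampling noise, and the acceptance suite
checks recovery within 3 standard errors at the default codon counts.
Internal codons are otherwise unconstrained by the genetic code — the
generator makes composition and order, not proteomes.

What the generator does *not* emulate, and what green tests therefore
do not show about real data: phylogenetic correlation between genomes,
annotation error and divergent naming (beyond what the normalizer's
synonym table covers), tRNA secondary structure, hypervariable control
regions, assembly artifacts and N-runs, and selection acting on
protein sequence. Overlapping genes share deposited sequence, with the
later-laid gene taking precedence — overlapping a PCG's terminus can
therefore alter its planned stop codon, as in real overlapping gene
pairs.

All randomness flows from one seeded NumPy generator; a spec (which is
YAML-serializable) plus its seed reproduces the genome and its on-disk
GenBank/FASTA/TSV files byte for byte (the GenBank date field is
pinned for this reason).

## Problem sizes and determinism of the validation suites

The acceptance checks use 200 random edit scripts on the 38-element
order, 300 random signed orders of 4–8 genes against the exhaustive
oracle, one default-size genome (3720 codons) for skew recovery, and
an 11-genome set with one engineered extreme genome for outlier
detection; together they run in a few seconds. The 3-standard-error
recovery bound is a per-class/per-metric check on a seeded simulation;
with 16 simultaneous checks a freshly drawn seed has a small (~4%)
chance of a benign excursion past 3 SE, which is the expected behavior
of the bound, not a defect — the seeded suites are deterministic.

## Known limitations

- Signature matching compares against the base model only; a genome
  that is, say, one extra edit away from the Lipothrix model is
  reported novel rather than "nearest Lipothrix". Rearrangement
  distances (DCJ/HP) and ancestral reconstruction are out of scope.
- The catalog encodes textual model descriptions; where the literature
  leaves destinations unspecified, exact matching is impossible by
  construction and signature matching is the designed behavior.
- Codon classification assumes the annotated reading frame; it does
  not scan for internal stops or frame errors.
- The FASTA + feature-table side channel carries gene name, strand,
  coordinates and anticodon only — qualifiers beyond these are
  GenBank-only.
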