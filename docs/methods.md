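# Methods

This note documents the models and procedures `hatscan` implements, the
parameters that matter, the numerical choices behind them, and what the
synthetic-data tests do and do not establish about real data.

## The foreign-gene screen

The screen treats a transcriptome of an obligate parasite as a mixture of
three populations: native transcripts, host-contaminant transcripts taken
up through the haustorium, and genuinely integrated foreign genes. Four
filters are applied in a fixed order; every transcript is annotated by
all of them so early rejects remain auditable.

**Stage filter.** A transcript must have abundance strictly above
`min_abundance` (FPKM units, default 0 — any positive value counts as
expressed) in at least one developmental stage sampled before the
parasite attaches to its host. Host mRNA cannot appear before a vascular
connection exists, so pre-attachment expression rules out contamination.
The pre-attachment stage set is data-dependent configuration (in the
standard stage key it is 0G and 2G).

**ORF length filter.** At least one maximal stop-free stretch strictly
longer than 100 aa across the six reading frames. The comparison is
strict (100 aa fails, 101 aa passes). ORFs are defined stop-to-stop with
no start-codon requirement: the screen targets homology, not gene models,
and a partial transcript's ORF need not begin with methionine. Codons
containing N translate to X, which never counts as a stop.

**Alien score ratio.** Hits are partitioned by subject taxon into self
(the screened species — never scored), ingroup (the recipient's clade)
and outgroup. R = best outgroup bitscore / best ingroup bitscore, and a
candidate requires R > 1.2 (strict). "Best" is highest bitscore, with
ties broken by lower e-value and then lexicographic subject id, making
the choice order-independent. R is invariant under any positive rescaling
of the scores, so the choice of bitscore over raw score cannot change a
verdict; the score type is nevertheless echoed in the run summary. A
query with outgroup evidence but no ingroup hit at all is a candidate
with R = ∞ and a `no_ingroup_hit` flag: total absence of ingroup homology
is stronger evidence of foreign origin than any finite ratio. No e-value
cutoff is applied before the ratio by default.

**Closest-relative nucleotide filter.** A transcript whose best
nucleotide-level hit lies in the designated closest ingroup relative
(default *Mimulus guttatus*) is removed as vertically inherited.
Transcripts with no nucleotide hits pass — deep nucleotide divergence
from the relative is the expected signature of a foreign gene.

The putative donor is the taxon of the best outgroup protein hit; an
exact score-and-evalue tie across taxa is reported in a separate
`donor_tie` field (deterministically resolved by the tie-break order).

## Similarity evidence

External search results enter as 12-column tabular hit files with a
prefix-based subject-to-taxon map. For self-contained operation the
package also computes local alignments with `Bio.Align.PairwiseAligner`
behind a `ScoringScheme` facade. Gap convention: a gap of length L scores
`gap_open + (L-1)·gap_extend`. Defaults are +1/−2 with gaps −5/−2 for
nucleotides and BLOSUM62 with gaps −12/−1 for proteins. Raw scores are
converted to bits with the Karlin–Altschul transform
bits = (λ·raw − ln K)/ln 2, with (λ, K) = (0.267, 0.041) for gapped
BLOSUM62 and (0.625, 0.41) for the nucleotide defaults; these constants
only set the bit scale and cancel in the alien ratio. Percent identity
counts identical aligned columns over all alignment columns, gaps
included. A non-positive best local score is reported as "no hit".

## TSD–TIR border structures

A hAT insertion is flanked by an exact 8-bp target site duplication (TSD)
and carries terminal inverted repeats (TIRs) of 8–23 bp. The finder
reports every coordinate tuple (left TSD, left TIR, interior, right TIR,
right TSD) in a window such that:

* the TSD copies match exactly — the duplication is created verbatim at
  insertion, so no tolerance is given (TIR tolerance is a separate,
  explicit parameter);
* the left TIR equals the reverse complement of the right TIR at every
  position, except that one mismatch may be tolerated at the outermost
  base (position 0 of the comparison, adjacent to the TSD) — the
  symmetric single-position reading of the "imperfect first base" rule;
* both TIR copies contain at least three distinct nucleotides. Applying
  the simple-repeat exclusion to both copies (not just the left) is what
  makes the search exactly strand-symmetric when a first-base mismatch is
  present;
* N never matches anything, including another N, in TSDs or TIRs.

All structures are reported, including overlapping and nested ones; there
is no maximality pruning. 8-mer TSDs are annotated (never filtered)
against the degenerate consensus (T/C)A(A/G)NG, scanned at offsets 0–3
because a 5-nt pattern cannot anchor an 8-nt TSD uniquely. Windows are
built as gene span ± 5000 bp (clamped), plus the intergenic segment
between consecutive genes, matching how borders of tandem copies are
inspected.

The production finder indexes TSD-length k-mers and validates candidate
position pairs; `brute_force_oracle` enumerates all coordinate tuples
exhaustively (guarded to ≤ 500 nt) with an identical output contract and
exists solely to verify the finder. The suite checks equivalence on 200
seeded random windows of 200–300 nt plus all constructed fixtures.

## Pseudogene calling

Candidates are aligned to an in-frame reference CDS by global alignment
with free end gaps on both sequences (semi-global), so partial candidates
are not charged for missing ends. Scoring defaults: match +2, mismatch
−3, gap open −10, gap extend −3. The gap costs are deliberately set so
that a fully substituted codon (three mismatches, −15 relative to
matches) is cheaper than a compensating indel pair (≥ −20): point
mutations are then never re-explained as two frameshifts.

* **Premature stops** are read codon-by-codon in the *reference frame
  projected through the alignment*: for each reference codon whose three
  positions all pair with candidate bases, those bases are translated.
  This keeps downstream codons in register after a frameshift — a linear
  translation of the candidate would scramble every codon behind an indel
  and generate spurious stop calls. A stop aligned to the reference's own
  final codon is not a lesion.
* **Frameshift indels** are contiguous internal alignment gaps (in either
  sequence) with length ≢ 0 mod 3. Each gap is one lesion: two separate
  1-nt and 2-nt gaps are two lesions even though they restore the global
  frame downstream, because each disrupts local coding. Terminal gaps
  (free ends) are never lesions, and clean in-frame indels never
  pseudogenize.

Candidates aligning over less than `min_aligned_fraction` (default 0.5,
measured as the fraction of reference positions paired with candidate
bases) are called *undetermined* and their lesion list is suppressed —
coverage too low to trust the call takes precedence over any lesions seen.

## Synteny

Species gene orders are compared against a reference arrangement of six
anchor genes (two upstream, labels `a`/`b`; four downstream, `1`–`4`)
bracketing the tandem transposase loci (`BO1`, `BO2a`, `BO2b`). Anchor
losses do not break order conservation: order is judged over the anchors
present, and a full block reversal is tolerated and flagged. Orientation
flips are counted after normalizing for block reversal, for anchors and
transposase entries alike. The tandem test asks that no anchor intervenes
inside the transposase block and that the block lies between anchors `b`
and `1`. Anchor assignment from hit tables is best-hit (not
reciprocal-best) with a 50-bit floor; two anchors claiming one locus are
resolved by bitscore and the conflict logged. Reference strands in the
built-in arrangement are a synthetic stand-in (all `+`); only relative
orientation is ever used.

## Expression

FPKM = fragments × 10⁹ / (effective length in bp × total mapped
fragments); effective length defaults to the annotated transcript length
(no fragment-length correction). The reference level for RNA-seq is the
sum of the usable reference-gene isoforms — mirroring the situation where
only the isoforms containing the qPCR primer sites are comparable across
platforms. qPCR relative expression uses the comparative Ct method on Ct
means, 2^−(Ct_target − Ct_ref), within a condition; no calibrator
condition is baked in, so cross-condition contrasts are ratios of
within-condition values. Ct standard errors are passed through without
propagation.

## The synthetic-data generator

`make_screen_dataset` emulates exactly the statistical structure the
screen assumes. Per gene family an ingroup reference CDS is drawn with
uniform random sense codons; the donor reference is that CDS mutated at
`sub_prob_donor` (default 0.35) and a second outgroup reference at a
further 0.15. Native transcripts diverge from ingroup references at
`sub_prob_ingroup` (default 0.05), foreign transcripts from donor
references at 0.05, contaminants from donor references at 0.02 (the host
is the donor-like taxon). Transcript mutation is codon-aware and never
creates in-frame stops, since the generated genes represent intact coding
sequences; the generic `mutate` (uniform substitutions plus geometric
mean-2 indels) is used where reading frames are irrelevant. Defaults of
20 native / 5 foreign / 3 contaminant transcripts of 360–600 nt define
the standard dataset. Hit tables are computed with the built-in aligner
at both protein and nucleotide level and reported above a 40-bit floor,
emulating a search tool's reporting cutoff. Stage tables give every
native/foreign transcript positive abundance in all stages and
contaminants zero before attachment. All outputs are byte-identical under
a fixed seed and tagged with a configuration hash.

With these settings the foreign transcripts sit ≈0.05 substitutions from
the donor references but ≈0.38 from the ingroup references — far enough
that their nucleotide-level ingroup similarity falls below the reporting
floor, reproducing the "no significant nucleotide similarity to the
relative" signature, while natives show the reverse pattern.

`plant_te` inserts TSD+TIR+interior+revcomp(TIR)+TSD at a chosen
position, with optional lesions: `outer_tir_base` (detectable, flagged
imperfect) or `tsd_mismatch` (undetectable by design, used to test
rejection). Planted TIRs must pass the composition filter, otherwise the
configuration is rejected as undetectable-by-construction.
`plant_lesions` plants premature stops (the nearest stop codon, fewest
substitutions) and frameshift indels into a CDS copy; lesion sites are
kept ≥ 4 codons from the ends and in locally non-repetitive context,
because an indel at a free end is absorbed into the end gap and an indel
inside a homopolymer has no unique gap placement — in both cases the
"expected position" would be ill-defined rather than wrongly recovered.

**What passing tests show — and don't.** The generator's uniform
substitution model has no transition/transversion bias, no rate
heterogeneity, no codon usage structure, and independent sites; gene
families are unrelated to each other; expression values are uniform
draws. Perfect precision/recall under these separable conditions
demonstrates that the pipeline's logic is correct, not that real
transcriptomes — with shared domains, recent paralogs, assembly chimeras
and incomplete taxon databases — will separate this cleanly. The manual
curation step that follows any real screen is out of scope.

## Problem sizes and runtime

The test suite and acceptance script use: 200 random windows of 200–300
nt for oracle equivalence (the brute-force oracle is quadratic in window
length, and this size yields thousands of TSD-pair candidates in total);
50 planted border structures over the grid TIR ∈ {8, 15, 23} × interior
∈ {50, 500} nt in 1.5-kb backgrounds, plus 12 TSD-mutated plants; the
standard 28-transcript screen dataset; 100 lesioned coding candidates of
140–220 codons plus 20 in-frame-deletion controls. The full suite runs
in well under a minute on one CPU; the acceptance script in ~10 s.

## Known limitations

* The aligner is full dynamic programming without heuristic seeding —
  appropriate at test scale, not for genome-wide search.
* E-values are not estimated; hit tables may carry them from an external
  search, and they are only used for tie-breaking.
* The screen's "first hit" is operationalized as the best hit per
  partition class, one top hit overall rather than one per taxon.
* Pseudogene calling is splice-unaware and offers no dN/dS or
  relaxed-selection evidence.
* The synteny module compares labeled gene-order tables; it does not
  discover synteny blocks genome-wide, and ortholog inference is best-hit
  only.
* The comparative-Ct implementation assumes perfect amplification
  efficiency and reports raw ratios without error propagation.
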