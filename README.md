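# hatscan

Screening and annotation of horizontally transferred **hAT transposase
genes** in parasitic-plant transcriptomes.

Parasitic plants such as the broomrapes (*Orobanche*, *Phelipanche*,
Orobanchaceae) draw water, nutrients and macromolecules from their hosts
through haustoria, and occasionally integrate host DNA into their own
genomes — horizontal gene transfer (HGT). `hatscan` implements, as a
tested and reusable pipeline, the computational procedures needed to
detect foreign hAT-superfamily (class II, cut-and-paste) transposase genes
in a parasite transcriptome and to characterize them:

1. **Foreign-gene screen** (`hatscan.hgt_screen`) — candidate transcripts
   must be (i) expressed in developmental stages sampled *before* host
   attachment (excluding host mRNA contamination), (ii) carry a stop-free
   ORF longer than 100 aa, (iii) have an **alien score ratio**

   > R = best outgroup bitscore / best ingroup bitscore > 1.2

   where the ingroup is the recipient's own clade (e.g. Lamiales,
   including *Mimulus guttatus*) and the outgroup everything else, and
   (iv) not have their best nucleotide-level hit in the designated closest
   ingroup relative. The putative donor is the taxon of the best outgroup
   hit. R is scale-free in the scores, so the verdicts do not depend on
   the score type.
2. **TSD–TIR border-structure search** (`hatscan.tsd_tir`) — an active hAT
   insertion is bracketed as TSD–TIR–transposase–TIR–TSD: an 8-bp target
   site duplication repeated exactly on both sides, and terminal inverted
   repeats of 8–23 bp, each the reverse complement of the other, with at
   most one mismatch tolerated at the outermost TIR base. TIRs built from
   fewer than three nucleotide types are excluded as simple repeats, and
   8-mer TSDs are annotated against the degenerate hAT consensus
   (T/C)A(A/G)NG. A brute-force enumeration oracle cross-checks the
   indexed finder.
3. **Pseudogene calling** (`hatscan.pseudogene`) — candidate coding
   sequences are aligned semi-globally to a reference CDS; premature stop
   codons (read in the reference frame through the alignment) and
   frameshift indels (contiguous internal gaps with length ≢ 0 mod 3) are
   reported as lesions. In-frame indels do not pseudogenize.
4. **Synteny analysis** (`hatscan.synteny`) — conservation of six anchor
   genes flanking the tandem transposase loci across species: anchor
   losses, order conservation (block inversions tolerated and flagged),
   strand flips, and whether the transposase genes remain a tandem block.
5. **Expression summarization** (`hatscan.expression`) — FPKM from
   fragment counts, reference levels as the sum of usable reference-gene
   isoforms, and qPCR relative expression by the comparative Ct method,
   2^−(Ct_target − Ct_reference), within condition.

Similarity evidence enters either as standard 12-column tabular hit files
(`hatscan.similarity.read_hit_table`) or from the built-in affine-gap
local aligner, so the whole pipeline runs self-contained. The
`hatscan.synthetic_data` module generates every input with a ground-truth
manifest — planted foreign genes, planted border structures, planted
coding lesions, planted synteny edits — which is what the test suite and
the acceptance script measure recovery against.

## Worked example

Generate a synthetic transcriptome (20 native genes at 5% divergence from
the ingroup references, 5 planted foreign genes derived from donor-taxon
references at 35% divergence, 3 host contaminants silent before
attachment) and screen it:

```sh
hatscan simulate --seed 1 --out-dir demo/sim
hatscan screen --dataset-dir demo/sim --out-dir demo/screen
# INFO hatscan: 5 of 28 transcripts are candidates
head -6 demo/screen/verdicts.tsv | cut -f1-7
```

```text
transcript_id  best_ingroup_bitscore  best_outgroup_bitscore  ratio   flags                 candidate  putative_donor
contig_0001    235.7300               75.4800                 0.3202  nt_relative_filtered  false      Sisymbrium_irio
contig_0002    234.5700               60.8500                 0.2594  nt_relative_filtered  false      Sisymbrium_irio
contig_0003    120.1700               367.4700                3.0579  -                     true       Sisymbrium_irio
contig_0004    155.9900               377.1000                2.4175  stage_filtered        false      Sisymbrium_irio
contig_0005    71.2500                327.7900                4.6006  -                     true       Sisymbrium_irio
```

`contig_0001` is a native gene: its best protein hit is in the ingroup
(bitscore 235.7 vs 75.5, ratio 0.32) and its best nucleotide hit is the
closest relative, so it is filtered. `contig_0003` is a planted foreign
gene: ratio 3.06 > 1.2 with no failing filter, so it is a candidate, and
its best outgroup homolog names the simulated donor taxon.
`contig_0004` has an alien-looking ratio but is only expressed after host
attachment — the contamination filter removes it. The five candidates are
exactly the five planted foreign transcripts in
`demo/sim/manifest.json`.

The other stages work the same way, e.g.:

```sh
hatscan tsdtir --windows windows.fasta --out structures.tsv
hatscan pseudo --candidates cands.fasta --reference ref.fasta --out report.tsv
```

## Layout

```
src/hatscan/         library modules (one per pipeline stage)
tests/               pytest suite, including end-to-end acceptance tests
scripts/acceptance.py   from-scratch recomputation of headline quantities
docs/methods.md      models, parameters, numerical choices, limitations
```
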