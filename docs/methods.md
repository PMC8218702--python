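# Methods

## Coordinate conventions

All internal genomic coordinates are 1-based and inclusive, expressed in
*transcription orientation*: `start_pos` is the first transcribed
nucleotide of the start codon and `stop_pos` the third (last transcribed)
nucleotide of the stop codon, so on the minus strand `start_pos >
stop_pos`. This follows the way start/stop are defined by codon nucleotide
order rather than by interval order; interval-style operations (overlap,
BED export) use the derived `(low, high)` bounds, and BED12 export converts
to 0-based half-open.

The stored nucleotide length **includes the stop codon**. Consequently the
encoded peptide has `length_nt / 3 − 1` residues, and a reported length
given in amino acids is converted as `nt = 3·(aa + 1)`. This convention is
applied uniformly: the theoretical length used by QC, the sequences
extracted from the genome, and the peptide lengths used for the ≤ 100 aa
"short" flag are all consistent with it.

## Source quality control

The theoretical length of an entry is `|start − stop| + 1` minus the summed
gaps between its splice blocks. An entry counts as length-mismatched only
when both the theoretical and the reported length are computable and
differ; entries with an uncomputable length are excluded from the
denominator (counting them would punish sources for honest missing data
rather than for wrong data). A source is rejected when the mismatch
fraction exceeds 0.95 — such a systematic discrepancy indicates splicing
information was dropped upstream, making every spliced coordinate pair
unreliable. Rejection is a default the pipeline flag
`override_qc_rejection` can lift for audit runs; the QC report is persisted
either way.

## Liftover

A native UCSC chain-file interpreter remaps each coordinate of an entry
independently (start, stop, every splice-block bound). Failure criteria are
checked in a fixed order so tallies are deterministic: **unmapped** (a
coordinate falls in a chain gap) → **strand** (remapped positions disagree
with each other; a uniform flip of all positions together is accepted and
flips the record's strand) → **chromosome** (the chromosome changed) →
**distance** (`|start − stop|` changed; integer equality, no tolerance).
The distance criterion uses the genomic span, not the spliced length,
because liftover runs before transcript attachment. Failed entries are
dropped and tallied per status. The backend is pluggable: anything
implementing `map_position(chromosome, position)` can replace the built-in
`ChainMap`.

## Two-phase merge

Phase one groups entries whose full identification feature set is present
and identical — chromosome, strand, start, stop, splicing status and the
canonicalized splice-block string (sorted, comma-joined `start-end` pairs).
Each group becomes one unique ORF with `experiment_count` = group size and
unioned provenance (sources, methods, transcripts, cell types).

Phase two rescues partially described leftovers. A leftover qualifies when
it provides the chromosome plus one of: (i) strand and start, (ii) strand
and stop, (iii) start and stop; these three patterns are exhaustive — a
chromosome with a single coordinate is unusable and dropped. Candidates are
the uniques agreeing on every field the leftover provides. "Best match" is
decided by a deterministic cascade: agreement on optional fields in fixed
order (reported length against the unique's theoretical length, then start
codon, then splicing status), then the highest current experiment count,
then the lexicographically smallest identity key. The cascade is a total
order, so the merge result is reproducible and invariant under input
shuffling; each leftover is absorbed by exactly one unique (its experiment
count increments — an absorbed entry is still an independent description of
the ORF) or dropped, preserving `Σ experiment_count + dropped = input
count`.

## Classification

Classes are assigned per ORF-to-transcript association, since the same ORF
can be a uORF on one transcript and CDS-overlapping on another; the
ORF-level class set is the union over its transcripts. The decision order,
using 1-based spliced-transcript coordinates and the annotated CDS interval
`[cs, ce]` (stop codon included, matching the ORF convention):

| condition | label |
|---|---|
| biotype `nonsense_mediated_decay` | NMD-ORF |
| biotype `non_stop_decay` | NSD-ORF |
| non-coding or unknown biotype, or no CDS | ncRNA-ORF |
| `rs == cs and re == ce` | CDS |
| `re < cs` | uORF |
| `rs < cs` | upstream-overlapping |
| `rs > ce` | dORF |
| `re > ce` | downstream-overlapping |
| inside CDS, `(rs − cs) % 3 ≠ 0` | CDS-internal-altframe |
| inside CDS, same frame | CDS |

An ORF strictly inside the CDS and in frame is an N-terminal truncation
sharing the annotated stop, so it carries the CDS label; only the exact
coincidence and this truncation case share it. ORFs attached to no
transcript and overlapping no gene are labelled intergenic. NMD/NSD labels
are assigned purely by transcript biotype, before any positional test. An
ORF whose boundaries are not exonic on a transcript is *flagged* (the
association is counted, not silently dropped). The "short" flag (≤ 100
amino acids) is carried separately from the class so longer ORFs are
retained rather than filtered.

## Kozak contexts

Positions are counted from the first start-codon nucleotide (+1). With the
upstream window `−6…−1` and the `+4` nucleotide:

- **optimal** — upstream hexamer matches `gcc[AG]cc` and +4 = G;
- **strong** — −3 ∈ {A, G} and +4 = G, without the full hexamer;
- **moderate** — exactly one of the two conditions;
- **weak** — neither;
- **undefined** — fewer than 3 nt upstream or no +4 nt available.

The optimal conditions strictly imply the strong conditions (verified by
exhaustive enumeration in the tests). For non-ATG start codons the same
positional tests are applied and the call carries a `alike` flag. When an
ORF sits on several transcripts whose UTRs differ, the ORF-level call is
the strongest defined category across its associations.

## Enrichment statistics

Both the gene list and the uORF-harboring feature set are intersected with
the universe before any counting (this makes the feature-set size
interpretable against the universe total). The p-value is the upper-tail
hypergeometric probability computed on the log scale (`hypergeom.logsf`),
which remains accurate at magnitudes around 1e−61. The odds ratio is the
sample (cross-product) estimate from the 2×2 table,
`k(N−n−K+k)/((n−k)(K−k))`, not a conditional-MLE estimate; it is exactly 1
on proportional tables and infinite when a denominator cell is 0.
Benjamini–Hochberg step-up adjustment is applied across the family of lists
tested together, with significance declared at FDR < 0.05.

## Synthetic fixtures

The generator *designs* every planted ORF rather than discovering it: the
class is fixed by placing the annotated CDS relative to the ORF on its host
transcript; the Kozak category by engineering the upstream hexamer and the
first nucleotide of the second codon (the +4 position); the sequences by
concatenating a start codon, stop-free sense codons and a stop codon. Each
planted ORF gets its own transcript; transcripts alternate strands and are
laid out with intergenic gaps on a random-background genome, with introns
placed inside ORFs to exercise spliced identity keys. The manifest
(identity keys, classes, Kozak categories, sequences, expected experiment
counts) fully determines the expected pipeline output.

Catalog emulation: each planted ORF is listed by a configurable number of
sources; corruption modes (drop strand, drop stop, strip splice blocks,
report amino-acid lengths) emulate real source heterogeneity, and a
"shifted build" source paired with a rigid-shift chain file exercises the
liftover stage. Random draws use independent seeded streams per purpose
(genome vs. catalogs), so adding a corruption mode does not perturb earlier
draws.

What the fixtures do **not** emulate: real Ribo-seq read evidence,
ambiguous multi-transcript loci with overlapping genes, chain files with
fragmented multi-chromosome alignments, and the scale of real catalogs
(millions of entries). Passing closure tests therefore demonstrates the
correctness of the coordinate arithmetic, merging logic and annotation
rules, not robustness to every pathology of real source data.

## Problem sizes and numerical choices

The default fixture configuration plants 10 ORFs on 2 chromosomes of a few
kilobases across 3 sources with redundancy 2 — small enough that exhaustive
oracles (pairwise merge comparison, brute-force overlap scans, full
enumeration of hypergeometric draws at N ≤ 12 and of all 4⁷ Kozak
heptamers) are practical, while still covering every class, both strands,
spliced and unspliced keys and all four context strengths. The
classification/Kozak closure property is checked over 20 independent seeds.
Integer coordinate arithmetic is exact throughout; the only floating-point
tolerance in the package's own logic is the printed rounding of odds ratios
(2 decimals, matching the convention for reporting them).

## Known limitations

- The partial-merge preference cascade is a pragmatic total order; other
  defensible tie-breaks exist, and with conflicting optional-field
  preferences among leftovers the outcome can depend on which rule fires,
  though never on input order for any fixture generated here.
- Chain inversion helpers only support plus-strand chains; strand-flipping
  chains are interpreted on mapping but not invertible by the helper.
- Gene recovery uses annotation extents (union of transcript spans), not
  exon-level overlap.
- Conservation/coding-potential scores (PhyloCSF, PhastCons, FLOSS, ORF
  score) are pass-through provenance fields; they are never computed.
- Cell-type normalization is a user-supplied two-column mapping; unmapped
  labels pass through with a warning rather than being dropped.
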