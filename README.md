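# sorfkit

Harmonization of heterogeneous short-ORF catalogs into a non-redundant,
uniformly annotated repository.

## The problem

Short open reading frames (sORFs, conventionally ≤ 100 amino acids) are
reported by computational predictions, ribosome profiling (Ribo-seq) and
mass spectrometry, but the resulting catalogs are scattered, aligned to
different genome builds, inconsistently annotated and highly redundant: the
same ORF may appear in several sources with different coordinate systems,
missing strand or stop positions, or silently dropped splicing information.
`sorfkit` turns such catalogs into a single repository of **unique** ORFs,
each carrying its provenance (sources, detection methods, cell types), an
**experiment count** (how many original entries described it — a proxy for
evidence strength), transcript-relative coordinates, a normalized ORF class
(uORF, upstream-overlapping, CDS, CDS-internal-altframe, dORF,
downstream-overlapping, ncRNA-ORF, NMD-ORF, NSD-ORF, intergenic) and a
Kozak-context call.

## What it does

1. **Ingest + QC** — per-source column dialects map arbitrary delimited
   tables onto a common record model. For every entry the theoretical
   length `|start − stop| + 1 − Σ introns` is compared with the reported
   length; a source where > 95% of assessable entries disagree has lost its
   splicing information upstream and is rejected.
2. **Liftover** — every coordinate (start, stop, each splice-block bound)
   is remapped through a UCSC chain file by a native chain interpreter. An
   entry fails if any coordinate is unmapped, the remapped positions
   disagree on strand, the chromosome changes, or the start–stop distance
   changes; failed entries are dropped and tallied.
3. **Two-phase merge** — entries with the full identification feature set
   (chromosome, strand, start, stop, splicing status, splice coordinates)
   are grouped by exact key. Partially described leftovers providing the
   chromosome plus (strand+start | strand+stop | start+stop) are absorbed
   by the best matching unique ORF under a deterministic preference
   cascade; anything else is dropped. `Σ experiment_count + dropped` always
   equals the input record count.
4. **Annotation** — missing nucleotide/peptide sequences are extracted from
   the genome FASTA; transcripts are attached by ID or exon-compatible
   overlap from a local GTF; 1-based spliced-transcript coordinates, a
   class per ORF-to-transcript association, and a Kozak category
   (optimal / strong / moderate / weak / undefined, with a Kozak-alike flag
   for non-ATG starts) are computed. The classic dichotomy applies: a
   purine at −3 and a G at +4 of the start codon.
5. **Export** — CSV, block-aware BED12 and FASTA, plus a run summary with
   per-stage counters.
6. **Enrichment** — for a gene list of size *n* from a universe of *N*
   genes of which *K* harbor a uORF, with *k* list genes in the uORF set,
   the upper-tail hypergeometric probability
   P(X ≥ k) = Σᵢ C(K,i)·C(N−K,n−i)/C(N,n) and the sample odds ratio
   k(N−n−K+k)/((n−k)(K−k)) are reported with Benjamini–Hochberg FDR across
   lists (significance at FDR < 0.05).

A deterministic fixture module generates toy genomes, annotations, chain
files and redundant multi-source catalogs with a ground-truth manifest, so
every stage is testable without downloads.

## Worked example

```bash
sorfkit fixtures --seed 7 --out-dir demo     # toy genome + 3 source catalogs
sorfkit run-all demo/config.yaml             # config listing the 3 sources
```

with `demo/config.yaml`:

```yaml
species_tag: TOY
annotation: annotation.gtf
genome: genome.fa
cell_type_map: cell_types.csv
out_dir: run
sources:
  - {id: source1, path: source1.csv, chain: source1.chain}
  - {id: source2, path: source2.csv, chain: source2.chain}
  - {id: source3, path: source3.csv, chain: source3.chain}
```

prints (abridged):

```json
{
 "n_input_records": 20,
 "n_unique_orfs": 10,
 "experiment_count_total": 20,
 "n_dropped_source_qc": 0,
 "n_dropped_liftover": 0,
 "n_dropped_partial_merge": 0,
 "n_genes_with_sorf": 10,
 "n_orfs_with_class": 10,
 "n_short_orfs": 10
}
```

Twenty redundant source records collapse into ten unique ORFs, each seen by
two sources (`experiment_count_total` = 20), all classified and all ≤ 100
aa. The exported `run/orfs.bed` encodes splicing as BED12 blocks:

```
chr1	216	352	TOY000001	2	+	216	352	0	2	38,25	0,111
```

On the enrichment side, the library reproduces published uORF
over-representation statistics from their 2×2 marginals:

```python
from sorfkit.enrich import enrich_counts, enrich_many
res = [enrich_counts("ATF4 targets", k=256, N=19985, K=8863, n=392)]
enrich_many(res)
print(f"OR={res[0].odds_ratio:.2f} p={res[0].p_value:.3g} FDR={res[0].fdr:.3g}")
# OR=2.40 p=2.76e-17 FDR=5.52e-17
```

meaning ATF4-target genes are ~2.4× more likely to harbor a uORF than the
rest of the universe, far beyond chance.

## Layout

- `sorfkit.model` — record/key/unique-ORF data model and coordinate
  conventions (1-based inclusive, transcription orientation).
- `sorfkit.io` — catalog dialects, BED12, FASTA, CSV export.
- `sorfkit.qc` — theoretical-length QC, source rejection, gene recovery.
- `sorfkit.chainlift` — native UCSC chain interpreter and liftover.
- `sorfkit.dedup` — two-phase redundancy merge.
- `sorfkit.annotation` — GTF transcript models, relative coordinates,
  classification, Kozak contexts, cell-type normalization.
- `sorfkit.enrich` — hypergeometric over-representation, BH adjustment.
- `sorfkit.fixtures` — synthetic ground-truth generator.
- `sorfkit.pipeline` / `sorfkit.cli` — orchestration and the `sorfkit`
  command.

See `docs/methods.md` for the modelling choices and their rationale.
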