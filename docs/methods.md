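# Methods

## The procedure

`transannot` models annotation transfer from a well-annotated reference
species to a de novo assembled transcriptome of a close relative. Four
operations carry the science; everything else is bookkeeping.

**1. Contamination filtering of read pairs.** Poly(A)-selected libraries
carry genomic DNA fragments. Reads deriving from mature mRNA align to the
reference species' mRNA set essentially end-to-end; genomic fragments do
not. The filter therefore keeps a read only when the *alignment length*
of its single best mRNA hit lies in an inclusive window — by default
[100, 102] columns for 101-bp reads, allowing one inserted or deleted
column — and removes the mate of every removed read so downstream
paired-end assembly sees consistent files. Reads with no reported hit are
removed by default (`drop_unaligned`), since "no match to any mRNA" is
precisely the signature of genomic contamination; the flag exists because
one could argue for keeping novel, unrepresented transcripts.

**2. Full-length CDS calling.** A translated (six-frame) local alignment
of the contig against the ortholog proteome anchors a reading frame and a
strand. Local alignments rarely terminate exactly at the start codon, so
the aligned range is extended codon-by-codon: upstream to the nearest
in-frame ATG (failing with `no_start` if an in-frame stop or the contig
edge comes first), downstream to the first in-frame stop (`no_stop` if
the contig ends first). A candidate whose aligned region itself contains
a stop is structurally invalid (`internal_stop`; the built-in aligner
cannot produce one because frames are segmented at stops, but externally
computed hits can). The candidate is accepted iff the derived protein
matches its ortholog at ≥ 85% identity with a length difference ≤ 10
residues, both inclusive. Identity is recomputed from a protein-level
alignment of the derived protein (identical columns / aligned columns),
not taken from the anchoring nucleotide-level hit — the rule is about the
conceptual protein, not about the seed alignment. Rejection reasons have
fixed precedence (structural before threshold) so reports are
deterministic. One annotation per transcript (single best hit).

Extension to the nearest ATG is a deliberate reading: the alternative —
requiring the alignment itself to begin at ATG — is available via
`extend=False` but discards nearly every real hit. The nearest-ATG rule
can, in principle, pick an internal methionine when noise clips the
N-terminal end of the seed alignment; the length-difference threshold
then acts as the guard.

**3. Assembly statistics.** N50 uses the descending cumulative-sum
convention: sort lengths descending, accumulate, report the length at
which the running sum first reaches half the total. Ties need no special
rule under this definition. Mean lengths are kept at full precision
internally and rounded to integers only in reports.

**4. Annotation-set comparison.** Both annotation sets are aligned to a
common reference proteome, keeping one best subject per protein. Percent
similarity counts columns with a positive BLOSUM62 score. "Gaps" is
reported as total gap characters (the BLAST `gaps` column semantics);
gap *opens* are also written to the per-protein table since the term is
ambiguous in common usage. Proteins with no reference hit count toward
the set size but are excluded from means — scoring them zero would
distort the comparison of alignment quality. For single-isoform analysis,
when a set holds several proteins for one gene symbol the best-identity
row represents the gene; the single-isoform gene list is an input, not
computed. Missing-gene detection is plain set difference on gene symbols
of with-hit rows, deduplicated and sorted.

## Alignment engines

All three modes (nucleotide, translated, protein) are exact local
Smith–Waterman with affine gaps, backed by `Bio.Align.PairwiseAligner` —
no heuristic seeding, no E-values; ranking uses the raw score with
deterministic tie-breaking (higher identical count, then lexicographically
smallest subject id). Nucleotide mode searches both query strands, as a
nucleotide BLAST search would. Defaults are the familiar BLAST
parameters: match +2 / mismatch −3 / gap open −5 / extend −2 for
nucleotides, BLOSUM62 with open −11 / extend −1 for proteins, where a gap
run of length k costs open + k·extend. `N` never counts as an identity
and scores as a mismatch; translated frames are split at stop codons and
the segments aligned independently, so a hit never spans an in-frame
stop. For large runs, every consumer also accepts BLAST tabular
(outfmt 6) files, optionally extended with `positive`/`gaps` columns
declared via a `#columns:` header line.

The pipeline's read-filtering stage adds one engineering layer: a read is
aligned only against contigs sharing at least one exact 16-mer with
either read strand (the same idea as BLAST's word seeding). Reads seeding
nowhere are classed unaligned. Without errors in the simulated reads a
true mRNA read always shares its source's 16-mers, while a random
101-mer shares a given 16-mer with ~60 kb of reference with probability
≪ 1, so the prescreen does not change the filter's decisions — it makes
the stage's cost proportional to true matches rather than to the
all-vs-all product.

## The synthetic study

The generator emulates the shape of a paired-end mRNA-seq annotation
study at desk scale. Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 50 | enough genes for stable counts, minutes-scale runtime |
| `protein_len_range` | 100–500 aa | typical protein sizes |
| `utr5_range`, `utr3_range` | 20–100 / 20–150 nt | short but non-trivial UTRs |
| `read_length` | 101 nt | HiSeq-era paired-end read length |
| `fragment_len_mean/sd` | 300 / 30 nt | standard TruSeq insert size |
| `coverage` | 2× | desk-scale stand-in for deep sequencing |
| `frac_decoy` | 0.2 | sizeable non-coding fraction to measure false positives |
| `frac_truncated` | 0.1 | incomplete assemblies exist; split evenly no_start/no_stop |
| `frac_antisense` | 0.25 | strand handling must be exercised |
| `frac_contaminant_pairs` | 0.1 | genomic contamination worth filtering |
| `substitution_rate`, `indel_rate` | 0 | the cross-species divergence dial; 0 isolates the machinery |

Transcripts are built as 5'UTR + CDS + stop + 3'UTR, reverse-translating
the (optionally mutated) ortholog protein with uniform synonymous codon
choice — codon-usage bias is irrelevant to every tested property.
Mutations act at the amino-acid level and are then reverse-translated, so
a substitution rate r yields an expected protein identity of ≈ 1 − r
against the ortholog, making threshold behaviour interpretable; indels
insert or delete whole residues, preserving frame. The leading methionine
is never mutated (mutating it would silently change a transcript's truth
label). Truncations are constructed, not sampled: a `no_start` transcript
has its ATG removed and an in-frame stop planted at the UTR/CDS junction,
and a `no_stop` transcript gets an in-frame, stop-free 3'UTR — so the
truth labels are structural guarantees, not probabilistic ones.
Internal deletions in the degraded annotation set are placed away from
protein termini so that they force gap columns rather than end-trimming.
Read pairs are inner fragments (mate 2 reverse-complemented) at
round(coverage·len/(2·read_length)) pairs per transcript; contaminant
pairs come from an unrelated random sequence. Qualities are constant Q40
— the procedure never reads them.

All randomness flows from one seed through named substreams
(`SeedSequence(seed, spawn_key=crc32(name))`), so outputs are
byte-reproducible and generators do not perturb each other's streams.

What the simulation does *not* emulate — and hence what passing tests do
not show about real data: sequencing errors and quality decay, splice
isoforms, codon-usage and GC bias, paralogy (each protein has one true
ortholog), expression-level variation, and real assembler artifacts
(chimeras, collapsed repeats). The decoy model (uniform random sequence)
is far from real intergenic sequence; decoy rejection rates on real data
will be worse than the simulated 100%.

## Numerical and degenerate-input choices

- Coordinates are 1-based, fully closed, matching BLAST tabular output;
  translated hits report nucleotide coordinates on the input strand with
  q_start > q_end on negative frames.
- All scores are integer-valued, so score comparisons in tests are exact.
- Identity/gap statistics refer to one optimal alignment; when several
  co-optimal tracebacks exist the reported statistics are those of the
  engine's deterministic choice. Tests validate them against the full
  enumerated co-optimal set of an independent DP oracle.
- Empty inputs: empty subject sets and empty queries yield "no hit";
  empty contig sets make `contig_stats` raise (undefined); an empty
  protein set is an error in `compare_to_reference` but an empty
  single-isoform intersection is a valid empty result.
- Thresholds are inclusive at both boundaries (identity 85.0 and length
  difference 10 are accepted), verified at exactly constructed boundary
  cases.
- Per-protein TSVs are written at full float precision so means
  recomputed from the files agree to 1e-9.

## Known limitations

- Exact Smith–Waterman is quadratic; built-in engines are meant for
  desk-scale runs (tens of contigs × hundreds of orthologs). Large
  studies should supply external BLAST tabular files.
- No ab initio ORF calling: a transcript without an ortholog hit is never
  annotated, so genuinely novel genes are invisible by design.
- One annotation per transcript and one best reference hit per protein;
  multi-HSP and multi-subject evidence is not combined.
- E-values are not computed; score ranking replaces significance
  filtering, which is appropriate only because downstream rules use
  identity and length thresholds.
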