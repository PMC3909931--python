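# Methods

This note documents the models and procedures implemented in txstratkit,
the parameters that matter, the numerical conventions, and what the
synthetic fixtures do and do not emulate.

## Sequencing saturation

The analysis asks how the fraction of "adequately covered" contigs grows
with sequencing effort. Coverage is *nominal*: for contig $i$ with
$n_i$ aligned reads of fixed length $L_r$ and contig length $L_i$,
$C_i = n_i L_r / L_i$. No base-level depth track is computed; mates of a
pair are counted independently (one SAM record = one read). Secondary
(0x100) and supplementary (0x800) SAM records are excluded at read time
so each read contributes at most once.

Subsets of size $m$ are drawn uniformly **without replacement from the
full record pool** — aligned and unaligned records alike — because the
curve's x-axis is total sequencing effort, not aligned yield. Each
(subset size, replicate) pair gets its own stream seed derived
deterministically from the master seed (SHA-256 of `"{seed}:{purpose}"`,
truncated to 31 bits), so curves reproduce record-for-record.

Defaults: read length 40 nt, threshold 10X, 3 replicates per subset
size. The spread across replicates is reported as the sample standard
deviation ($n-1$ denominator; defined as exactly 0 when all replicate
values are identical, which includes the size-0 and full-subset points —
those are deterministic and are computed as such).

Two sampling paths exist. The record-level path subsamples actual
alignment records and is the reference behavior. The counts path draws
per-contig aligned counts directly from the multivariate hypergeometric
distribution — the exact distribution record-level sampling induces —
and is preferred at deep sequencing scale. The test suite asserts their
agreement in distribution, and checks the record path's mean against the
closed-form expectation $\frac{1}{N}\sum_i P(X_i \ge \lceil t L_i / L_r
\rceil)$ with $X_i \sim \mathrm{Hypergeom}(M, n_i, m)$.

## Phylostratigraphy

A `LineageModel` orders taxonomic database bins from the focal species'
closest relative outward and maps each to an ancestral-branch label. The
default model has seven in-lineage bins (confamilial sister species;
other cnidarians; Bilateria; basal Metazoa; other Eukaryota; Archaea;
Eubacteria) plus viruses out-of-lineage — the nested-search design used
for anthozoan transcriptome surveys.

Assignment is **deepest-hit-wins**: the most distant in-lineage bin with
at least one hit sets the origin. E-value filtering (default 1e-3)
happens when hit tables are read; this module sees only per-bin
presence/absence, so assignment is invariant to hit order and count.
Design choices made where the procedure was genuinely open:

* Virus hits are ignored whenever any in-lineage hit exists; virus-only
  contigs form their own `out_of_lineage_only` category rather than a
  stratum (viruses sit on no branch of the focal species' descent).
* Archaea and Eubacteria carry distinct ancestor labels by default;
  `default_model(merge_prokaryote_labels=True)` merges them into one
  cellular-ancestor class, the convention used when a survey reports a
  single deepest stratum.
* The contamination flag is true iff the deepest hit bin is in a
  configurable distal set (default: prokaryote bins + out-of-lineage)
  *and* no hit falls in any configurable intermediate bin (default: the
  eukaryote bins between the cnidarian and prokaryote bins). The flag is
  advisory: likely contaminants keep their deepest-hit origin, since
  hit-pattern evidence alone cannot prove non-focal origin.
* Stratum percentages use contigs assigned an in-lineage ancestor as the
  denominator; no-hit, out-of-lineage-only and flagged counts are
  reported alongside. This keeps per-branch percentages summing to 100.

A robust alternative — per-gene alignments and trees — is out of scope;
the binned-hit approach is a provisional stratigraphy by design.

## Ontology subtree coverage

The ontology is loaded from OBO 1.2 with **is_a edges only** by default
(a configurable relationship allow-list exists); obsolete terms are
retained but flagged and excluded from all traversals and tallies;
acyclicity and referential integrity are verified at load.

"Coverage of the sub-hierarchy under a term" admits two readings, and
both are implemented rather than silently resolved:

* `children` (default): the counting units are the start term's direct
  children; a unit is recovered for a species iff the unit or any term
  in its subtree carries a direct annotation. This matches coverage
  reports whose per-subcategory totals are small integers (child counts).
* `terms`: units are all terms strictly below the start term; a unit is
  recovered only if directly annotated.

Annotations to the start term itself belong to no child unit and count
nowhere. Multi-parent terms may be counted under several subcategories —
no cross-subcategory deduplication, since a term genuinely belongs to
each parent's subtree. Recovered counts are monotone under annotation
addition; the tests verify both modes against a brute-force transitive
closure of the adjacency list.

## Reciprocal gene-family recovery

Protocol: (1) each reference protein queries the transcriptome in
protein-vs-translated mode; hits scoring at least `min_score` are kept,
at most `top_k` (default 10) per query; (2) each candidate transcript is
searched, translated, against the *full* reference protein set; the
candidate is verified iff its reciprocal top hit — ties broken by score,
then lexicographic subject id — is the original query. A relaxed mode
accepts any member of the same declared family.

The search step is a contract (`SearchBackend`) so external translated
search tools can be plugged in. The built-in backend translates all six
frames (standard code; ambiguity codes become X; stops stay inline as
`*`) and scores a transcript as the maximum affine-gap Smith–Waterman
score over its frames. Scoring conventions:

* BLOSUM62, gap open 11, extend 1 — a gap of length $k$ costs
  $11 + k$ — the familiar protein-search defaults.
* Stop symbols are reassigned the matrix minimum against everything
  (including `*`/`*`), so read-through matches across stop codons cannot
  win a frame.
* E-values are not computed: only ranking matters to the reciprocal
  criterion, and raw scores rank identically.
* `min_score` (default 50) is a free parameter. 50 raw score suppresses
  chance matches between unrelated ~100-residue random sequences (whose
  local scores fall well below it) while retaining genuine homologs,
  which score in the hundreds at ≥60% identity.

The underlying `local_align` is checked against exhaustive enumeration —
best global affine score over every substring pair, floored at 0 — on
short peptides.

## EC-number pathway comparison

EC labels are normalized (optional `EC:` prefix stripped, padded to four
dotted fields with `-`), then the two species' sets are partitioned
exactly into shared / focal-only / reference-only; `n_matched` (shared +
focal-only) is the focal species' enzyme count. Partial ECs are compared
as exact strings — no hierarchical matching of `1.2.3.-` to its
children — because no principled completion rule exists without a target
enzyme database; the normalization makes the choice explicit. The iPath
selection dialect is `<EC> <#RRGGBB> W<width>` with shared→green
(#00ff00), focal-only→yellow (#ffff00), reference-only→red (#ff0000),
width 10; ECs absent from both sets are omitted and render in the
viewer's default gray/black.

## Assembly statistics

N50 uses the ≥ convention: sort descending, accumulate, return the
length at which the running sum first reaches half the total (a sum
exactly equal to total/2 counts). Histogram and hit-rate bins are
closed-open $[l, u)$ except the last bin, which is closed — stated so
counts are bit-reproducible. When every contig has a hit, the no-hit
focus fraction is reported as absent (None), not zero.

## Synthetic fixtures

All generators are seed-deterministic (byte-identical regeneration) and
feed every stage with recorded truth:

* **Transcriptome**: i.i.d.-uniform nucleotide contigs; a stated
  fraction carry an embedded ORF (ATG, ≥30 codons, stop) at recorded
  coordinates. Lengths are uniform on the configured range.
* **Reads**: aligned records land on contigs with probability
  proportional to contig length (uniform expression); a stated fraction
  is unaligned. True counts sum exactly to the rounded aligned total.
* **Hit tables**: each gene draws a birth stratum; hits appear in its
  deepest bin and every closer bin (a consistent nested pattern), so
  deepest-hit assignment recovers truth exactly at contamination 0.
  Contaminants instead receive hits only in distal bins. The default
  stratum mix places 60% of contigs in the no-hit class and, among
  hit-producing genes, ~19.2% at the bacterial/eukaryote split, ~10.8%
  at the metazoan ancestor, ~2.2% at the cnidarian ancestor and ~16%
  confamilial-only — the shape of published anthozoan surveys.
* **Ontologies**: random DAGs, edges only from later to earlier terms
  (acyclic by construction), 1..max_parents parents per term.
* **Families**: orthologs are point-substituted to the stated protein
  identity, reverse-translated through uniformly random synonymous
  codons, and embedded at random offset/strand among random flanks;
  decoys are unrelated random contigs.

What the fixtures deliberately do **not** emulate: sequencing error and
quality strings, paired-end structure, expression heterogeneity,
paralogy and gene families with real phylogenetic structure, biased
database composition, or compositional (GC) structure. Consequences to
keep in mind: because simulated expression is uniform, per-contig
coverage is tightly clustered and the demo saturation curve switches
from 0 to 1 over a narrow depth window — real curves rise gradually.
Passing tests therefore demonstrate correctness of the algorithms under
their stated models, not robustness to every artifact of real libraries.

The demo preset (150 contigs of 150–1,500 nt; 100,000 40-nt reads, 15%
unaligned, giving ~27X full-depth nominal coverage; 5% contamination;
120-term ontology; 3 planted families at 80% identity among 10 decoys)
is sized so a full end-to-end run completes in seconds while exhibiting
the saturated regime the coverage analysis exists to detect.

## Problem sizes used by the test suite and acceptance script

Saturation is verified on a 20-contig pool (~1,200 records) with 1,000
replicates; phylostratigraphic recovery on 1,000 genes; ontology
coverage on 50 (tests) / 20 (script) random 100-term DAGs; N50 on 1,000
random length lists; family recovery on 5 families at 80% identity with
20 decoys; EC partition conservation on 1,000 random set pairs. These
sizes give Monte-Carlo standard errors small enough for 3-SE assertions
while keeping a full run fast on a single CPU.

## Known limitations

* SAM support is deliberately minimal (QNAME/FLAG/RNAME; no BAM/CRAM,
  CIGAR or positions) — sufficient for count-based coverage, nothing else.
* Variable-length reads are not supported; `read_length` is global.
* The built-in search backend is quadratic-time alignment over six
  frames: appropriate for gene-family panels, not for transcriptome-wide
  all-vs-all search (plug an external backend behind `SearchBackend` for
  that).
* Contamination flagging is a hit-pattern heuristic; it cannot detect
  contaminants whose hosts are close relatives, and its distal /
  intermediate bin sets must be chosen per lineage model.
* GO annotation handling ignores evidence codes and does not propagate
  annotations to ancestors (this is coverage accounting, not enrichment).
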