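# txstratkit

An annotation toolkit for de novo transcriptomes of non-model organisms —
assemblies with no reference genome, annotated purely by homology search.
It answers the questions such a project faces once the contigs exist:

* **Did I sequence enough?** — a saturation curve from seeded random
  subsampling of read-to-contig alignments;
* **How old are my genes?** — phylostratigraphic origin assignment from
  taxonomically binned homology hits, with a contamination heuristic;
* **How much functional space is covered?** — Gene Ontology subtree
  coverage per top-level subcategory, comparable between two species;
* **Are the expected gene families present?** — reciprocal-search
  recovery of reference gene families with a built-in translated-search
  backend (six-frame translation + Smith–Waterman);
* **Which metabolic enzymes are shared?** — EC-number set comparison with
  iPath selection export;
* plus assembly summary statistics (N50, length histograms,
  hit-rate-by-length tables).

A seeded synthetic-fixture generator produces contigs, SAM alignments,
taxon-binned hit tables, OBO ontologies and planted ortholog families with
recorded ground truth, so the entire toolkit runs and is tested offline.

## The statistics at the core

**Nominal coverage.** For a contig of length $L_c$ with $n$ aligned reads
of fixed length $L_r$, the nominal fold-coverage is
$C = n L_r / L_c$. The saturation analysis subsamples $m$ reads without
replacement from the full pool of $M$ sequencing records (aligned and
unaligned), recomputes $C$ per contig, and reports the fraction of
contigs with $C \ge t$ (default $t = 10$), three replicates per subset
size. Under uniform subsampling the per-contig aligned count is
hypergeometric, $X_i \sim \mathrm{Hypergeom}(M, n_i, m)$, which the test
suite uses as an independent expectation oracle and which powers an
equivalent fast sampling path.

**Phylostratigraphy.** Database bins are ordered from the focal species'
closest relative outward; a contig's origin is the ancestral branch of
its *deepest* hit bin (a single distal hit wins). Contigs whose hits are
confined to distal bins (prokaryotes, viruses) with none in intermediate
eukaryote bins are flagged as likely contaminants; the flag is advisory
and never changes the assignment.

**Reciprocal family recovery.** Each reference protein queries the
transcriptome in translated mode; the top $k$ (default 10) candidates are
searched back against the full reference set, and a candidate is verified
iff its reciprocal best hit is the original query.

**N50.** The largest $\ell$ such that contigs of length $\ge \ell$ hold at
least half the assembly.

## Worked example

```bash
txstratkit fixtures --preset demo --seed 42 --out demo/
txstratkit stats --fasta demo/contigs.fa --out out/stats
txstratkit saturate --sam demo/reads.sam --fasta demo/contigs.fa \
    --sizes 0,25000,50000,100000 --seed 17 --out out/sat
txstratkit phylostrat --model demo/model.tsv --fasta demo/contigs.fa \
    --hits N_vectensis=demo/hits/N_vectensis.tsv \
    --hits Bilateria=demo/hits/Bilateria.tsv ... --out out/ps
txstratkit ecdiff --focal demo/ec_focal.tsv --reference demo/ec_reference.tsv \
    --out out/ec
```

`out/stats/stats.tsv` (the demo assembly: 150 contigs, 126,071 nt total,
N50 of 1,090 bp):

```
metric  value
n_contigs       150
total_length    126071
n50     1090
```

`out/sat/saturation.tsv` — the fraction of contigs at ≥10X rises from 0
at 25,000 reads to 1.0 by 50,000 reads and stays saturated at full depth
(the demo's synthetic reads are length-proportional, so the transition is
sharp; see `docs/methods.md`):

```
n_reads mean_fraction_covered   sd_fraction_covered
0       0.0     0.0
25000   0.0     0.0
50000   1.0     0.0
100000  1.0     0.0
```

`out/ps/strata.tsv` — per-branch counts and percentages of the 64 contigs
assigned an in-lineage origin (86 of the 150 demo contigs produce no hit;
9 are contamination-flagged):

```
stratum count   percent_of_assigned
Edwardsiidae ancestor   8       12.5000
Eumetazoa ancestor      19      29.6875
ancestor of Eubacteria + Eukaryota      14      21.8750
...
no_hit  86
contamination_flagged   9
```

`out/ec/ec_counts.tsv` — of 30 EC numbers matched in the focal species,
13 are shared with the reference species and 17 are focal-exclusive;
`ipath_selection.txt` colors them green/yellow/red for iPath:

```
n_matched       30
n_shared        13
n_only_focal    17
n_only_reference        12
```

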