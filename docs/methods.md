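# Methods

This note documents the models and procedures implemented in
`cyanophot`, the parameters that matter, the scope of the synthetic-data
generator, and the numerical and design choices made where the problem
left them open.

## Translated homology screen

The screen is an exact-DP replacement for a seeded translated search
(TBLASTN-style). Each contig is translated in all six frames under the
bacterial genetic code (table 11); maximal stop-to-stop runs of at least
`min_orf_aa = 60` residues are taken as ORFs, with contig ends treated
as open (no stop required). Every ORF is aligned against every panel
protein by Smith–Waterman local alignment with affine gap penalties
under BLOSUM62. The reference protein is the query: identity and
coverage are measured on the reference, as when a bait protein drives
the search.

Acceptance thresholds (all configurable, echoed to the log):

| knob | default | meaning |
|---|---|---|
| `min_identity` | 0.30 | matches / alignment columns (gaps count as columns) |
| `min_query_cov` | 0.50 | aligned fraction of the reference |
| `min_score` | 60 | raw BLOSUM62 score; first gap residue costs 11, each further 1 |
| `min_orf_aa` | 60 | ORF length floor |

This triple is a conventional remote-homology working point. **E-values
are not computed**: a single MAG defines no meaningful database size, so
fixed score/identity/coverage thresholds substitute. Overlapping hits to
the same gene family are dereplicated keeping the best score. For
efficiency the full alignment is only constructed for pairs whose
score-only pass already clears `min_score`; this is a pure reordering of
the same exact computation, not a heuristic.

Among co-optimal alignments the aligner's first deterministic traceback
is reported. This is stable across runs and platforms; scores, identity
and coverage are invariant across co-optimal choices. Unknown residues
score through the substitution matrix's X column.

## Rhodopsin classification

Rhodopsins have many functions (proton, chloride and sodium pumping,
light sensing), so a hit alone does not establish phototrophy. Three
lines of evidence are combined.

**Subtree assignment.** Instead of maximum-likelihood tree inference,
each hit is assigned the label of its nearest reference (best global
alignment score) among labeled references spanning the three
proteorhodopsin/xanthorhodopsin subtrees (I: Bacteroidota-type
proteorhodopsins, II: proteorhodopsins including the *E. sibiricum*
branch, III: xanthorhodopsins). The margin between best and second-best
labels below 5% of the best score raises a low-confidence flag, which
guards against chimeric or ambiguous sequences. Nearest-reference is
deterministic and directly testable; a tree would add bootstrap and
model choices without changing the three-way decision.

**Diagnostic residues.** Residue numbering is *anchor-relative*: the hit
is globally aligned to the anchor sequence of its assigned subtree and
positions 85/89/96/156/292 are read off the anchor columns (anchor
columns aligned to gaps yield nulls, and a null never satisfies a
motif). The shipped anchors place the canonical D/T/E triad, G-156 and
K-292 exactly at these positions; users substituting their own anchors
can reconfigure `rhodopsin.positions` accordingly. An anchor alignment
with identity below 0.15 is rejected as unreliable rather than silently
profiled.

**Operon context.** Neighbors are features on the same contig within
5000 bp of the hit, any strand. The window is deliberately generous:
operon structures are drawn as synteny plots in the field but "adjacent"
is rarely defined; 5 kb spans a typical rhodopsin operon (rhodopsin +
up to four *crt* genes + *brp/blh*) with margin. The *brp/blh*
β-carotene 15,15′-dioxygenase releases retinal and is required for a
functional pump, but it need not be adjacent — the genome-wide presence
clause decides the functional call, adjacency is recorded separately.

**Functional call**, in priority order:

1. N‑85/D‑89/Q‑96 → `na_pump_excluded` (the established Na-pump motif;
   reported but not counted as phototrophy),
2. no K‑292 → `divergent_unknown` (no retinal Schiff base, function
   unclear),
3. subtree assigned and *brp/blh* anywhere in the genome →
   `bona_fide_pump` — a divergent position 96 alone does not
   disqualify, because characterized subtree-II pumps lack E‑96,
4. otherwise `candidate_pump`.

A carotenoid antenna is predicted when G‑156 is present and the subtree
is I or III; the prediction is residue-based and independent of the
functional call.

## PGC inventory and synteny

A MAG's PGC inventory is the set of screen hits to the reference
cluster's gene families, ordered along the genome. Completeness is the
fraction of reference genes found. A MAG *has a PGC* when `pufL` and
`pufM` are both present and completeness ≥ 0.5; the cluster is
contiguous when all genes lie on one contig within 80 kb (roughly twice
the canonical ~45 kb cluster, leaving room for insertions). "Complete
PGC" has no standard numeric definition, so all three knobs are
configuration with the defaults above.

Rearrangement between two clusters is measured as **signed adjacency
breakpoints**: orders are restricted to shared genes, each neighboring
pair (x, y) is taken with strand and considered equal to (−y, −x), and
the breakpoints are the adjacencies of one order absent from the other.
This statistic is symmetric, zero exactly for identical signed orders,
invariant under reverse-complementing a whole cluster, and counts a
single internal block inversion as 2. Heavier rearrangement distances
(block-interchange, DCJ) were deliberately avoided as over-specified for
a per-figure synteny summary. The shipped reference gene order is a
curated canonical Rhodobacterales-style cluster layout keyed to
*D. shibae* DFL 12 symbols (a synthetic stand-in; substitute your own
ordered reference to reproduce a specific published numbering).

## Phototrophy calls and Venn counts

Per MAG: hosts (flagged in the manifest, never inferred from taxonomy)
are `cyano_oxygenic`; a non-host with a PGC and either a bona fide pump
or a subtree-III rhodopsin with adjacent *brp/blh* (`xr_operon`) is
`dual`; PGC alone `pgc_only`; pump alone `rhodopsin_only`; else `none`.
Because "rhodopsin-positive" is ambiguous between the broad and strict
readings, the summary reports both tallies: `rhodopsin_total` counts
MAGs with at least one bona fide *or* candidate pump, and
`rhodopsin_bona_fide` only the former.

## Community metrics

Coverage arrives as a mapped-bases table (read mapping itself is
upstream plumbing): coverage = mapped bases / genome size, and relative
abundance = 100 × coverage / host coverage within the same metagenome.
The host is 100% by construction, and abundances are invariant under
rescaling all mapped-base counts of a metagenome. QC thresholds are
read strictly (> 80% completeness, < 10% contamination), so boundary
values are removed; relax to ≥/≤ via the configuration if desired.
Taxon assignment is an external input (six-rank, semicolon-separated
lineages); commonality counts a taxon once per metagenome, and
presence–absence matrices are exported per rank for external ordination
rather than embedding them here.

## Synthetic data generator

The generator emulates the *structure* of a per-culture MAG set: one
GC-rich host genome (GC 0.69) plus associated genomes at GC 0.40–0.62,
with log-normal coverages (σ = 1.0, median 20×) and the host at a 5×
multiple. Planted features are reverse-translated with uniform
synonymous codons, inserted in frame between stop codons, and spaced at
least 1 kb apart; each planted feature gets its own contig so
"elsewhere in the genome" variants are genuinely non-adjacent. The
default feature mix covers every variant class the classifier
distinguishes: complete / rearranged / partial / puf-less / split PGCs,
PR and XR operons, E96Q and K292A variants, an NDQ Na-pump decoy, a
pump with no retinal gene, and a solitary rhodopsin with *brp/blh* on
another contig. The truth manifest records each feature's location and
the subtree, functional call and per-MAG mode a correct pipeline must
produce; expected calls are derived from the override table, not from
running the pipeline.

Problem sizes are scaled to desk scale as the package's own default:
14 metagenomes with 3–6 MAGs each and genome backgrounds of 9–15 kb
(against Mb-scale real MAGs and 3–40 bins per culture). Since every
ORF is aligned against every panel protein by exact DP, runtime grows
linearly in background size and the scaled defaults keep a full
collection analysis around a minute; all sizes are configurable upward.

What the generator does **not** model: sequencing reads and errors,
assembly and binning artifacts, codon-usage bias, paralogous gene
families, mobile elements, or realistic protein families (background is
i.i.d. nucleotide sequence; reference proteins are deterministic
synthetic sequences). Passing the planted-recovery suite therefore
demonstrates the pipeline's internal correctness — coordinates, strand
handling, residue mapping, rule logic, bookkeeping — not the
sensitivity/specificity of the thresholds on real genomes, which depend
on real homolog divergence.

Nested-mutation series (`mutation_series`) couple mutants across rates:
positions mutated at a lower rate stay mutated at higher rates, so
per-replicate divergence is monotone and recall-vs-rate curves are free
of resampling noise.

## Degenerate inputs and edge behavior

Empty FASTA files parse to empty collections with a warning; empty MAGs
screen to empty hit lists. A metagenome whose host is missing from the
coverage table is skipped by the metrics stage with a warning rather
than failing the run. Synteny comparison of clusters sharing no genes
reports null breakpoints instead of zero. Duplicate MAG ids, malformed
lineages, missing QC rows, strandless GFF rows and out-of-range
coordinates all fail loudly with the offending identifier.

## Known limitations

- The shipped reference panel and anchors are synthetic stand-ins;
  results on real MAGs require user-supplied reference FASTA panels.
- ORF-based search misses genes interrupted by frameshifts or assembly
  gaps, and exact DP without seeding is not intended for Mb-scale
  genomes against large panels.
- Nearest-reference subtree assignment cannot discover new subtrees; a
  hit outside the three references' neighborhoods is still forced into
  the nearest label (the low-confidence flag is the only guard).
- The carotenoid-antenna prediction is a single-residue heuristic.
- Dual-phototrophy calls inherit any binning contamination present in
  the input MAGs; the QC filter mitigates but cannot exclude this.
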