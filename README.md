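# cyanophot

Phototrophy annotation for metagenome-assembled genomes (MAGs) from
non-axenic cyanobacterial cultures.

Cyanobacteria kept in culture collections carry a stable community of
associated heterotrophic bacteria — the *cyanosphere*. Many of these
housemates are photoheterotrophs of two kinds: aerobic anoxygenic
phototrophs encoding a ~45 kb **photosynthesis gene cluster** (PGC,
with bacteriochlorophyll *bch*, carotenoid *crt*, reaction-center
*puf*/*puh* genes and cytochrome *c*₂), and bacteria using
**proton-pumping rhodopsins** (proteorhodopsin/xanthorhodopsin). A
single organism carrying both systems is a **dual phototroph**.
`cyanophot` finds and classifies this evidence in a MAG collection and
summarizes it per culture.

## What it computes

Given per-MAG nucleotide FASTA, a manifest, and optional QC / coverage /
taxonomy tables, the pipeline runs:

1. **QC filter** — keep MAGs with completeness > 80% and contamination
   < 10% (strict inequalities).
2. **Translated homology screen** — six-frame translation, stop-to-stop
   ORF calling (≥ 60 aa, bacterial code), exact Smith–Waterman alignment
   of every ORF against a reference protein panel (BLOSUM62, affine gaps
   11/1). A reference *r* hits an ORF when identity ≥ 0.30, reference
   coverage ≥ 0.50 and score ≥ 60.
3. **Rhodopsin classification** — nearest-reference assignment to one of
   three proteorhodopsin/xanthorhodopsin subtrees; diagnostic residues
   read off an anchor-relative numbering (D‑85/T‑89/E‑96 proton-transfer
   triad, G‑156 carotenoid-antenna site, retinal-binding K‑292); operon
   context within a 5 kb window (*brp/blh* retinal gene, *crtE/B/I/Y*).
   Calls: `na_pump_excluded` (NDQ triad), `divergent_unknown` (no
   K‑292), `bona_fide_pump` (subtree assigned and *brp/blh* in the
   genome — E‑96 divergence alone does not disqualify),
   else `candidate_pump`.
4. **PGC inventory** — gene census numbered against a reference cluster
   ordering, completeness, contiguity, and synteny comparison between
   clusters as **signed adjacency breakpoints** (an adjacency of two
   genes, taken with strand, present in one cluster but not the other).
5. **Phototrophy calls** — one mode per MAG
   (`cyano_oxygenic`/`pgc_only`/`rhodopsin_only`/`dual`/`none`) and the
   collection-level Venn counts.
6. **Community metrics** — host-calibrated relative abundance
   (coverage as a percentage of the cyanobacterial host's coverage, host
   ≡ 100%), commonality (number of metagenomes containing a taxon), and
   rank-wise presence–absence matrices for external ordination.

A fully deterministic synthetic-data generator plants PGCs (complete,
rearranged, partial, split), rhodopsin operons and residue variants with
a recorded truth manifest, so the whole pipeline is testable offline.
The shipped reference panel consists of deterministic *synthetic*
stand-in proteins; point `--panel` at your own protein FASTA
(`>accession|gene_label`) to screen against real references.

## Worked example

```python
from cyanophot import generate_collection, analyze_collection

coll = generate_collection(rng_seed=1)          # 14 synthetic metagenomes
bundle = analyze_collection(coll.mags,
                            coverage=coll.coverage,
                            taxonomy=coll.taxonomy)
print(bundle.venn)
```

```
{'total_mags': 65, 'cyano': 14, 'pgc_total': 5, 'rhodopsin_total': 6,
 'rhodopsin_bona_fide': 5, 'dual': 1, 'none': 42}
```

Of 65 MAGs, 14 are cyanobacterial hosts (oxygenic photosynthesis), 5
associated MAGs carry a PGC, 6 carry a pump-type rhodopsin (5 of them
bona fide proton pumps), and 1 MAG carries both — a dual phototroph.
The per-hit classification table shows why:

```
   mag_id subtree res85 res89 res96 res156 resK              call
A1-C01-02     III     D     T     E      G    K    bona_fide_pump   # dual MAG
A1-C08-02      II     D     T     Q      G    K    bona_fide_pump   # E96Q still pumps
A1-C09-02       I     D     T     E      G    A divergent_unknown   # K292A: no retinal K
A1-C10-02      II     N     D     Q      G    K  na_pump_excluded   # NDQ Na-pump
A1-C11-02       I     D     T     E      G    K    candidate_pump   # no brp/blh anywhere
```

The same run is available from the shell:

```bash
cyanophot demo --out demo_run --seed 1
```

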