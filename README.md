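# endofish

Tools for studying bacterial endosymbionts inside fungal hyphae with
fluorescence in situ hybridization (FISH): **design of taxon-specific
rRNA probes** and **quantification of endohyphal bacterial density from
multi-channel micrographs**. The intended users are microbiologists
working on bacterial–fungal interactions (e.g. *Mycoavidus* inside
Mortierellaceae) who need specific 16S/18S probes from their own
assemblies and reproducible, scriptable counting of labelled bacteria
within mycelia.

## What it computes

**Probe design.** From a target rRNA sequence, the host rRNA and the
remaining assembled contigs, every possible 25-mer of the target is
screened sequentially:

1. uniqueness — the 25-mer occurs exactly once among targets and never
   in any other sequence (both strands of non-target sequences);
2. melting temperature — Wallace rule 2·(#A+#T) + 4·(#G+#C) inside
   [37, 90] °C (nearest-neighbor estimator available);
3. indel robustness — the Levenshtein distance between the 25-mer's
   last 18 nt and every non-self 18-nt window of the input set must be
   **> 6** (windows overlapping the candidate's own suffix are "self");
4. probe assembly — the probe is the reverse complement of the site;
5. structure — no self-complementary 4-mer pair at distinct positions
   and no G-quadruplex motif (4 × G≥3 with 1–7-nt loops).

**Image quantification.** For sets of confocal stacks with a bacterial
(16S) and a host (18S) channel: maximum-intensity Z projection; min–max
normalization per channel across the whole set; adaptive local-mean
threshold mask of the mycelium (block 5.1 µm, margin 0.15 above local
mean, small objects removed, holes filled); difference-of-Gaussian blob
detection of bacteria (σ = 0.1–0.4 µm, 5 scales, scale-normalized strict
local maxima above 0.15, overlap-pruned); counting of blobs whose center
falls in the mask; density as cells per 100 µm² of mycelium; transect
counts along ordered ROIs; and Welch's unequal-variance t-test between
conditions. See `docs/methods.md` for every parameter, default and
rationale.

Both pipelines are backed by seeded synthetic generators
(`endofish simulate …`) producing sequence sets with planted compliant
probe sites and two-channel micrographs of tubular hyphae with planted
Gaussian bacteria — each with machine-readable ground truth, so the whole
package is testable without external data.

## Worked example

```
$ endofish simulate sequences --seed 0 -o seqs
wrote fixture with 1 planted region(s)

$ endofish design --target seqs/target.fasta --host seqs/host.fasta \
      --background seqs/background.fasta -o probes
1 accepted / 476 k-mers; stages {'kmerize': 476, 'unique': 2, 'tm': 2,
'levenshtein': 1, 'structure': 1}
```

The seed-0 fixture plants one fully compliant unique 25-mer plus one
decoy whose mutated suffix copy sits in the host. Of 476 target 25-mers,
2 survive uniqueness (the planted site and the decoy), both pass the Tm
window, the decoy dies at the Levenshtein screen (its minimum suffix
distance is 3 ≤ 6) and the planted site alone is accepted.
`probes/probes.tsv` holds one row per candidate with all metrics; the
accepted row reads

```
probe_target_16S_361  target_16S  361  -  CCTGTAACAAGCCGTATAGTTTGCC \
    GGCAAACTATACGGCTTGTTACAGG  74.0  7.0  ...  True
```

i.e. the probe `GGCAAACTATACGGCTTGTTACAGG` (reverse complement of the
site at position 361), Wallace Tm 74 °C, minimum suffix edit distance 7.

```
$ endofish simulate image --seed 0 -o img
wrote image with 25 inside / 5 outside spots

$ endofish quantify img/image.tif --ch-16s 0 --ch-18s 1 \
      --pixel-size-um 0.1 -o quant
image: count=25 area_um2=112.7 density_per_100um2=22.175
```

All 25 planted intramycelial bacteria are recovered, the 5 spots outside
the hypha are excluded by the mask, and the density — 25 cells over
112.7 µm² of mycelium — is 22.2 cells / 100 µm². `quant/` additionally
contains the per-blob table, the mask TIFF and a run manifest. Density
CSVs from several conditions can be compared with
`endofish compare pd.csv r2a.csv -o compare.csv` (pairwise Welch tests).

## Layout

```
src/endofish/
  sequences.py   sequence records, reverse complement, k-mer windows
  design.py      probe design screens and pipeline
  imaging.py     projection, masking, DoG detection, densities, Welch test
  synthetic.py   seeded fixture generators with ground truth
  io.py          FASTA/TIFF/CSV/YAML, manifests, atomic writes
  cli.py         `endofish` command-line interface
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  models, parameters, fixture design, limitations
```
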