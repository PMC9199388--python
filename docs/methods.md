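# Methods

`endofish` bundles two computational methods used in studies of bacterial
endosymbionts living inside fungal hyphae (e.g. *Mycoavidus* within
Mortierellaceae): design of taxon-specific FISH oligonucleotide probes from
rRNA sequences, and quantification of bacterial density inside mycelia from
multi-channel fluorescence micrographs. This note records the models,
parameter choices and their rationale, what the synthetic fixtures do and
do not emulate, and known limitations.

## Probe design

### Model

A probe is the reverse complement of a 25-nt target site on the
endosymbiont's 16S rRNA (or any designated target sequence). A site is
accepted when it survives five sequential screens:

1. **k-merization.** Every 25-mer of every target record is a candidate.
   k-mers containing `N` are excluded: assembly gaps must not generate
   probes. Coordinates are 0-based half-open internally; FASTA headers of
   accepted probes report 1-based inclusive coordinates for readability.
2. **Uniqueness.** The k-mer must occur exactly once in the union of
   target sequences and never in the host rRNA or any background contig.
   Because background contigs are double-stranded DNA while the probe
   targets single-stranded rRNA, the reverse complement of every
   non-target sequence is screened as well (`screen_revcomp_background`,
   default on).
3. **Melting temperature.** The site's Tm must fall in
   `[tm_low, tm_high]` = [37, 90] °C by default. 37 °C is a typical
   hybridization temperature; the upper bound excludes GC-saturated sites.
   The default estimator is the Wallace rule, 2·(#A+#T) + 4·(#G+#C),
   which is exact and integer-valued for short oligos; a nearest-neighbor
   estimator (unified SantaLucia parameter set, 1 M Na+, 25/12.5 nM
   strands, constants in `design.py`) is available via
   `tm_method="nearest_neighbor"`.
4. **Indel robustness (suffix Levenshtein screen).** The last 18 nt of the
   site must be at edit distance **strictly greater than 6** from every
   *non-self* 18-nt window of the input set. "Non-self" excludes every
   window that overlaps the candidate's own suffix occurrence in its
   source sequence: a window shifted by *s* bases from the suffix itself
   is trivially at distance ≤ 2·s, so without overlap exclusion the screen
   would reject every candidate and be vacuous. The comparison set spans
   all input sequences by default (`lev_scope="all"`); a
   `target_only` mode restricts it to target records. When no non-self
   window exists the screen passes vacuously and the distance is reported
   as `+inf`.
5. **Structure.** On the assembled probe: (a) no self-complementary 4-mer
   pair — a 4-mer and its reverse complement at two *distinct* positions;
   a single palindromic occurrence does not count, since intramolecular
   pairing needs two physically distinct segments (and published accepted
   probes begin with the palindrome `ACGT`); (b) no canonical
   G-quadruplex motif, four runs of ≥ 3 G separated by loops of 1–7
   arbitrary bases.

Candidates that fail a stage do not advance; metrics of later stages stay
unset for them. Stage survivor counts are recorded and are monotonically
non-increasing. Candidates are ordered by (source id, position); no
ranking score is imposed. The pipeline is fully deterministic.

Edit distances are computed with edlib, using a k-bounded band equal to
the running minimum during the window scan so hopeless alignments abandon
early; the distance reported is nevertheless the exact minimum. Tests
validate against a textbook recursion, and the acceptance script
recomputes the headline quantity with its own vectorized Wagner–Fischer
dynamic program.

### What is deliberately out of scope

No alignment/BLAST off-target search (exact and edit-distance screens
only), no fluorophore assignment, no amplification-hairpin design.

## Image quantification

### Pipeline

For a set of multi-channel confocal stacks (channels: 16S = bacteria,
18S = host mycelium, optional nuclei):

1. **Maximum-intensity Z projection** per channel.
2. **Min–max normalization per channel across the whole image set** — a
   single linear map taking the set's global minimum to 0 and maximum
   to 1. Set-level (not per-image) scaling keeps intensities comparable
   across culture conditions.
3. **Mycelial mask** from the 18S projection: pixel is foreground iff its
   intensity exceeds the local mean over a `block_size` window minus
   `offset`. Defaults: block 5.1 µm (51 px at 0.1 µm/px) — comfortably
   wider than a 2 µm hypha, so tube interiors are not hollowed out — and
   offset −0.15 in normalized units, i.e. a pixel must exceed its local
   mean by 0.15. The sign matters: for bright-on-dark images the margin
   must exceed a few standard deviations of the background noise
   (≈ 0.06–0.12 after normalization at a spot SNR of 5) or roughly half
   of all background pixels would be marked foreground. Components
   smaller than `min_object_px` (64 px ≈ 0.64 µm²) are removed with
   8-connectivity, and enclosed holes are filled: at SNR 5 about 10 % of
   in-tube pixels dip below the local threshold, and unfilled pinholes
   would drop detections under the rounded-center mask rule.
4. **Difference-of-Gaussian blob detection** on the 16S projection.
   Gaussian blurs at `n_scales` = 5 geometrically spaced sigmas from 1 to
   4 px (0.1–0.4 µm, matching 0.5–1 µm bacteria at 0.1 µm/px); adjacent
   differences divided by (ratio − 1) approximate the scale-normalized
   Laplacian. Detections are *strict* local maxima over the 3×3×3
   (y, x, scale) neighborhood above `response_threshold`, then greedily
   pruned so no two retained discs (radius √2·σ) overlap by more than
   `overlap` = 0.5 of the smaller disc. The response threshold default
   0.15 was set by characterizing the detector at its design operating
   point (unit-amplitude spots over σ = 0.2 noise, i.e. SNR 5, after set
   normalization): pure-noise responses cap at ≈ 0.14 while the weakest
   true spot responds at ≈ 0.19, so 0.15 separates the two populations.
   At thresholds near the noise floor (≤ 0.05) the smallest scale floods
   with thousands of noise maxima.
5. **Masking and density.** A blob counts as intramycelial iff its
   integer-rounded center pixel lies in the mask (simple and exactly
   testable). Density = count / (masked area / 100 µm²). Zero-area masks
   yield an undefined density (an error at the operation level; a flagged
   `NA` row in batch mode).
6. **Transects.** Counts per ordered, pairwise-disjoint, half-open
   rectangular ROIs — used to profile density along a hyphal bundle.
7. **Statistics.** Welch's unequal-variance two-sided t-test with
   Welch–Satterthwaite degrees of freedom, implemented from the closed
   form (p-value from the t distribution) and test-verified to 1e-9
   against an independent reference. No multiple-testing correction by
   default, matching the practice of reporting raw pairwise p-values; a
   Holm flag exists in `compare`.

`QuantConfig` expresses lengths in micrometres and converts per image, so
densities are invariant (within discretization) to consistent resampling.
Projection precedes masking and detection; 3-D detection, stitching,
deconvolution and flat-field correction are out of scope.

## Synthetic fixtures

### Sequences

The generator emulates the real input of probe design: a target 16S-like
record (500 nt), a host 18S-like record (600 nt), and background contigs
(700 nt), with `n_planted_unique` compliant probe sites planted in the
target. Acceptance of *exactly* the planted sites is guaranteed by
construction rather than by chance:

* the first background contig is a copy of the target with each planted
  locus image replaced by random bases, so every non-planted target
  25-mer fails the uniqueness screen (mimicking a duplicated or highly
  conserved region);
* single `N` sentinels flank each planted locus, so the 48 shifted
  25-mers straddling it — which would be unique and would pass the
  overlap-excluded suffix screen — are excluded from candidacy by the
  N rule;
* planted k-mers are rejection-sampled until unique on both strands,
  inside the Tm window, structurally clean, and at suffix distance > 6
  from every non-self window (checked against the final record set; the
  erasure bases come from a fixed derived RNG so validation and the
  final build see identical contigs);
* one decoy locus receives the same treatment except that a copy of its
  suffix mutated to edit distance `mutation_distance` (default 3) is
  planted in the host, so the decoy survives uniqueness, Tm and
  structure and is rejected exactly by the indel screen.

Generation self-validates and raises rather than returning a fixture
whose truth is wrong. Identical spec + seed gives byte-identical records.

What this fixture does *not* emulate: real rRNA secondary structure and
conservation gradients, sequencing error, and the scale of a full
assembly (hundreds of contigs). Passing the design acceptance therefore
shows algorithmic correctness of the screens, not probe performance on
real genomes.

### Images

One or more hyphae are bounded-turning random walks spanning the field
left to right (mimicking procumbent single hyphae), dilated to
`tube_width_um` (2 µm) with a 1-px soft edge, amplitude 1, in the 18S
channel. Bacteria are isotropic Gaussian spots (σ = 0.25 µm, amplitude 1)
in the 16S channel: `n_spots_inside` (25) at least one spot radius (2σ)
inside the tube, `n_spots_outside` (5) well outside it, all centers at
least 4σ apart so exact-count assertions are well defined. Both channels
share a linear autofluorescence gradient along x and i.i.d. Gaussian
noise (σ = 0.2, i.e. spot SNR 5), clipped at zero as a detector black
level would; because of clipping, the noise-model sanity check measures
the noise std in the high-gradient (unclipped) half of the field. Stacks
carry two z-slices, the lower an exact half-intensity copy, so the max
projection reproduces the designed field exactly. Under `linear_decay`
the inside-spot x-positions are drawn with weight falling linearly to
0.2 across the field, giving the proximal-to-distal decline probed by
the transect analysis. The default field is 512×512 px at 0.1 µm/px;
with the default tube this yields ≈ 115 µm² of mycelium and a planted
density near 20 cells / 100 µm².

Not emulated: optical PSF and photon (Poisson) statistics, z-dependent
signal, hyphal branching and crossing, autofluorescent debris. Passing
recall/precision acceptance at SNR 5 therefore bounds detector behavior
under idealized noise, not on real micrographs.

## Numerical choices and degenerate inputs

* Constant image sets normalize to zeros with a warning (not an error).
* A blank field yields an empty mask and `NA` density in batch mode;
  the density operation itself raises on zero area.
* Strict (not ≥) local maxima in scale space; array borders do not
  constrain. Ties in overlap pruning break deterministically by
  (−response, y, x).
* The vacuous indel screen reports `+inf` and passes.
* Wallace Tm bounds are compared inclusively; values are exact integers.
* 16-bit TIFF export quantizes [0, max] linearly with round-half-even.
* All file writes are atomic (temp + rename); every CLI run writes a
  manifest with input digests and the resolved configuration.

## Problem sizes used in the shipped checks

Design checks run on the 500/600/2×700-nt fixture (≈ 2.4k suffix
windows); oracle equivalence uses ≤ 1800-nt inputs for the quadratic
uniqueness scan, 500 random pairs for edit distance, and 64×64 images
with 4-sigma ladders for the blob oracle; detection quality uses 10
replicates of the 512×512 SNR-5 fixture. These sizes were chosen so the
whole suite exercises every screen at full fidelity while remaining
quick to run on a laptop.

## Known limitations

* The uniqueness screen is exact-match only; near-identical off-targets
  are caught solely by the 18-nt edit-distance screen, and homology
  search (e.g. BLAST) remains a sensible external confirmation.
* The adaptive mask offset is expressed in normalized units and assumes
  bright-on-dark fluorescence; strongly autofluorescent backgrounds may
  need a larger margin or a different `block_um`.
* Blob positions are reported at pixel resolution (no sub-pixel
  refinement); density estimates are insensitive to this.
* Welch's test is applied per image-set pair; with many conditions the
  Holm option should be enabled.
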