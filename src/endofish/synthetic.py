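"""Deterministic synthetic fixtures with machine-readable ground truth.

Two generators:

* :func:`generate_sequences` builds an rRNA-like input set (one target, one
  host, background contigs) with planted probe-compliant 25-mer regions
  whose acceptance by the design pipeline is guaranteed by construction,
  plus a decoy region that the Levenshtein indel screen must reject.

* :func:`generate_image` builds a two-channel confocal-like field: a tubular
  hypha in the 18S channel and isotropic Gaussian bacterial spots in the 16S
  channel, with a shared linear autofluorescence gradient and Gaussian
  noise, plus the true mask and spot centers.

Both are driven by a single explicitly seeded ``numpy.random.Generator``;
identical spec + seed gives byte-identical output.

Construction of the sequence fixture (why acceptance is exact):

* every non-planted target k-mer also occurs verbatim in a background
  contig that is a copy of the target (with the planted loci erased), so it
  fails the uniqueness screen;
* each planted locus is flanked by single ``N`` sentinels, so the shifted
  k-mers straddling a planted locus contain an N and are excluded from
  candidacy (otherwise they would be unique and pass the suffix screen,
  since windows overlapping their own suffix are excluded from it);
* planted k-mers are rejection-sampled until they are unique on both
  strands, inside the melting-temperature window, structurally clean, and
  at suffix Levenshtein distance > the threshold from every non-self
  window of the whole set;
* the decoy k-mer gets the same treatment except that a copy of its suffix
  mutated to a prescribed edit distance is planted in the host record, so
  the decoy survives every stage except the indel screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .design import (
    DesignConfig,
    has_g_quadruplex,
    has_self_complementary_4mer,
    levenshtein_distance,
    melting_temperature,
    reverse_complement,
    suffix_indel_screen,
    _suffix_windows,
)
from .errors import GenerationError, InvalidParameterError
from .imaging import ImageStack
from .sequences import SequenceRecord

_BASES = np.array(list("ACGT"))


# ==========================================================================
# sequence fixtures

@dataclass(frozen=True)
class SeqFixtureSpec:
    """Conditions for the planted-probe sequence fixture."""

    seed: int = 0
    target_len: int = 500
    host_len: int = 600
    n_background: int = 2
    background_len: int = 700
    n_planted_unique: int = 1
    mutation_distance: int = 3

    def __post_init__(self):
        k = DesignConfig().k
        for name in ("target_len", "host_len", "background_len"):
            if getattr(self, name) < k:
                raise InvalidParameterError(f"{name} must be >= {k}")
        if self.n_planted_unique < 0:
            raise InvalidParameterError("n_planted_unique must be >= 0")
        if self.n_background < 1:
            raise InvalidParameterError(
                "at least one background contig is required (carries the "
                "target copy that de-uniquifies non-planted k-mers)"
            )
        if self.background_len < self.target_len:
            raise InvalidParameterError(
                "background_len must be >= target_len so the copy contig "
                "covers the whole target"
            )
        if self.mutation_distance < 1:
            raise InvalidParameterError("mutation_distance must be >= 1")


@dataclass
class SeqGroundTruth:
    """What was planted where."""

    planted: List[Tuple[str, int, str]]  # (source_id, position, kmer)
    decoy: Optional[Tuple[str, int, str]] = None
    decoy_copy: Optional[Tuple[str, int, str]] = None  # mutated suffix in host


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate_to_distance(
    rng: np.random.Generator, seq: str, distance: int, max_tries: int = 200
) -> str:
    """Substitution-mutated copy at exactly the requested edit distance."""
    for _ in range(max_tries):
        s = list(seq)
        for pos in rng.choice(len(s), size=distance, replace=False):
            choices = [b for b in "ACGT" if b != s[pos]]
            s[pos] = choices[rng.integers(len(choices))]
        mutated = "".join(s)
        if levenshtein_distance(mutated, seq) == distance:
            return mutated
    raise GenerationError(
        f"could not mutate segment to edit distance {distance}"
    )


def _kmer_ok_standalone(kmer: str, config: DesignConfig) -> bool:
    probe = reverse_complement(kmer)
    tm = melting_temperature(kmer, config.tm_method)
    if not (config.tm_low <= tm <= config.tm_high):
        return False
    if has_self_complementary_4mer(probe) or has_g_quadruplex(probe):
        return False
    return True


def _plant_slots(target_len: int, k: int, n_slots: int) -> List[int]:
    """Evenly spaced planting positions with N sentinels and no overlap."""
    margin = 2  # sentinel + one spare base at each end
    span = k + 2 * margin
    usable = target_len - 2 * margin
    if n_slots * (span + 10) > usable + 10:
        raise GenerationError(
            f"target_len {target_len} too short for {n_slots} planted regions"
        )
    step = usable // n_slots
    return [margin + i * step + (step - k) // 2 for i in range(n_slots)]


def generate_sequences(
    spec: SeqFixtureSpec, config: DesignConfig | None = None
) -> Tuple[List[SequenceRecord], SeqGroundTruth]:
    """Generate the planted-probe sequence fixture (see module docstring)."""
    if config is None:
        config = DesignConfig()
    rng = np.random.default_rng(spec.seed)
    k, sl = config.k, config.suffix_len
    max_attempts = 500

    target = list(_random_seq(rng, spec.target_len))
    host = list(_random_seq(rng, spec.host_len))
    extra_bgs = [
        _random_seq(rng, spec.background_len)
        for _ in range(spec.n_background - 1)
    ]

    n_slots = spec.n_planted_unique + 1  # + decoy
    slots = _plant_slots(spec.target_len, k, n_slots)
    decoy_pos, planted_pos = slots[0], slots[1:]

    # sentinels around every planted locus exclude straddling candidates
    for p in slots:
        target[p - 1] = "N"
        target[p + k] = "N"

    def build_records(
        target_s: str, host_s: str, copy_s: str
    ) -> List[SequenceRecord]:
        recs = [
            SequenceRecord("target_16S", target_s, "target"),
            SequenceRecord("host_18S", host_s, "host"),
            SequenceRecord("bg_contig_0", copy_s, "background"),
        ]
        for i, s in enumerate(extra_bgs):
            recs.append(SequenceRecord(f"bg_contig_{i + 1}", s, "background"))
        return recs

    def make_copy_contig(target_s: str) -> str:
        """Background copy of the target with planted images erased.

        Uses a fixed derived RNG so the erasure bases are identical on
        every call: trial validation during rejection sampling and the
        final build must see the same contig for the same target string.
        """
        erng = np.random.default_rng(spec.seed + 1_000_003)
        copy = list(target_s)
        for p in slots:
            for j in range(p - 1, p + k + 1):
                copy[j] = str(erng.choice(_BASES))
        pad = spec.background_len - len(copy)
        return "".join(copy) + _random_seq(erng, pad)

    def all_kmer_occurrences(records: List[SequenceRecord]) -> Dict[str, int]:
        occ: Dict[str, int] = {}
        for rec in records:
            seqs = [rec.sequence]
            if rec.role != "target" and config.screen_revcomp_background:
                seqs.append(reverse_complement(rec.sequence))
            for s in seqs:
                for i in range(len(s) - k + 1):
                    w = s[i : i + k]
                    occ[w] = occ.get(w, 0) + 1
        return occ

    # --- plant the decoy and the compliant k-mers by rejection sampling ---
    planted_kmers: List[str] = []
    decoy_kmer = ""
    decoy_copy_seg = ""
    decoy_host_pos = 0

    for attempt in range(max_attempts):
        kmer = _random_seq(rng, k)
        if "N" in kmer or not _kmer_ok_standalone(kmer, config):
            continue
        decoy_kmer = kmer
        decoy_copy_seg = _mutate_to_distance(
            rng, kmer[k - sl :], spec.mutation_distance
        )
        break
    else:
        raise GenerationError("could not sample a structurally clean decoy k-mer")

    decoy_host_pos = int(
        rng.integers(0, spec.host_len - sl + 1)
    )
    host[decoy_host_pos : decoy_host_pos + sl] = list(decoy_copy_seg)
    target[decoy_pos : decoy_pos + k] = list(decoy_kmer)

    for slot in planted_pos:
        placed = False
        for attempt in range(max_attempts):
            kmer = _random_seq(rng, k)
            if not _kmer_ok_standalone(kmer, config):
                continue
            trial_target = target.copy()
            trial_target[slot : slot + k] = list(kmer)
            records = build_records(
                "".join(trial_target), "".join(host),
                make_copy_contig("".join(trial_target)),
            )
            occ = all_kmer_occurrences(records)
            if occ.get(kmer, 0) != 1:
                continue
            d, ok = suffix_indel_screen(
                kmer, records, config,
                self_location=("target_16S", slot),
            )
            if not ok:
                continue
            # the new locus must not break previously planted loci
            earlier_ok = True
            for prev_slot, prev_kmer in zip(planted_pos, planted_kmers):
                dprev, okprev = suffix_indel_screen(
                    prev_kmer, records, config,
                    self_location=("target_16S", prev_slot),
                )
                if not okprev or occ.get(prev_kmer, 0) != 1:
                    earlier_ok = False
                    break
            if not earlier_ok:
                continue
            target = trial_target
            planted_kmers.append(kmer)
            placed = True
            break
        if not placed:
            raise GenerationError(
                "could not plant a compliant unique k-mer satisfying the "
                "suffix Levenshtein constraint"
            )

    records = build_records(
        "".join(target), "".join(host), make_copy_contig("".join(target))
    )

    # --- verify construction (truth must self-validate) ---
    occ = all_kmer_occurrences(records)
    for kmer in planted_kmers:
        if occ.get(kmer, 0) != 1:
            raise GenerationError("planted k-mer lost uniqueness")
    d_decoy, ok_decoy = suffix_indel_screen(
        decoy_kmer, records, config, self_location=("target_16S", decoy_pos)
    )
    if ok_decoy or d_decoy > spec.mutation_distance or occ.get(decoy_kmer, 0) != 1:
        raise GenerationError("decoy does not exercise the Levenshtein screen")

    truth = SeqGroundTruth(
        planted=[
            ("target_16S", slot, kmer)
            for slot, kmer in zip(planted_pos, planted_kmers)
        ],
        decoy=("target_16S", decoy_pos, decoy_kmer),
        decoy_copy=("host_18S", decoy_host_pos, decoy_copy_seg),
    )
    return records, truth


# ==========================================================================
# image fixtures

@dataclass(frozen=True)
class ImageFixtureSpec:
    """Conditions for the synthetic two-channel FISH micrograph.

    Defaults emulate a 51.2 µm confocal field at 0.1 µm/px with one hypha
    of 2 µm diameter, 25 bacteria inside it and 5 spots outside, spot
    amplitude 1 over Gaussian noise σ 0.2 (signal-to-noise ratio 5) and a
    mild linear autofluorescence gradient along x.
    """

    seed: int = 0
    shape: Tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.1
    n_hyphae: int = 1
    tube_width_um: float = 2.0
    n_spots_inside: int = 25
    n_spots_outside: int = 5
    spot_sigma_um: float = 0.25
    spot_amplitude: float = 1.0
    noise_sigma: float = 0.2
    background_gradient: float = 0.0002  # intensity per px along x
    density_profile: str = "uniform"

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise InvalidParameterError("pixel_size_um must be positive")
        if self.density_profile not in ("uniform", "linear_decay"):
            raise InvalidParameterError(
                f"unknown density_profile {self.density_profile!r}"
            )
        if min(self.shape) < 64:
            raise InvalidParameterError("image must be at least 64x64")


@dataclass
class ImageGroundTruth:
    """True mask and spot centers of a generated image."""

    mask: np.ndarray
    centers_inside: np.ndarray  # (n, 2) float (y, x)
    centers_outside: np.ndarray
    roi_counts: List[int] = field(default_factory=list)
    rois: List[Tuple[int, int, int, int]] = field(default_factory=list)


def _hypha_path(
    rng: np.random.Generator, shape: Tuple[int, int]
) -> np.ndarray:
    """Bounded-turning random walk spanning the field left to right."""
    h, w = shape
    y = float(rng.uniform(0.3 * h, 0.7 * h))
    heading = float(rng.uniform(-0.2, 0.2))
    pts = []
    x = 0.0
    while x < w:
        pts.append((y, x))
        heading += float(rng.uniform(-0.15, 0.15))
        heading = float(np.clip(heading, -0.5, 0.5))
        x += 2.0 * np.cos(heading)
        y += 2.0 * np.sin(heading)
        y = float(np.clip(y, 0.15 * h, 0.85 * h))
    return np.array(pts)


def _tube_distance(shape: Tuple[int, int], paths: List[np.ndarray]) -> np.ndarray:
    """Per-pixel distance to the nearest hyphal centerline."""
    canvas = np.ones(shape, dtype=bool)
    for pts in paths:
        ys = np.clip(np.rint(pts[:, 0]).astype(int), 0, shape[0] - 1)
        xs = np.clip(np.rint(pts[:, 1]).astype(int), 0, shape[1] - 1)
        canvas[ys, xs] = False
    if canvas.all():
        return np.full(shape, np.inf)
    return ndi.distance_transform_edt(canvas)


def _place_spots(
    rng: np.random.Generator,
    allowed: np.ndarray,
    n: int,
    min_sep: float,
    weights: Optional[np.ndarray] = None,
    max_attempts_factor: int = 500,
) -> np.ndarray:
    """Rejection-sample n spot centers on allowed pixels with min separation."""
    coords = np.argwhere(allowed)
    if len(coords) == 0 and n > 0:
        raise GenerationError("no allowed pixels for spot placement")
    if weights is not None:
        w = weights[allowed]
        p = w / w.sum()
    else:
        p = None
    placed: List[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts_factor * max(n, 1):
            raise GenerationError(
                f"could not place {n} spots with separation {min_sep:.1f} px"
            )
        idx = rng.choice(len(coords), p=p)
        cand = coords[idx].astype(float) + rng.uniform(-0.5, 0.5, size=2)
        if all(np.hypot(*(cand - q)) >= min_sep for q in placed):
            placed.append(cand)
    return np.array(placed).reshape(-1, 2)


def _render_spots(
    shape: Tuple[int, int], centers: np.ndarray, sigma: float, amplitude: float
) -> np.ndarray:
    """Sum of isotropic Gaussians, rendered on local patches for speed."""
    img = np.zeros(shape)
    half = int(np.ceil(4 * sigma))
    for (cy, cx) in centers:
        y0, y1 = max(0, int(cy) - half), min(shape[0], int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(shape[1], int(cx) + half + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
        )
    return img


def default_transect_rois(
    shape: Tuple[int, int], n: int = 5
) -> List[Tuple[int, int, int, int]]:
    """n equal-width vertical strips spanning the image, ordered along x."""
    h, w = shape
    edges = np.linspace(0, w, n + 1).astype(int)
    return [(0, h, edges[i], edges[i + 1]) for i in range(n)]


def generate_image(
    spec: ImageFixtureSpec,
) -> Tuple[ImageStack, ImageGroundTruth]:
    """Generate the synthetic micrograph (see module docstring).

    The stack has two z-slices (the lower one an exact half-intensity copy,
    so the max projection reproduces the designed field exactly) and two
    channels: 16S (bacterial spots) and 18S (hypha).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    px = spec.pixel_size_um
    sigma_px = spec.spot_sigma_um / px
    radius_px = spec.tube_width_um / 2.0 / px

    paths = [_hypha_path(rng, shape) for _ in range(spec.n_hyphae)]
    dist = _tube_distance(shape, paths)
    true_mask = dist <= radius_px
    # soft 1-px edge so the tube boundary is not aliased
    tube = np.clip(radius_px + 1.0 - dist, 0.0, 1.0)

    # inside spots sit >= one spot radius (2σ) from the tube boundary
    spot_radius = 2.0 * sigma_px
    inside_allowed = dist <= max(radius_px - spot_radius, 1.0)
    outside_allowed = dist >= radius_px + 3.0 * sigma_px
    weights = None
    if spec.density_profile == "linear_decay":
        xs = np.arange(shape[1], dtype=float)
        ramp = 1.0 - 0.8 * xs / max(shape[1] - 1, 1)
        weights = np.broadcast_to(ramp, shape).copy()

    min_sep = 4.0 * sigma_px
    centers_in = _place_spots(
        rng, inside_allowed, spec.n_spots_inside, min_sep, weights
    )
    all_centers = list(centers_in)
    centers_out = np.empty((0, 2))
    if spec.n_spots_outside > 0:
        # outside spots also keep separation from inside ones
        coords_attempts = 0
        placed_out: List[np.ndarray] = []
        coords = np.argwhere(outside_allowed)
        while len(placed_out) < spec.n_spots_outside:
            coords_attempts += 1
            if coords_attempts > 500 * spec.n_spots_outside:
                raise GenerationError("could not place outside spots")
            cand = coords[rng.choice(len(coords))].astype(float)
            cand = cand + rng.uniform(-0.5, 0.5, size=2)
            if all(
                np.hypot(*(cand - q)) >= min_sep
                for q in all_centers + placed_out
            ):
                placed_out.append(cand)
        centers_out = np.array(placed_out).reshape(-1, 2)

    spots = _render_spots(
        shape,
        np.vstack([centers_in, centers_out]) if len(centers_out) else centers_in,
        sigma_px,
        spec.spot_amplitude,
    )

    xs = np.arange(shape[1], dtype=float)
    gradient = np.broadcast_to(spec.background_gradient * xs, shape)

    ch16 = spots + gradient + rng.normal(0.0, spec.noise_sigma, shape)
    ch18 = tube + gradient + rng.normal(0.0, spec.noise_sigma, shape)
    ch16 = np.clip(ch16, 0.0, None)
    ch18 = np.clip(ch18, 0.0, None)

    data = np.stack(
        [
            np.stack([0.5 * ch16, ch16]),
            np.stack([0.5 * ch18, ch18]),
        ]
    ).astype(np.float32)
    stack = ImageStack(
        data=data,
        channel_roles={"sixteenS": 0, "eighteenS": 1},
        pixel_size_um=px,
        image_id=f"synthetic_seed{spec.seed}",
    )

    rois = default_transect_rois(shape)
    xs_in = np.rint(centers_in[:, 1]).astype(int) if len(centers_in) else np.array([], int)
    roi_counts = [
        int(np.sum((xs_in >= x0) & (xs_in < x1))) for (_, _, x0, x1) in rois
    ]
    truth = ImageGroundTruth(
        mask=true_mask,
        centers_inside=centers_in,
        centers_outside=centers_out,
        roi_counts=roi_counts,
        rois=rois,
    )
    return stack, truth
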