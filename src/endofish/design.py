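"""Taxon-specific FISH probe design.

The design pipeline derives candidate probes from a target small-subunit
rRNA sequence and screens them against the host rRNA and all other
assembled contigs:

1. k-merize the target into every possible k-mer (default k = 25);
2. keep k-mers occurring exactly once in the union of target sequences and
   never in any non-target sequence (both strands of non-target sequences
   by default, since background contigs are double-stranded DNA);
3. melting-temperature window screen;
4. indel robustness screen: the last ``suffix_len`` nucleotides (default 18)
   of the k-mer must be at Levenshtein distance strictly greater than
   ``lev_min_exclusive`` (default 6) from every non-self window of the
   input set — "non-self" excludes windows overlapping the candidate's own
   suffix occurrence, without which the shifted copies of the suffix itself
   (distance ≤ 2 per shifted base) would reject every candidate;
5. reverse complementation: the probe is the reverse complement of the
   target site;
6. structural screens on the probe: no self-complementary 4-mer pair at
   two distinct positions, and no canonical G-quadruplex motif.

Candidates are emitted in (source_id, position) order; no ranking score is
defined. Edit distances are computed with edlib using a k-bounded search so
the window scan abandons alignments that already exceed the running minimum.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import edlib

from .errors import InvalidInputError, InvalidParameterError
from .sequences import (
    SequenceRecord,
    check_unique_ids,
    enumerate_kmers,
    normalize_sequence,
    reverse_complement,
)

#: Sentinel reported when the indel screen has no non-self window to compare
#: against (the screen is then vacuously passed).
NO_WINDOW = math.inf

#: Stage names, in pipeline order, used for survivor counts and flags.
STAGES = ("kmerize", "unique", "tm", "levenshtein", "structure")


# --------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the probe design pipeline.

    Attributes
    ----------
    k : int
        Probe/target site length in nt.
    suffix_len : int
        Length of the terminal segment used by the indel screen.
    lev_min_exclusive : int
        Minimum Levenshtein distance; candidates pass only when strictly
        greater than this.
    tm_low, tm_high : float
        Inclusive melting-temperature window in °C. The lower bound is the
        hybridization temperature; the upper bound caps GC-saturated sites.
    tm_method : str
        ``wallace`` (2·AT + 4·GC) or ``nearest_neighbor`` (SantaLucia
        unified parameters, see :func:`melting_temperature`).
    forbid_selfcomp_4mers, forbid_g_quadruplex : bool
        Structural screens on the assembled probe.
    screen_revcomp_background : bool
        Also require absence of the target k-mer from the reverse
        complement of every non-target sequence.
    lev_scope : str
        ``all`` screens suffixes against every input sequence;
        ``target_only`` restricts the comparison set to target records.
    """

    k: int = 25
    suffix_len: int = 18
    lev_min_exclusive: int = 6
    tm_low: float = 37.0
    tm_high: float = 90.0
    tm_method: str = "wallace"
    forbid_selfcomp_4mers: bool = True
    forbid_g_quadruplex: bool = True
    screen_revcomp_background: bool = True
    lev_scope: str = "all"

    def __post_init__(self):
        if self.k < 1:
            raise InvalidParameterError(f"k must be >= 1, got {self.k}")
        if not (0 < self.suffix_len <= self.k):
            raise InvalidParameterError(
                f"suffix_len must satisfy 0 < suffix_len <= k, got {self.suffix_len}"
            )
        if self.lev_min_exclusive < 0:
            raise InvalidParameterError("lev_min_exclusive must be >= 0")
        if self.tm_low > self.tm_high:
            raise InvalidParameterError("tm_low must not exceed tm_high")
        if self.tm_method not in ("wallace", "nearest_neighbor"):
            raise InvalidParameterError(f"unknown tm_method {self.tm_method!r}")
        if self.lev_scope not in ("all", "target_only"):
            raise InvalidParameterError(f"unknown lev_scope {self.lev_scope!r}")


@dataclass
class ProbeCandidate:
    """One target site and its derived probe, with all screening metrics."""

    source_id: str
    position: int  # 0-based start of the k-mer on the target sequence
    target_kmer: str
    probe_sequence: str
    tm_c: Optional[float] = None
    min_suffix_lev: Optional[float] = None
    flags: Dict[str, bool] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        """True iff every pipeline flag was evaluated and passed."""
        required = ("unique", "tm", "levenshtein", "structure")
        return all(self.flags.get(name, False) for name in required)


@dataclass
class ProbeSet:
    """Ordered candidates plus the config and per-stage survivor counts."""

    candidates: List[ProbeCandidate]
    config: DesignConfig
    counts: Dict[str, int]

    @property
    def accepted(self) -> List[ProbeCandidate]:
        return [c for c in self.candidates if c.accepted]


# --------------------------------------------------------------------------
# melting temperature

# SantaLucia unified nearest-neighbor parameters (ΔH kcal/mol, ΔS cal/mol/K)
# at 1 M NaCl; duplex initiation 0.2/-5.7, terminal A·T penalty 2.2/6.9.
_NN_TABLE = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_NN_INIT = (0.2, -5.7)
_NN_TERM_AT = (2.2, 6.9)
_R_GAS = 1.987  # cal/mol/K
# Probe and target strand concentrations (nM), probe in excess.
_NN_DNAC1 = 25.0
_NN_DNAC2 = 12.5


def melting_temperature(seq: str, method: str = "wallace") -> float:
    """Melting temperature of a probe-length oligo in °C.

    ``wallace``: the Wallace rule 2·(#A+#T) + 4·(#G+#C), exact and
    integer-valued, appropriate for screening short oligos.

    ``nearest_neighbor``: two-state nearest-neighbor model with the
    SantaLucia unified parameter set at 1 M Na+ (no salt correction term),
    Tm = ΔH·1000 / (ΔS + R·ln(C_probe − C_target/2)) − 273.15 with the
    strand concentrations above.
    """
    seq = normalize_sequence(seq)
    if len(seq) < 2:
        raise InvalidInputError("melting temperature needs length >= 2")
    if "N" in seq:
        raise InvalidInputError("melting temperature undefined for sequences with N")
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        gc = seq.count("G") + seq.count("C")
        return float(2 * at + 4 * gc)
    if method == "nearest_neighbor":
        dh, ds = _NN_INIT
        for end in (seq[0], seq[-1]):
            if end in "AT":
                dh += _NN_TERM_AT[0]
                ds += _NN_TERM_AT[1]
        for i in range(len(seq) - 1):
            h, s = _NN_TABLE[seq[i : i + 2]]
            dh += h
            ds += s
        conc = (_NN_DNAC1 - _NN_DNAC2 / 2.0) * 1e-9
        return dh * 1000.0 / (ds + _R_GAS * math.log(conc)) - 273.15
    raise InvalidParameterError(f"unknown tm method {method!r}")


# --------------------------------------------------------------------------
# edit distance

def levenshtein_distance(a: str, b: str) -> int:
    """Standard unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def _bounded_distance(a: str, b: str, k: int) -> int:
    """Edit distance if ≤ k, else -1 (edlib early-exit band)."""
    if not a or not b:
        d = max(len(a), len(b))
        return d if d <= k else -1
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


# --------------------------------------------------------------------------
# uniqueness

def unique_target_kmers(
    targets: Sequence[SequenceRecord],
    others: Sequence[SequenceRecord],
    config: DesignConfig,
) -> Set[Tuple[str, int, str]]:
    """Target k-mers occurring exactly once in the union of targets and
    never in any other sequence (nor, by default, in the reverse complement
    of any other sequence).

    k-mers containing N are excluded from candidacy: assembly gaps must not
    generate probes.
    """
    if not targets:
        raise InvalidInputError("at least one target record is required")
    check_unique_ids(list(targets) + list(others))
    k = config.k

    target_counts: Dict[str, int] = {}
    occurrences: List[Tuple[str, int, str]] = []
    for rec in targets:
        for pos, kmer in enumerate_kmers(rec.sequence, k):
            target_counts[kmer] = target_counts.get(kmer, 0) + 1
            occurrences.append((rec.id, pos, kmer))

    other_kmers: Set[str] = set()
    for rec in others:
        seqs = [rec.sequence]
        if config.screen_revcomp_background:
            seqs.append(reverse_complement(rec.sequence))
        for s in seqs:
            for _, kmer in enumerate_kmers(s, k):
                other_kmers.add(kmer)

    return {
        (sid, pos, kmer)
        for (sid, pos, kmer) in occurrences
        if "N" not in kmer
        and target_counts[kmer] == 1
        and kmer not in other_kmers
    }


# --------------------------------------------------------------------------
# indel screen

def _suffix_windows(
    all_sequences: Sequence[SequenceRecord], suffix_len: int
) -> List[Tuple[str, int, str]]:
    """All suffix_len-length windows of the input set as (seq_id, start, window)."""
    out = []
    for rec in all_sequences:
        for pos in range(len(rec.sequence) - suffix_len + 1):
            out.append((rec.id, pos, rec.sequence[pos : pos + suffix_len]))
    return out


def suffix_indel_screen(
    candidate_kmer: str,
    all_sequences: Sequence[SequenceRecord],
    config: DesignConfig,
    *,
    self_location: Optional[Tuple[str, int]] = None,
    windows: Optional[List[Tuple[str, int, str]]] = None,
) -> Tuple[float, bool]:
    """Minimum edit distance of the candidate's terminal segment to every
    non-self window, and whether it strictly exceeds the threshold.

    ``self_location`` is the (sequence id, k-mer start) of the candidate's
    own occurrence; windows overlapping the candidate's suffix occurrence
    there are excluded from the comparison (they are shifted copies of the
    suffix itself and would otherwise always sit at distance ≤ 2 per base
    of shift). When no non-self window exists the screen is vacuous: the
    distance is reported as the ``NO_WINDOW`` (+inf) sentinel and the
    candidate passes.

    ``windows`` may carry a precomputed window list for repeated calls.
    """
    sl = config.suffix_len
    if len(candidate_kmer) != config.k:
        raise InvalidInputError(
            f"candidate length {len(candidate_kmer)} != k={config.k}"
        )
    suffix = candidate_kmer[config.k - sl :]
    if windows is None:
        windows = _suffix_windows(all_sequences, sl)

    self_id, self_suffix_start = (None, None)
    if self_location is not None:
        self_id = self_location[0]
        self_suffix_start = self_location[1] + config.k - sl

    best: float = NO_WINDOW
    for seq_id, pos, window in windows:
        if seq_id == self_id and abs(pos - self_suffix_start) < sl:
            continue  # overlaps the candidate's own suffix occurrence
        if best is NO_WINDOW or best == NO_WINDOW:
            d = levenshtein_distance(suffix, window)
        else:
            d = _bounded_distance(suffix, window, int(best) - 1)
            if d < 0:
                continue
        if d < best:
            best = d
            if best == 0:
                break
    return best, best > config.lev_min_exclusive


# --------------------------------------------------------------------------
# structural screens

def has_self_complementary_4mer(probe: str) -> bool:
    """True iff some 4-mer and its reverse complement occur at two distinct
    start positions of the probe.

    A single palindromic 4-mer occurrence (its own reverse complement at
    one position) does not trigger rejection: intramolecular pairing needs
    two physically distinct segments.
    """
    if len(probe) < 4:
        raise InvalidInputError("probe shorter than 4 nt")
    positions: Dict[str, List[int]] = {}
    for i in range(len(probe) - 3):
        positions.setdefault(probe[i : i + 4], []).append(i)
    for word, locs in positions.items():
        rc = reverse_complement(word)
        partner = positions.get(rc)
        if not partner:
            continue
        for i in locs:
            for j in partner:
                if i != j:
                    return True
    return False


# Canonical quadruplex motif: four runs of >= 3 G separated by loops of
# 1-7 arbitrary nucleotides.
_G4_RE = re.compile(r"G{3,}(?:[ACGTN]{1,7}?G{3,}){3}")


def has_g_quadruplex(probe: str) -> bool:
    """True iff the probe contains the canonical G-quadruplex motif
    (G≥3 N1–7 G≥3 N1–7 G≥3 N1–7 G≥3)."""
    return _G4_RE.search(probe) is not None


# --------------------------------------------------------------------------
# pipeline

def design_probes(
    records: Sequence[SequenceRecord], config: DesignConfig | None = None
) -> ProbeSet:
    """Run the full probe design pipeline over an input sequence set.

    Deterministic given identical input and config. Candidates that fail a
    stage do not advance (later metrics stay ``None``); stage survivor
    counts are recorded and are monotonically non-increasing.
    """
    if config is None:
        config = DesignConfig()
    records = list(records)
    check_unique_ids(records)
    targets = [r for r in records if r.role == "target"]
    others = [r for r in records if r.role != "target"]
    if not targets:
        raise InvalidInputError("at least one target record is required")

    counts: Dict[str, int] = {}
    candidates: List[ProbeCandidate] = []
    n_kmers = 0
    for rec in targets:
        for pos, kmer in enumerate_kmers(rec.sequence, config.k):
            n_kmers += 1
            if "N" in kmer:
                continue
            candidates.append(
                ProbeCandidate(
                    source_id=rec.id,
                    position=pos,
                    target_kmer=kmer,
                    probe_sequence=reverse_complement(kmer),
                )
            )
    counts["kmerize"] = n_kmers

    unique = unique_target_kmers(targets, others, config)
    unique_keys = {(sid, pos) for (sid, pos, _) in unique}
    for c in candidates:
        c.flags["unique"] = (c.source_id, c.position) in unique_keys
    survivors = [c for c in candidates if c.flags["unique"]]
    counts["unique"] = len(survivors)

    for c in survivors:
        c.tm_c = melting_temperature(c.target_kmer, config.tm_method)
        c.flags["tm"] = config.tm_low <= c.tm_c <= config.tm_high
    survivors = [c for c in survivors if c.flags["tm"]]
    counts["tm"] = len(survivors)

    scope = targets if config.lev_scope == "target_only" else records
    windows = _suffix_windows(scope, config.suffix_len)
    for c in survivors:
        d, ok = suffix_indel_screen(
            c.target_kmer,
            scope,
            config,
            self_location=(c.source_id, c.position),
            windows=windows,
        )
        c.min_suffix_lev = d
        c.flags["levenshtein"] = ok
    survivors = [c for c in survivors if c.flags["levenshtein"]]
    counts["levenshtein"] = len(survivors)

    for c in survivors:
        ok = True
        if config.forbid_selfcomp_4mers and has_self_complementary_4mer(
            c.probe_sequence
        ):
            ok = False
        if ok and config.forbid_g_quadruplex and has_g_quadruplex(c.probe_sequence):
            ok = False
        c.flags["structure"] = ok
    survivors = [c for c in survivors if c.flags.get("structure")]
    counts["structure"] = len(survivors)

    candidates.sort(key=lambda c: (c.source_id, c.position))
    return ProbeSet(candidates=candidates, config=config, counts=counts)
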