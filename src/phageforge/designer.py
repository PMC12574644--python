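"""Single-base programming of immunostimulatory ssDNA for reprogrammed M13 phages.

The packaged ssDNA of an M13 phagemid is non-coding, so its sequence can be
rewritten freely to tune the particle's adjuvanticity (TLR9 stimulation by
unmethylated CG dinucleotides) and, through its length, the filament length.
This module builds such sequences from three design principles:

1. CG dimers are placed at a controlled density; the flanking DNA between
   them is drawn from {A,T,C,G} but may not start with C or end with G, and
   is kept free of incidental CG dimers so the dimer count is exact.
2. Direct repeats of ``min_repeat_len`` (default 9) bases or longer are
   eliminated by A<->T point mutations, which cannot change C/G content.
3. Hairpin stems -- intramolecular inverted repeats of ``min_stem_len``
   (default 13, i.e. "longer than 12") bases -- are eliminated the same way.

A chosen fraction of the placed CG dimers can additionally be embedded in
canonical murine CpG hexamers (AACGTT / GACGTT), the most potent TLR9
contexts, by replacing the 2-nt dimer with the 6-nt hexamer (net +4 nt per
site, lengthening the phage correspondingly).

All coordinates are 0-based, half-open, 5'->3'.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InfeasibleDesignError,
    UnresolvableHairpinError,
    UnresolvableRepeatError,
)

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_HEXAMERS = ("AACGTT", "GACGTT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """Recipe for one reprogrammed ssDNA.

    Parameters
    ----------
    length_nt
        Target sequence length before any hexamer expansion, in nucleotides.
    cg_fraction
        Target fraction of nucleotides belonging to placed CG dimers,
        ``2 * n_cg / length_nt``; 0.27 places 191 dimers in 1415 nt.
    hexamer_fraction
        Fraction of placed CG dimers to embed in canonical CpG hexamers.
    hexamer_set
        Hexamer motifs to draw from; each must contain exactly one CG dimer.
    min_repeat_len
        Shortest direct repeat that is disallowed (default 9).
    min_stem_len
        Shortest inverted-repeat stem that is disallowed (default 13,
        i.e. stems "longer than 12" bases).
    seed
        Seed for all randomness in scaffold generation and hexamer placement.
    hexamer_in_place
        If True, hexamers overwrite the 6-nt window centred on the dimer
        instead of expanding the sequence by 4 nt per site.
    max_restarts
        Fresh scaffolds to try in :func:`design` before surfacing a repair
        failure.
    """

    length_nt: int
    cg_fraction: float = 0.0
    hexamer_fraction: float = 0.0
    hexamer_set: tuple[str, ...] = DEFAULT_HEXAMERS
    min_repeat_len: int = 9
    min_stem_len: int = 13
    seed: int = 0
    hexamer_in_place: bool = False
    max_restarts: int = 5

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise ValueError("length_nt must be positive")
        if not 0.0 <= self.cg_fraction <= 1.0:
            raise ValueError("cg_fraction must lie in [0, 1]")
        if not 0.0 <= self.hexamer_fraction <= 1.0:
            raise ValueError("hexamer_fraction must lie in [0, 1]")
        if self.min_repeat_len < 2 or self.min_stem_len < 2:
            raise ValueError("min_repeat_len and min_stem_len must be >= 2")
        for h in self.hexamer_set:
            if len(h) != 6 or h.count("CG") != 1:
                raise ValueError(
                    f"hexamer {h!r} must be a 6-mer containing exactly one CG dimer"
                )
        if self.length_nt < 2 * self.n_cg:
            raise InfeasibleDesignError(
                f"cannot place {self.n_cg} CG dimers in {self.length_nt} nt"
            )

    @property
    def n_cg(self) -> int:
        """Number of CG dimers implied by ``cg_fraction``."""
        return round(self.cg_fraction * self.length_nt / 2)


@dataclass(frozen=True)
class RepeatHit:
    """A k-mer occurring at two or more offsets in the same orientation."""

    kmer: str
    length: int
    positions: tuple[int, ...]


@dataclass(frozen=True)
class HairpinHit:
    """Two windows of length ``stem_len`` that are mutually reverse-complementary."""

    stem_len: int
    arm1_start: int
    arm2_start: int


@dataclass(frozen=True)
class Mutation:
    position: int
    from_base: str
    to_base: str
    reason: str  # "repeat" | "hairpin" | "hexamer" | "scaffold"


@dataclass
class MutationLog:
    entries: list[Mutation] = field(default_factory=list)

    def add(self, position: int, from_base: str, to_base: str, reason: str) -> None:
        self.entries.append(Mutation(position, from_base, to_base, reason))

    def extend(self, other: "MutationLog") -> None:
        self.entries.extend(other.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def to_dicts(self) -> list[dict]:
        return [dataclasses.asdict(e) for e in self.entries]


@dataclass
class ConstraintReport:
    """Audit of a sequence against the design principles."""

    length_nt: int
    n_cg_dimers: int
    cg_fraction_realized: float
    cg_percent: int
    n_hexamer_embedded: int
    hexamer_pct_of_cg: float
    repeats: list[RepeatHit]
    hairpins: list[HairpinHit]
    boundary_violations: list[int]
    clean: bool

    def to_dict(self) -> dict:
        return {
            "length_nt": self.length_nt,
            "n_cg_dimers": self.n_cg_dimers,
            "cg_fraction_realized": self.cg_fraction_realized,
            "cg_percent": self.cg_percent,
            "n_hexamer_embedded": self.n_hexamer_embedded,
            "hexamer_pct_of_cg": self.hexamer_pct_of_cg,
            "repeats": [dataclasses.asdict(r) for r in self.repeats],
            "hairpins": [dataclasses.asdict(h) for h in self.hairpins],
            "boundary_violations": list(self.boundary_violations),
            "clean": self.clean,
        }


@dataclass
class DesignResult:
    sequence: str
    mask: np.ndarray  # boolean; True = protected
    report: ConstraintReport
    log: MutationLog
    spec: DesignSpec
    restarts_used: int = 0


# ---------------------------------------------------------------------------
# Motif bookkeeping
# ---------------------------------------------------------------------------


def find_cg_dimers(seq: str) -> list[int]:
    """0-based start offsets of every CG dinucleotide (overlap-free by nature)."""
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def _hexamer_occurrences(seq: str, hexamer_set: tuple[str, ...]) -> list[int]:
    """Start offsets of every hexamer-set motif occurrence."""
    hits = []
    motifs = set(hexamer_set)
    for i in range(len(seq) - 5):
        if seq[i : i + 6] in motifs:
            hits.append(i)
    return hits


def _creates_hexamer(seq: list[str], pos: int, new_base: str,
                     hexamer_set: tuple[str, ...]) -> bool:
    """Would setting seq[pos] = new_base create a hexamer-set motif covering pos?

    Hexamer motifs are reserved as deliberate immunostimulatory signals: the
    scaffold generator and the repair passes refuse to create one by accident,
    so a motif census over the final sequence counts exactly the intended
    conversions.
    """
    old = seq[pos]
    seq[pos] = new_base
    try:
        motifs = set(hexamer_set)
        # only occurrences covering pos can be new; pre-existing motifs are
        # fully protected and never contain a mutable position
        for s in range(max(0, pos - 5), min(len(seq) - 6, pos) + 1):
            if "".join(seq[s : s + 6]) in motifs:
                return True
        return False
    finally:
        seq[pos] = old


# ---------------------------------------------------------------------------
# Scaffold generation
# ---------------------------------------------------------------------------


def _split_gaps(total: int, n_gaps: int, rng: np.random.Generator) -> list[int]:
    """Partition `total` nt of flank across `n_gaps` gaps, evenly with jitter.

    Jitter is +/-25% of the mean gap, enough to break the periodicity that an
    exactly even placement would imprint (periodic dimer placement seeds long
    direct repeats), while keeping the density visually uniform.
    """
    if n_gaps == 1:
        return [total]
    mean = total / n_gaps
    raw = mean + rng.uniform(-0.25, 0.25, size=n_gaps) * mean
    raw = np.clip(raw, 0.0, None)
    # largest-remainder rounding to hit the exact total
    base = np.floor(raw).astype(int)
    deficit = total - int(base.sum())
    if deficit > 0:
        order = np.argsort(-(raw - base))
        base[order[:deficit]] += 1
    elif deficit < 0:
        order = np.argsort(raw - base)
        k = 0
        while deficit < 0:
            i = order[k % n_gaps]
            if base[i] > 0:
                base[i] -= 1
                deficit += 1
            k += 1
    return base.tolist()


class _KmerTracker:
    """Rolling census of the k-mers emitted so far during scaffold growth.

    Lets the sampler steer away from completing a k-mer that already exists,
    which keeps the scaffold essentially repeat-free from the start instead
    of leaving dozens of collisions for the repair pass.
    """

    def __init__(self, k: int):
        self.k = k
        self.counts: dict[str, int] = defaultdict(int)
        self.chars: list[str] = []

    def push(self, c: str) -> None:
        self.chars.append(c)
        if len(self.chars) >= self.k:
            self.counts["".join(self.chars[-self.k :])] += 1

    def completed_count(self, c: str) -> int:
        """Occurrences of the k-mer that appending ``c`` would complete."""
        if len(self.chars) < self.k - 1:
            return 0
        return self.counts["".join(self.chars[-(self.k - 1) :]) + c]


def _sample_flank(length: int, rng: np.random.Generator,
                  tracker: _KmerTracker) -> None:
    """Append a random flank: no internal CG, no leading C, no trailing G.

    Among the bases the boundary rules allow, prefer those that do not
    complete a k-mer already present (ties broken by the seeded generator);
    when every choice collides, take one with the lowest occurrence count.
    """
    for i in range(length):
        allowed = "ACGT"
        if i == 0:
            allowed = allowed.replace("C", "")
        if i == length - 1:
            allowed = allowed.replace("G", "")
        if tracker.chars and tracker.chars[-1] == "C":
            allowed = allowed.replace("G", "")
        counts = [tracker.completed_count(c) for c in allowed]
        best = min(counts)
        pool = [c for c, n in zip(allowed, counts) if n == best]
        tracker.push(pool[rng.integers(len(pool))])


def scaffold_sequence(spec: DesignSpec) -> tuple[str, np.ndarray]:
    """Generate the initial sequence: evenly spread CG dimers in random flanks.

    Flank bases are sampled with a preference against completing an already
    seen k-mer, and a refinement pass then re-samples flank bases (full legal
    alphabet) until no direct repeat of length >= ``min_repeat_len`` remains,
    so the scaffold hands the composition-preserving A<->T repair passes a
    sequence they can always finish.  Returns the sequence and a protection
    mask flagging every placed dimer position.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_cg = spec.n_cg
    flank_total = spec.length_nt - 2 * n_cg
    if flank_total < 0:
        raise InfeasibleDesignError(
            f"cannot place {n_cg} CG dimers in {spec.length_nt} nt"
        )
    gaps = _split_gaps(flank_total, n_cg + 1, rng)
    tracker = _KmerTracker(spec.min_repeat_len)
    dimer_starts: list[int] = []
    for g in gaps[:-1]:
        _sample_flank(g, rng, tracker)
        dimer_starts.append(len(tracker.chars))
        tracker.push("C")
        tracker.push("G")
    _sample_flank(gaps[-1], rng, tracker)
    seq = tracker.chars
    assert len(seq) == spec.length_nt

    # Scrub accidental hexamer motifs: flanks are CG-free, so any motif must
    # straddle a placed dimer with AA/GA on the left and TT on the right.
    # Setting the base just after the dimer to A destroys it irreversibly.
    for d in dimer_starts:
        for m in spec.hexamer_set:
            off = m.index("CG")
            s = d - off
            if s >= 0 and s + 6 <= len(seq) and "".join(seq[s : s + 6]) == m:
                seq[d + 2] = "A"
    mask = np.zeros(spec.length_nt, dtype=bool)
    for d in dimer_starts:
        mask[d] = mask[d + 1] = True
    _refine_context(seq, mask, spec.min_repeat_len, spec.hexamer_set,
                    MutationLog(), reason="scaffold", rng=rng,
                    stem_k=spec.min_stem_len)
    return "".join(seq), mask


# ---------------------------------------------------------------------------
# Repeat / hairpin detection
# ---------------------------------------------------------------------------


def find_direct_repeats(seq: str, min_len: int) -> list[RepeatHit]:
    """Every ``min_len``-mer occurring at >= 2 distinct offsets.

    Any direct repeat of length >= min_len contains a repeated min_len-mer,
    so an empty result certifies the sequence repeat-free at that threshold.
    """
    _check_alphabet(seq)
    k = min_len
    if len(seq) < k:
        return []
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    hits = [
        RepeatHit(kmer, k, tuple(pos))
        for kmer, pos in index.items()
        if len(pos) >= 2
    ]
    hits.sort(key=lambda h: h.positions)
    return hits


def find_inverted_repeats(seq: str, min_stem: int) -> list[HairpinHit]:
    """Every window pair (length ``min_stem``) that is mutually reverse-complementary.

    No minimum loop separation is imposed and arms may overlap; a window is
    never paired with itself at identical coordinates.  This is a conservative
    superset of thermodynamically foldable hairpins.
    """
    _check_alphabet(seq)
    k = min_stem
    if len(seq) < k:
        return []
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    pairs: set[tuple[int, int]] = set()
    for kmer, positions in index.items():
        rc = reverse_complement(kmer)
        if rc not in index:
            continue
        for i in positions:
            for j in index[rc]:
                if i != j:
                    pairs.add((min(i, j), max(i, j)))
    return [HairpinHit(k, a, b) for a, b in sorted(pairs)]


# ---------------------------------------------------------------------------
# Repair passes
# ---------------------------------------------------------------------------


def _mutable_positions(seq: list[str], mask: np.ndarray, start: int, k: int) -> list[int]:
    return [
        p
        for p in range(start, start + k)
        if seq[p] in "AT" and not mask[p]
    ]


def _flip(base: str) -> str:
    return "T" if base == "A" else "A"

# Flips allowed per position per repair pass.  A flip that breaks one window
# can recreate another; bounding revisits makes every pass terminate.
_POSITION_FLIP_BUDGET = 6


def _candidate_order(chars, mask, instances, k, flip_count, hexamer_set):
    """Candidate flip positions: first instance first, leftmost first.

    Skips protected positions, positions over their flip budget, and flips
    that would incidentally create a CpG-hexamer motif.
    """
    seen: set[int] = set()
    for inst in instances:
        for p in _mutable_positions(chars, mask, inst, k):
            if p in seen or flip_count.get(p, 0) >= _POSITION_FLIP_BUDGET:
                continue
            seen.add(p)
            if _creates_hexamer(chars, p, _flip(chars[p]), hexamer_set):
                continue
            yield p


def _repeat_excess_delta(chars, counts, p: int, new_char: str, k: int) -> int:
    """Change in total repeat multiplicity if chars[p] becomes new_char.

    ``counts`` maps each k-mer to its occurrence count; the repeat excess is
    sum(max(c - 1, 0)).  Only the k windows covering p change.
    """
    n = len(chars)
    lo = max(0, p - k + 1)
    hi = min(p, n - k)
    old = chars[p]
    delta = 0
    touched: list[tuple[str, int]] = []
    for s in range(lo, hi + 1):
        u = "".join(chars[s : s + k])
        if counts[u] >= 2:
            delta -= 1
        counts[u] -= 1
        touched.append((u, 1))
    chars[p] = new_char
    for s in range(lo, hi + 1):
        v = "".join(chars[s : s + k])
        if counts[v] >= 1:
            delta += 1
        counts[v] += 1
        touched.append((v, -1))
    chars[p] = old
    for kmer, d in touched:
        counts[kmer] += d
    return delta


def eliminate_repeats(
    seq: str,
    mask: np.ndarray,
    min_len: int,
    hexamer_set: tuple[str, ...] = DEFAULT_HEXAMERS,
    max_mutations: int | None = None,
) -> tuple[str, MutationLog]:
    """Break every direct repeat of length >= ``min_len`` by A<->T mutations.

    Each round addresses the first (leftmost) flagged repeat family: among
    the unprotected A/T positions inside its instances (first instance
    preferred, leftmost first) the pass flips the one that most reduces the
    global count of repeated k-mers, then re-scans.  C and G counts, and
    hence the CG-dimer count, are invariant under this pass.
    """
    _check_alphabet(seq)
    k = min_len
    cap = max_mutations if max_mutations is not None else 10 * len(seq)
    chars = list(seq)
    log = MutationLog()
    flip_count: dict[int, int] = {}
    while True:
        hits = find_direct_repeats("".join(chars), k)
        if not hits:
            break
        if len(log) >= cap:
            raise UnresolvableRepeatError(
                f"repeat elimination exceeded {cap} mutations", window=hits[0]
            )
        counts: dict[str, int] = defaultdict(int)
        for i in range(len(chars) - k + 1):
            counts["".join(chars[i : i + k])] += 1

        # First flip that strictly reduces the global repeat excess wins
        # (families in leftmost order, first instance preferred).  If no
        # flip improves, take the flattest plateau move; the per-position
        # budget keeps plateau ping-pong finite.
        best_p, best_key = None, None
        improving = None
        for hit in hits:
            for p in _candidate_order(chars, mask, hit.positions, k,
                                      flip_count, hexamer_set):
                d = _repeat_excess_delta(chars, counts, p, _flip(chars[p]), k)
                if d < 0:
                    improving = p
                    break
                key = (d, flip_count.get(p, 0), p)
                if best_key is None or key < best_key:
                    best_p, best_key = p, key
            if improving is not None:
                break
        best_p = improving if improving is not None else best_p
        if best_p is None:
            hit = hits[0]
            raise UnresolvableRepeatError(
                f"no mutable A/T available for repeat {hit.kmer!r} "
                f"at {hit.positions}",
                window=hit,
            )
        old = chars[best_p]
        chars[best_p] = _flip(old)
        flip_count[best_p] = flip_count.get(best_p, 0) + 1
        log.add(best_p, old, chars[best_p], "repeat")
    return "".join(chars), log


def eliminate_hairpins(
    seq: str,
    mask: np.ndarray,
    min_stem: int,
    hexamer_set: tuple[str, ...] = DEFAULT_HEXAMERS,
    max_mutations: int | None = None,
) -> tuple[str, MutationLog]:
    """Break every inverted repeat with stem >= ``min_stem`` by A<->T mutations.

    Mutation choice mirrors :func:`eliminate_repeats`: candidates are the
    unprotected A/T positions in the flagged arms (first arm preferred,
    leftmost first) and the flip minimizing the remaining number of
    inverted-repeat hits is applied; the sequence is re-scanned after every
    mutation.
    """
    _check_alphabet(seq)
    k = min_stem
    cap = max_mutations if max_mutations is not None else 10 * len(seq)
    chars = list(seq)
    log = MutationLog()
    flip_count: dict[int, int] = {}
    while True:
        hits = find_inverted_repeats("".join(chars), k)
        if not hits:
            break
        if len(log) >= cap:
            raise UnresolvableHairpinError(
                f"hairpin elimination exceeded {cap} mutations", window=hits[0]
            )
        hit = hits[0]
        arms = (hit.arm1_start, hit.arm2_start)
        best_p, best_n = None, None
        for p in _candidate_order(chars, mask, arms, k, flip_count, hexamer_set):
            old = chars[p]
            chars[p] = _flip(old)
            n_hits = len(find_inverted_repeats("".join(chars), k))
            chars[p] = old
            if best_n is None or n_hits < best_n:
                best_p, best_n = p, n_hits
                if n_hits < len(hits) - 1:
                    break
        if best_p is None:
            raise UnresolvableHairpinError(
                f"no mutable A/T available for hairpin arms at {arms}",
                window=hit,
            )
        old = chars[best_p]
        chars[best_p] = _flip(old)
        flip_count[best_p] = flip_count.get(best_p, 0) + 1
        log.add(best_p, old, chars[best_p], "hairpin")
    return "".join(chars), log


# ---------------------------------------------------------------------------
# Hexamer conversion
# ---------------------------------------------------------------------------


def insert_cpg_hexamers(
    seq: str,
    mask: np.ndarray,
    fraction: float,
    hexamer_set: tuple[str, ...] = DEFAULT_HEXAMERS,
    seed: int = 0,
    in_place: bool = False,
    refine_k: int | None = None,
    refine_stem_k: int | None = None,
) -> tuple[str, np.ndarray, MutationLog]:
    """Embed ``round(fraction * n_cg)`` CG dimers in canonical CpG hexamers.

    By default each selected 2-nt CG dimer is replaced by a 6-nt hexamer
    (net +4 nt per site), lengthening the packaged ssDNA and hence the phage.
    With ``in_place=True`` the hexamer instead overwrites the 6-nt window
    centred on the dimer, preserving total length; sites whose window touches
    another protected position are ineligible in that mode.

    Hexamers initially alternate through ``hexamer_set`` deterministically
    from the seed; a subsequent sweep re-chooses each site's motif greedily
    to minimize the direct repeats the insertion creates (two sites with
    identical rigid flanks would otherwise collide irreparably, since repair
    may only touch A/T).  A site whose left neighbour is C always receives
    an A-starting motif so the junction cannot create a new CG dimer.  All
    inserted motif positions are protected.  The CG-dimer count is unchanged.

    With ``refine_k`` set, a context-refinement step follows: flank bases
    around the insertions may be re-sampled (full legal alphabet, scaffold
    rules enforced) until no direct repeat of length >= refine_k remains, so
    the subsequent A<->T repair passes are never asked to break a collision
    they cannot.  Without it, repeat/hairpin re-elimination is entirely the
    caller's responsibility, normally via :func:`design`.
    """
    _check_alphabet(seq)
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    dimers = find_cg_dimers(seq)
    if fraction > 0 and not dimers:
        raise InfeasibleDesignError("hexamer conversion requested but sequence has no CG dimer")
    n_hex = round(fraction * len(dimers))
    log = MutationLog()
    if n_hex == 0:
        return seq, mask.copy(), log

    rng = np.random.default_rng(seed)
    if in_place:
        eligible = [
            d for d in dimers
            if d >= 2 and d + 4 <= len(seq)
            and not (mask[d - 2 : d].any() or mask[d + 2 : d + 4].any())
        ]
        # rewritten 6-nt windows must not overlap each other
        sites: list[int] = []
        for i in rng.permutation(len(eligible)).tolist():
            d = eligible[i]
            if all(abs(d - s) >= 6 for s in sites):
                sites.append(d)
                if len(sites) == n_hex:
                    break
        sites.sort()
        if len(sites) < n_hex:
            raise InfeasibleDesignError(
                f"only {len(sites)} non-overlapping CG dimers are eligible for "
                f"in-place hexamer conversion; {n_hex} requested"
            )
    else:
        if len(dimers) < n_hex:
            raise InfeasibleDesignError(
                f"only {len(dimers)} of {len(dimers)} CG dimers are eligible "
                f"for hexamer conversion; {n_hex} requested"
            )
        # Random selection, spread out where possible: two adjacent dimers
        # both converted leave almost no free context between their motifs,
        # the dominant source of unrepairable repeats.
        order = rng.permutation(len(dimers)).tolist()
        picked: set[int] = set()
        for i in order:
            if len(picked) == n_hex:
                break
            if (i - 1) not in picked and (i + 1) not in picked:
                picked.add(i)
        for i in order:  # fall back to adjacency if the spread runs out
            if len(picked) == n_hex:
                break
            picked.add(i)
        sites = [dimers[i] for i in sorted(picked)]

    a_starting = [m for m in hexamer_set if m[0] != "G"]
    motif_cycle = list(hexamer_set)
    start = int(rng.integers(len(motif_cycle)))

    chars = list(seq)
    new_chars: list[str] = []
    new_mask: list[bool] = []
    motif_starts: list[int] = []  # coordinates in the new sequence
    allowed_per_site: list[list[str]] = []
    prev_end = 0
    for j, d in enumerate(sites):
        left_at = d - 3 if in_place else d - 1
        left = chars[left_at] if left_at >= 0 else ""
        if left == "C":
            if not a_starting:
                raise InfeasibleDesignError(
                    "no A-starting hexamer available to avoid a junction CG"
                )
            allowed = a_starting
        else:
            allowed = list(hexamer_set)
        motif = motif_cycle[(start + j) % len(motif_cycle)]
        if motif not in allowed:
            motif = allowed[j % len(allowed)]
        seg_start = d - 2 if in_place else d
        new_chars.extend(chars[prev_end:seg_start])
        new_mask.extend(mask[prev_end:seg_start].tolist())
        motif_starts.append(len(new_chars))
        allowed_per_site.append(allowed)
        new_chars.extend(motif)
        new_mask.extend([True] * 6)
        prev_end = d + 4 if in_place else d + 2
    new_chars.extend(chars[prev_end:])
    new_mask.extend(mask[prev_end:].tolist())

    _optimize_motif_choice(new_chars, motif_starts, allowed_per_site)
    for d, q in zip(sites, motif_starts):
        log.add(d, "CG", "".join(new_chars[q : q + 6]), "hexamer")
    mask_out = np.array(new_mask, dtype=bool)
    if refine_k is not None:
        _reassign_site_contexts(new_chars, mask_out, motif_starts, refine_k,
                                hexamer_set, rng, log)
        _refine_context(new_chars, mask_out, refine_k, hexamer_set, log,
                        rng=rng, stem_k=refine_stem_k)
    return "".join(new_chars), mask_out, log


def _legal_substitutions(chars: list[str], mask: np.ndarray, p: int,
                         hexamer_set: tuple[str, ...]) -> list[str]:
    """Bases that may replace chars[p] without violating any scaffold rule.

    Unprotected flank positions only.  A substitute must not create a CG
    dimer with either neighbour (flanks stay CG-free, so the placed-dimer
    census is preserved), must respect the flank boundary rules (no C right
    after, no G right before, a protected block or a sequence end), and must
    not complete a CpG-hexamer motif.
    """
    if mask[p]:
        return []
    n = len(chars)
    # boundary rules bind only at placed CG dimers: a flank may not start
    # with C right after a dimer nor end with G right before one (hexamer
    # motifs shield their internal dimer with their own A/T context)
    after_dimer = p >= 2 and mask[p - 1] and chars[p - 2] == "C" and chars[p - 1] == "G"
    before_dimer = (p + 2 < n and mask[p + 1]
                    and chars[p + 1] == "C" and chars[p + 2] == "G")
    out = []
    for b in ALPHABET:
        if b == chars[p]:
            continue
        if b == "G" and p > 0 and chars[p - 1] == "C":
            continue
        if b == "C" and p + 1 < n and chars[p + 1] == "G":
            continue
        if b == "C" and after_dimer:
            continue
        if b == "G" and before_dimer:
            continue
        if _creates_hexamer(chars, p, b, hexamer_set):
            continue
        out.append(b)
    return out


def _refine_context(
    chars: list[str],
    mask: np.ndarray,
    k: int,
    hexamer_set: tuple[str, ...],
    log: MutationLog,
    reason: str = "hexamer_context",
    rng: np.random.Generator | None = None,
    max_changes: int | None = None,
    max_kicks: int = 60,
    stem_k: int | None = None,
) -> None:
    """Drive direct-repeat excess (and hairpin count) to zero by re-sampling.

    Unlike the A<->T repair passes, this refinement may substitute any base
    the scaffold rules allow at an unprotected position, which lets it break
    collisions whose windows carry no mutable A/T at all (e.g. two hexamer
    conversion sites with identical rigid flank context).  With ``stem_k``
    set, inverted repeats of that stem length count in the objective too, so
    fixing one class of violation cannot silently trade for the other.
    Greedy descent: first strictly improving substitution wins, flattest
    plateau move as fallback, a per-position budget against ping-pong, and
    -- when the descent is globally stuck -- a seeded random kick (one legal
    substitution in a flagged window, budgets reset), i.e. iterated local
    search.  In-place on ``chars``.
    """
    cap = max_changes if max_changes is not None else 10 * len(chars)
    rng = rng if rng is not None else np.random.default_rng(0)
    change_count: dict[int, int] = {}
    n_changes = 0
    kicks = 0
    best_seen = None
    stall = 0
    stall_limit = 150
    while True:
        s = "".join(chars)
        hits = find_direct_repeats(s, k)
        stems = find_inverted_repeats(s, stem_k) if stem_k else []
        if not hits and not stems:
            return
        excess_now = sum(len(h.positions) - 1 for h in hits) + len(stems)
        if best_seen is None or excess_now < best_seen:
            best_seen, stall = excess_now, 0
        else:
            stall += 1
        if n_changes >= cap or stall >= stall_limit:
            raise UnresolvableRepeatError(
                f"context refinement stalled at violation count {excess_now} "
                f"after {n_changes} substitutions",
                window=(hits or stems)[0],
            )
        counts: dict[str, int] = defaultdict(int)
        for i in range(len(s) - k + 1):
            counts[s[i : i + k]] += 1
        stem_counts: dict[str, int] | None = None
        if stem_k:
            stem_counts = defaultdict(int)
            for i in range(len(s) - stem_k + 1):
                stem_counts[s[i : i + stem_k]] += 1

        # flagged windows: every repeat instance plus every hairpin arm
        windows = [(inst, k) for hit in hits for inst in hit.positions]
        windows += [(arm, stem_k) for st in stems
                    for arm in (st.arm1_start, st.arm2_start)]

        def move_delta(p, b):
            d = _repeat_excess_delta(chars, counts, p, b, k)
            if stem_counts is not None:
                d += _hairpin_pairs_delta(chars, stem_counts, p, b, stem_k)
            return d

        best, best_key = None, None
        improving = None
        all_moves: list[tuple[int, str]] = []
        seen: set[int] = set()
        for wstart, wlen in windows:
            for p in range(wstart, wstart + wlen):
                if p in seen:
                    continue
                seen.add(p)
                subs = _legal_substitutions(chars, mask, p, hexamer_set)
                all_moves.extend((p, b) for b in subs)
                if change_count.get(p, 0) >= _POSITION_FLIP_BUDGET:
                    continue
                for b in subs:
                    d = move_delta(p, b)
                    if d < 0:
                        improving = (p, b)
                        break
                    key = (d, change_count.get(p, 0), p, b)
                    if best_key is None or key < best_key:
                        best, best_key = (p, b), key
                if improving:
                    break
            if improving:
                break
        if improving is None and best_key is not None and best_key[0] >= 0:
            # No single substitution reduces the excess: the flank "codes"
            # distinguishing rigid windows are saturated and escaping the
            # bin needs a coordinated jump.  Try pairs of substitutions
            # inside one flagged window.
            pair = _find_improving_pair(chars, mask, counts, hits, k, hexamer_set)
            if pair is not None:
                for p, b in pair:
                    log.add(p, chars[p], b, reason)
                    chars[p] = b
                    n_changes += 1
                continue
        choice = improving or best
        if choice is None:
            # every in-budget move exhausted: random restart within the
            # flagged windows, or give up if nothing is substitutable at all
            if not all_moves or kicks >= max_kicks:
                first = (hits or stems)[0]
                raise UnresolvableRepeatError(
                    f"no legal substitution resolves {first}",
                    window=first,
                )
            burst = min(1 + kicks // 10, 4)  # escalate the perturbation
            for _ in range(burst):
                p, b = all_moves[int(rng.integers(len(all_moves)))]
                # earlier moves in the burst may have outdated this one
                if b not in _legal_substitutions(chars, mask, p, hexamer_set):
                    continue
                log.add(p, chars[p], b, reason)
                chars[p] = b
                n_changes += 1
            change_count.clear()
            kicks += 1
            continue
        p, b = choice
        log.add(p, chars[p], b, reason)
        chars[p] = b
        change_count[p] = change_count.get(p, 0) + 1
        n_changes += 1


def _hairpin_pairs_delta(chars, counts, p: int, b: str, k2: int) -> int:
    """Change in the number of inverted-repeat window pairs if chars[p] = b.

    Uses the identity #pairs = (S - D) / 2 with S = sum_w cnt[w]*cnt[rc(w)]
    (ordered matches, self-positions included) and D = sum over palindromic
    w of cnt[w]; only the k2 windows covering p change, so the deltas of S
    and D are accumulated while updating the census, then rolled back.
    """
    n = len(chars)
    lo, hi = max(0, p - k2 + 1), min(p, n - k2)
    dS = 0
    dD = 0
    touched: list[tuple[str, int]] = []
    for s in range(lo, hi + 1):
        u = "".join(chars[s : s + k2])
        ru = reverse_complement(u)
        if u == ru:
            dS -= 2 * counts[u] - 1
            dD -= 1
        else:
            dS -= 2 * counts[ru]
        counts[u] -= 1
        touched.append((u, 1))
    old = chars[p]
    chars[p] = b
    for s in range(lo, hi + 1):
        v = "".join(chars[s : s + k2])
        rv = reverse_complement(v)
        if v == rv:
            dS += 2 * counts[v] + 1
            dD += 1
        else:
            dS += 2 * counts[rv]
        counts[v] += 1
        touched.append((v, -1))
    chars[p] = old
    for kmer, d in touched:
        counts[kmer] += d
    return (dS - dD) // 2


def _apply_counted(chars, counts, p, b, k):
    """Substitute chars[p]=b keeping the k-mer census in step; returns undo info."""
    n = len(chars)
    lo, hi = max(0, p - k + 1), min(p, n - k)
    removed = []
    for s in range(lo, hi + 1):
        u = "".join(chars[s : s + k])
        counts[u] -= 1
        removed.append(u)
    old = chars[p]
    chars[p] = b
    added = []
    for s in range(lo, hi + 1):
        v = "".join(chars[s : s + k])
        counts[v] += 1
        added.append(v)
    return (p, old, removed, added)


def _undo_counted(chars, counts, undo, k):
    p, old, removed, added = undo
    n = len(chars)
    lo, hi = max(0, p - k + 1), min(p, n - k)
    for v in added:
        counts[v] -= 1
    chars[p] = old
    for u in removed:
        counts[u] += 1


def _find_improving_pair(chars, mask, counts, hits, k, hexamer_set,
                         max_families: int = 12):
    """Search pairs of substitutions within one flagged window.

    Single moves shuffle a rigid window between occupied 'bins'; a pair can
    jump to a free bin two edits away.  Returns ((p1, b1), (p2, b2)) with a
    strictly negative combined excess delta, or None.
    """
    for hit in hits[:max_families]:
        for inst in hit.positions:
            free = [p for p in range(inst, inst + k) if not mask[p]]
            for i, p1 in enumerate(free):
                subs1 = _legal_substitutions(chars, mask, p1, hexamer_set)
                for b1 in subs1:
                    d1 = _repeat_excess_delta(chars, counts, p1, b1, k)
                    undo = _apply_counted(chars, counts, p1, b1, k)
                    try:
                        for p2 in free[i + 1 :]:
                            for b2 in _legal_substitutions(
                                    chars, mask, p2, hexamer_set):
                                d2 = _repeat_excess_delta(
                                    chars, counts, p2, b2, k)
                                if d1 + d2 < 0:
                                    return ((p1, b1), (p2, b2))
                    finally:
                        _undo_counted(chars, counts, undo, k)
    return None


def _local_collision_score(chars, counts, q: int, k: int) -> int:
    """Summed multiplicity excess of the k-windows intersecting motif [q, q+6)."""
    n = len(chars)
    score = 0
    for s in range(max(0, q - k + 1), min(q + 5, n - k) + 1):
        c = counts["".join(chars[s : s + k])]
        if c > 1:
            score += c - 1
    return score


def _reassign_site_contexts(
    chars: list[str],
    mask: np.ndarray,
    motif_starts: list[int],
    k: int,
    hexamer_set: tuple[str, ...],
    rng: np.random.Generator,
    log: MutationLog | None = None,
    sweeps: int = 4,
    trials: int = 300,
) -> None:
    """Joint re-sampling of the free flank bases around colliding motifs.

    With dozens of identical protected hexamers, the k-mers straddling a
    motif are distinguished only by ~3 free flank bases on either side --
    a near-saturated code-assignment problem that no sequence of
    single-base moves solves.  For each site whose straddling windows
    collide globally, draw seeded random joint assignments of the free
    context bases and keep the best; repeat in sweeps until stable.
    """
    n = len(chars)
    for _ in range(sweeps):
        counts: dict[str, int] = defaultdict(int)
        s_all = "".join(chars)
        for i in range(n - k + 1):
            counts[s_all[i : i + k]] += 1
        improved = False
        for q in motif_starts:
            if _local_collision_score(chars, counts, q, k) == 0:
                continue
            free = [p for p in range(max(0, q - 3), min(n, q + 9))
                    if not mask[p]]
            if not free:
                continue
            best_score = _local_collision_score(chars, counts, q, k)
            best_assign = None
            for _t in range(trials):
                undos = []
                for p in free:
                    subs = _legal_substitutions(chars, mask, p, hexamer_set)
                    pool = subs + [chars[p]]
                    b = pool[int(rng.integers(len(pool)))]
                    if b != chars[p]:
                        undos.append(_apply_counted(chars, counts, p, b, k))
                score = _local_collision_score(chars, counts, q, k)
                assign = [chars[p] for p in free]
                for u in reversed(undos):
                    _undo_counted(chars, counts, u, k)
                if score < best_score:
                    best_score = score
                    best_assign = assign
                    if score == 0:
                        break
            if best_assign is not None:
                for p, b in zip(free, best_assign):
                    if chars[p] != b:
                        if log is not None:
                            log.add(p, chars[p], b, "hexamer_context")
                        _apply_counted(chars, counts, p, b, k)
                improved = True
        if not improved:
            return


def _optimize_motif_choice(
    chars: list[str],
    motif_starts: list[int],
    allowed_per_site: list[list[str]],
    k: int = 9,
    sweeps: int = 3,
) -> None:
    """Greedy per-site motif re-assignment minimizing direct-repeat excess.

    Two conversion sites with identical rigid (non-A/T) flank context would
    create a repeated k-mer that no later A<->T repair can break; picking the
    other motif at one of them removes the collision up front.  Deterministic;
    sweeps left-to-right until no swap improves.
    """

    def excess() -> int:
        counts: dict[str, int] = defaultdict(int)
        s = "".join(chars)
        for i in range(len(s) - k + 1):
            counts[s[i : i + k]] += 1
        return sum(c - 1 for c in counts.values() if c > 1)

    current = excess()
    for _ in range(sweeps):
        improved = False
        for q, allowed in zip(motif_starts, allowed_per_site):
            if len(allowed) < 2:
                continue
            present = "".join(chars[q : q + 6])
            best_motif, best_e = present, current
            for m in allowed:
                if m == present:
                    continue
                chars[q : q + 6] = m
                e = excess()
                if e < best_e:
                    best_motif, best_e = m, e
            chars[q : q + 6] = best_motif
            if best_e < current:
                current = best_e
                improved = True
        if not improved:
            break


# ---------------------------------------------------------------------------
# Validation and the full pipeline
# ---------------------------------------------------------------------------


def validate(seq: str, spec: DesignSpec) -> ConstraintReport:
    """Audit ``seq`` against every design principle by exact scanning."""
    _check_alphabet(seq)
    n = len(seq)
    dimers = find_cg_dimers(seq)
    n_cg = len(dimers)
    frac = 2 * n_cg / n if n else 0.0

    embedded = 0
    motif_offsets = [(m, m.index("CG")) for m in spec.hexamer_set]
    for d in dimers:
        for m, off in motif_offsets:
            s = d - off
            if s >= 0 and s + 6 <= n and seq[s : s + 6] == m:
                embedded += 1
                break

    repeats = find_direct_repeats(seq, spec.min_repeat_len)
    hairpins = find_inverted_repeats(seq, spec.min_stem_len)

    boundary: list[int] = []
    for i, d in enumerate(dimers):
        nxt = dimers[i + 1] if i + 1 < len(dimers) else None
        flank_start = d + 2
        flank_end = nxt if nxt is not None else n
        if flank_start < flank_end and seq[flank_start] == "C":
            boundary.append(flank_start)
        prev_end = dimers[i - 1] + 2 if i > 0 else 0
        if prev_end < d and seq[d - 1] == "G":
            boundary.append(d - 1)
    boundary = sorted(set(boundary))

    clean = not repeats and not hairpins and not boundary
    return ConstraintReport(
        length_nt=n,
        n_cg_dimers=n_cg,
        cg_fraction_realized=frac,
        cg_percent=round(frac * 100),
        n_hexamer_embedded=embedded,
        hexamer_pct_of_cg=100.0 * embedded / n_cg if n_cg else 0.0,
        repeats=repeats,
        hairpins=hairpins,
        boundary_violations=boundary,
        clean=clean,
    )


def _repair_until_clean(seq, mask, spec, log, seed: int = 0, max_rounds: int = 20):
    """Alternate repeat and hairpin elimination until both scanners are clean.

    A repeat fix can in principle open a hairpin and vice versa, so the two
    passes iterate jointly.  If the composition-preserving A<->T repeat pass
    gets cornered (e.g. a hairpin fix reopened a repeat whose window has no
    usable A/T), a full-alphabet context refinement clears the block before
    the next round rather than discarding the whole attempt.
    """
    for round_no in range(max_rounds):
        try:
            seq, rlog = eliminate_repeats(seq, mask, spec.min_repeat_len,
                                          spec.hexamer_set)
            log.extend(rlog)
        except UnresolvableRepeatError:
            chars = list(seq)
            _refine_context(chars, mask, spec.min_repeat_len, spec.hexamer_set,
                            log, reason="scaffold",
                            rng=np.random.default_rng(seed + 31 * round_no + 1),
                            stem_k=spec.min_stem_len)
            seq = "".join(chars)
        seq, hlog = eliminate_hairpins(seq, mask, spec.min_stem_len, spec.hexamer_set)
        log.extend(hlog)
        if not hlog.entries and not find_direct_repeats(seq, spec.min_repeat_len):
            return seq
    raise UnresolvableRepeatError("joint repeat/hairpin repair did not converge")


def design(spec: DesignSpec) -> DesignResult:
    """Run the full pipeline: scaffold, repair, optional hexamer embedding, audit.

    Deterministic given ``spec.seed``.  On an unresolvable repair the pipeline
    retries with a fresh scaffold (derived deterministically from the seed) up
    to ``spec.max_restarts`` times before surfacing the error.
    """
    last_err: Exception | None = None
    for restart in range(spec.max_restarts + 1):
        seed = spec.seed if restart == 0 else spec.seed + 7919 * restart
        attempt = dataclasses.replace(spec, seed=seed)
        try:
            seq, mask = scaffold_sequence(attempt)
            log = MutationLog()
            seq = _repair_until_clean(seq, mask, spec, log, seed=seed)
            if spec.hexamer_fraction > 0:
                seq, mask, hlog = insert_cpg_hexamers(
                    seq, mask, spec.hexamer_fraction, spec.hexamer_set,
                    seed=seed, in_place=spec.hexamer_in_place,
                    refine_k=spec.min_repeat_len,
                    refine_stem_k=spec.min_stem_len,
                )
                log.extend(hlog)
                seq = _repair_until_clean(seq, mask, spec, log, seed=seed)
            report = validate(seq, spec)
            if not report.clean:
                raise UnresolvableRepeatError(
                    "pipeline produced a non-clean sequence"
                )
            return DesignResult(seq, mask, report, log, spec, restarts_used=restart)
        except (UnresolvableRepeatError, UnresolvableHairpinError) as err:
            last_err = err
    assert last_err is not None
    raise last_err
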