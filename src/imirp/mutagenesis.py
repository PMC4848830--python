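"""Constrained mutagenesis of 6-nt core target sites.

A mutation site is the 6-nt stretch of the target sequence complementary
to miRNA positions 2-7 (the "core" of a seed match) — the region where a
couple of substitutions reliably abolish repression.  The user specifies
each site by its anchor: the 1-based position complementary to miRNA
position 7, i.e. the first base of the core; the site span is
``[anchor, anchor + 5]``.

Sites whose spans are separated by fewer than 7 intact nucleotides are
grouped into a single *mutationally independent region* and mutated as a
unit: the largest recognized seed site is 8 nt, so no newly created site
can span two regions separated by >= 7 unchanged bases.  Mutating one
region at a time keeps the combinatorial space tractable.

A mutation strategy fixes the set of replacement bases and the number of
changes per site (2-6).  By default the changes within a site must be
adjacent — a single run of exactly ``changes_per_site`` positions, each
set to an allowed base different from the original.  Adjacency narrows
the altered stretch, which both shrinks the search space and reduces the
surface on which illegitimate new sites can appear.
"""

from __future__ import annotations

import enum
import itertools
import logging
import random
from dataclasses import dataclass, field

from .alphabet import in_alphabet, is_dna, normalize_dna
from .errors import UsageError

logger = logging.getLogger(__name__)

CORE_LENGTH = 6
#: Minimum number of intact nucleotides between spans for independence:
#: an 8-nt window cannot cover parts of two spans separated by >= 7 nt.
MIN_INDEPENDENT_GAP = 7

#: Spaces at most this large are enumerated exhaustively; larger spaces
#: are sampled randomly with rejection and dedup.
DEFAULT_ENUMERATION_THRESHOLD = 10**6
#: Attempt cap for the sampling path before exhaustion becomes uncertain.
MAX_RANDOM_DRAWS = 10**7


@dataclass(frozen=True)
class MutationSite:
    """A user-specified 6-nt core span, anchored at its first base."""

    anchor: int

    @property
    def start(self) -> int:
        return self.anchor

    @property
    def end(self) -> int:
        return self.anchor + CORE_LENGTH - 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class IndependentRegion:
    region_id: int
    sites: tuple[MutationSite, ...]

    @property
    def start(self) -> int:
        return min(s.start for s in self.sites)

    @property
    def end(self) -> int:
        return max(s.end for s in self.sites)

    @property
    def span_positions(self) -> set[int]:
        """Union of member site spans (1-based sequence positions)."""
        out: set[int] = set()
        for s in self.sites:
            out.update(s.positions)
        return out

    def has_overlap(self) -> bool:
        sites = sorted(self.sites, key=lambda s: s.anchor)
        return any(
            b.start <= a.end for a, b in zip(sites, sites[1:])
        )


@dataclass(frozen=True)
class MutationStrategy:
    """Which bases may replace originals, and how many changes per site."""

    allowed_bases: frozenset[str] = frozenset("ACGT")
    changes_per_site: int = 2
    adjacency_required: bool = True

    def __post_init__(self) -> None:
        bases = frozenset(normalize_dna(b) for b in self.allowed_bases)
        if not bases or not bases <= frozenset("ACGT"):
            raise UsageError(
                f"allowed_bases must be a nonempty subset of A/C/G/T, got "
                f"{sorted(self.allowed_bases)}"
            )
        object.__setattr__(self, "allowed_bases", bases)
        if self.changes_per_site not in range(2, CORE_LENGTH + 1):
            raise UsageError(
                "changes_per_site must be between 2 and 6, got "
                f"{self.changes_per_site}"
            )


@dataclass(frozen=True)
class MutantCandidate:
    """One candidate mutation of a region, spliced into the full sequence."""

    region_id: int
    changed_positions: frozenset[int]
    full_sequence: str
    mutated_region_sequence: str


class StreamStatus(enum.Enum):
    EXHAUSTED = "exhausted"
    LIMIT_REACHED = "limit_reached"
    EXHAUSTION_UNCERTAIN = "exhaustion_uncertain"
    RUNNING = "running"


def partition_regions(
    sites: list[MutationSite], sequence_length: int | None = None
) -> list[IndependentRegion]:
    """Group mutation sites into mutationally independent regions.

    Sites are sorted by anchor; consecutive spans separated by fewer than
    :data:`MIN_INDEPENDENT_GAP` intact nucleotides (gap = next.start -
    prev.end - 1) merge into one region, so overlapping sites always
    share a region.  Region ids run 1..k in sequence order.  Duplicate
    anchors are collapsed with a warning; an empty site list is a usage
    error (at least one mutation site is required).
    """
    if not sites:
        raise UsageError("at least one mutation site must be specified")
    seen: set[int] = set()
    unique: list[MutationSite] = []
    for s in sorted(sites, key=lambda s: s.anchor):
        if s.anchor in seen:
            logger.warning("duplicate mutation-site anchor %d collapsed", s.anchor)
            continue
        seen.add(s.anchor)
        unique.append(s)
    for s in unique:
        if s.start < 1 or (sequence_length is not None and s.end > sequence_length):
            raise UsageError(
                f"mutation site anchored at {s.anchor} (span {s.start}-{s.end}) "
                f"falls outside the sequence"
            )
    regions: list[list[MutationSite]] = [[unique[0]]]
    for s in unique[1:]:
        prev_end = max(p.end for p in regions[-1])
        gap = s.start - prev_end - 1
        if gap < MIN_INDEPENDENT_GAP:
            regions[-1].append(s)
        else:
            regions.append([s])
    return [
        IndependentRegion(region_id=i, sites=tuple(group))
        for i, group in enumerate(regions, start=1)
    ]


def _site_runs(site: MutationSite, strategy: MutationStrategy) -> list[tuple[int, ...]]:
    """All admissible changed-position sets for one site (1-based)."""
    n = strategy.changes_per_site
    positions = list(site.positions)
    if strategy.adjacency_required:
        return [tuple(positions[i : i + n]) for i in range(CORE_LENGTH - n + 1)]
    return [tuple(c) for c in itertools.combinations(positions, n)]


def _position_choices(
    pos: int, strategy: MutationStrategy, sequence: str
) -> list[str]:
    """Replacement bases for one position: allowed bases minus the original."""
    original = normalize_dna(sequence[pos - 1])
    return sorted(strategy.allowed_bases - {original})


def _enumerate_region(
    region: IndependentRegion, strategy: MutationStrategy, sequence: str
):
    """Yield every distinct changed-map ``{position: new_base}`` (deduped).

    A candidate is the union of one admissible run per member site, with
    one replacement base per changed position; where runs of overlapping
    sites share positions the base assignments must agree.
    """
    per_site: list[list[dict[int, str]]] = []
    for site in region.sites:
        assignments: list[dict[int, str]] = []
        for run in _site_runs(site, strategy):
            choices = [_position_choices(p, strategy, sequence) for p in run]
            if any(not c for c in choices):
                continue
            for combo in itertools.product(*choices):
                assignments.append(dict(zip(run, combo)))
        per_site.append(assignments)
    seen: set[frozenset[tuple[int, str]]] = set()
    for combo in itertools.product(*per_site):
        merged: dict[int, str] = {}
        ok = True
        for assignment in combo:
            for pos, base in assignment.items():
                if merged.get(pos, base) != base:
                    ok = False
                    break
                merged[pos] = base
            if not ok:
                break
        if not ok:
            continue
        key = frozenset(merged.items())
        if key in seen:
            continue
        seen.add(key)
        yield merged


def count_mutation_space(
    region: IndependentRegion,
    strategy: MutationStrategy,
    input_sequence: str,
) -> int:
    """Exact number of distinct mutant sequences for one region.

    For non-overlapping sites this is the product over sites of the
    per-site count (sum over admissible runs of the product of per-position
    replacement choices): distinct runs always produce distinct sequences,
    because the changed-position set differs and every changed base
    differs from the original.  Overlapping sites fall back to explicit
    enumeration with dedup.  A count of 0 means the strategy is infeasible
    for this region (e.g. mutating to G only at positions already G).
    """
    if region.has_overlap():
        return sum(1 for _ in _enumerate_region(region, strategy, input_sequence))
    total = 1
    for site in region.sites:
        site_count = 0
        for run in _site_runs(site, strategy):
            run_count = 1
            for pos in run:
                run_count *= len(_position_choices(pos, strategy, input_sequence))
            site_count += run_count
        total *= site_count
    return total


def _build_candidate(
    region: IndependentRegion, sequence: str, changes: dict[int, str]
) -> MutantCandidate:
    dna = is_dna(sequence)
    chars = list(sequence)
    for pos, base in changes.items():
        chars[pos - 1] = in_alphabet(base, dna)
    full = "".join(chars)
    return MutantCandidate(
        region_id=region.region_id,
        changed_positions=frozenset(changes),
        full_sequence=full,
        mutated_region_sequence=full[region.start - 1 : region.end],
    )


class CandidateStream:
    """Iterator over distinct :class:`MutantCandidate`\\ s for one region.

    Generation is a random draw -> constraint filter -> dedup loop, with
    an exhaustive-enumeration fast path when the space is small (at most
    ``enumeration_threshold``).  After iteration finishes, ``status``
    reports whether the space was exhausted, the emission limit was
    reached, or (on the sampling path) exhaustion is uncertain because the
    attempt cap was hit.  ``attempts`` counts raw draws.  The stream is
    deterministic for a fixed ``rng_seed``.
    """

    def __init__(
        self,
        region: IndependentRegion,
        strategy: MutationStrategy,
        input_sequence: str,
        rng_seed: int,
        limit: int | None = None,
        enumeration_threshold: int = DEFAULT_ENUMERATION_THRESHOLD,
        max_attempts: int | None = None,
    ) -> None:
        self.region = region
        self.strategy = strategy
        self.sequence = input_sequence
        self.rng = random.Random(rng_seed)
        self.limit = limit
        self.space = count_mutation_space(region, strategy, input_sequence)
        self.enumeration_threshold = enumeration_threshold
        if max_attempts is None:
            max_attempts = min(100 * max(self.space, 1), MAX_RANDOM_DRAWS)
        self.max_attempts = max_attempts
        self.status = StreamStatus.RUNNING
        self.attempts = 0
        self.emitted = 0

    def __iter__(self):
        if self.space == 0:
            self.status = StreamStatus.EXHAUSTED
            return
        if self.space <= self.enumeration_threshold:
            yield from self._enumerated()
        else:
            yield from self._sampled()

    def _emit_limit_ok(self) -> bool:
        return self.limit is None or self.emitted < self.limit

    def _enumerated(self):
        all_changes = list(_enumerate_region(self.region, self.strategy, self.sequence))
        self.rng.shuffle(all_changes)
        for changes in all_changes:
            if not self._emit_limit_ok():
                self.status = StreamStatus.LIMIT_REACHED
                return
            self.attempts += 1
            self.emitted += 1
            yield _build_candidate(self.region, self.sequence, changes)
        self.status = StreamStatus.EXHAUSTED

    def _random_changes(self) -> dict[int, str] | None:
        merged: dict[int, str] = {}
        for site in self.region.sites:
            runs = _site_runs(site, self.strategy)
            run = runs[self.rng.randrange(len(runs))]
            for pos in run:
                choices = _position_choices(pos, self.strategy, self.sequence)
                if not choices:
                    return None
                base = choices[self.rng.randrange(len(choices))]
                if merged.get(pos, base) != base:
                    return None
                merged[pos] = base
        return merged

    def _sampled(self):
        seen: set[frozenset[tuple[int, str]]] = set()
        while self.attempts < self.max_attempts:
            if not self._emit_limit_ok():
                self.status = StreamStatus.LIMIT_REACHED
                return
            if self.emitted >= self.space:
                self.status = StreamStatus.EXHAUSTED
                return
            self.attempts += 1
            changes = self._random_changes()
            if changes is None:
                continue
            key = frozenset(changes.items())
            if key in seen:
                continue
            seen.add(key)
            self.emitted += 1
            yield _build_candidate(self.region, self.sequence, changes)
        if self.emitted >= self.space:
            self.status = StreamStatus.EXHAUSTED
        else:
            self.status = StreamStatus.EXHAUSTION_UNCERTAIN


def generate_candidates(
    region: IndependentRegion,
    strategy: MutationStrategy,
    input_sequence: str,
    rng_seed: int,
    limit: int | None = None,
    **kwargs,
) -> CandidateStream:
    """Stream distinct mutant candidates for one region (see CandidateStream)."""
    return CandidateStream(region, strategy, input_sequence, rng_seed, limit, **kwargs)


def validate_candidate(
    candidate: MutantCandidate,
    region: IndependentRegion,
    strategy: MutationStrategy,
    input_sequence: str,
) -> bool:
    """Declarative re-check of the candidate invariants.

    Independent of the generator's construction: verifies from first
    principles that (a) only positions inside member site spans changed,
    (b) every changed base is an allowed base differing from the original,
    and (c) there exists an assignment of one admissible run per site,
    fully changed, whose union is exactly the changed set.
    """
    seq, mut = input_sequence.upper(), candidate.full_sequence.upper()
    if len(mut) != len(seq):
        return False
    changed = {i + 1 for i in range(len(seq)) if seq[i] != mut[i]}
    if changed != set(candidate.changed_positions):
        return False
    if not changed <= region.span_positions:
        return False
    for pos in changed:
        new = normalize_dna(mut[pos - 1])
        if new not in strategy.allowed_bases:
            return False
        if new == normalize_dna(seq[pos - 1]):
            return False
    # Cover check: one fully-changed run per site, union == changed.
    per_site = [
        [run for run in _site_runs(site, strategy) if set(run) <= changed]
        for site in region.sites
    ]
    if any(not runs for runs in per_site):
        return False

    def cover(i: int, covered: frozenset[int]) -> bool:
        if i == len(per_site):
            return covered == changed
        return any(cover(i + 1, covered | set(run)) for run in per_site[i])

    return cover(0, frozenset())
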