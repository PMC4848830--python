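"""Synthetic miRNA databases and sequences with planted seed sites.

Every other module is testable without downloading anything: this module
generates random mature-miRNA records, plants seed matches of any site
type (optionally with one G:U wobble) into sequences, and builds
complete project fixtures — a background sequence screened to contain no
incidental matches, planted target sites at controlled spacings, and
optionally a "trap" miRNA whose seed matches one specific mutated
version of a planted site so that the validity engine must reject that
candidate.

Backgrounds are screened by running the seed predictor itself (rejection
sampling), not by alphabet tricks, so fixtures stay valid if site
definitions are ever extended.  All generation is deterministic per rng
seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .alphabet import RNA_COMPLEMENT, in_alphabet, is_dna
from .errors import FixtureError
from .mirna_db import MiRNA, to_fasta
from .mutagenesis import (
    CORE_LENGTH,
    IndependentRegion,
    MutationSite,
    MutationStrategy,
    _enumerate_region,
    _position_choices,
    _site_runs,
)
from .seed_predictor import (
    Pairing,
    PredictedSite,
    SiteType,
    bases_pair,
    classify_window,
    predict_sites,
)

#: Window positions that must pair for each site type (w8 of the A1 types
#: is a literal adenosine on the sequence, not a pair).
_PAIRED_POSITIONS: dict[SiteType, tuple[int, ...]] = {
    SiteType.EIGHT_MER: (1, 2, 3, 4, 5, 6, 7),
    SiteType.SEVEN_MER_M8: (1, 2, 3, 4, 5, 6, 7),
    SiteType.SEVEN_MER_A1: (2, 3, 4, 5, 6, 7),
    SiteType.SIX_MER: (2, 3, 4, 5, 6, 7),
    SiteType.OS_SIX_MER: (1, 2, 3, 4, 5, 6),
}

_A1_TYPES = (SiteType.EIGHT_MER, SiteType.SEVEN_MER_A1)


@dataclass(frozen=True)
class PlantSpec:
    """Instructions for planting one seed match.

    ``position`` is the 1-based window start (w1).  ``gu`` optionally
    names the window position (1-8) whose Watson-Crick pair should be
    replaced by a G:U wobble.
    """

    mirna: MiRNA
    site_type: SiteType
    position: int
    gu: int | None = None


def random_mirna_set(
    n: int,
    length_range: tuple[int, int] = (20, 24),
    species_code: str = "syn",
    rng_seed: int = 0,
) -> tuple[list[MiRNA], str]:
    """``n`` uniform-random mature miRNAs plus their FASTA text."""
    lo, hi = length_range
    if lo < 18:
        raise FixtureError(f"miRNA lengths must be >= 18, got range {length_range}")
    rng = random.Random(rng_seed)
    mirnas = [
        MiRNA(
            id=f"{species_code}-miR-synth-{k}",
            sequence="".join(rng.choice("ACGU") for _ in range(rng.randint(lo, hi))),
            accession=f"SYN{k:07d}",
        )
        for k in range(1, n + 1)
    ]
    return mirnas, to_fasta(mirnas)


def _mismatch_base(mir_base: str, dna: bool) -> str:
    """A sequence base that neither Watson-Crick- nor wobble-pairs mir_base."""
    for cand in "ACGT" if dna else "ACGU":
        if bases_pair(cand, mir_base, True, True) is Pairing.NONE:
            return cand
    raise FixtureError(f"no non-pairing base exists opposite {mir_base!r}")


def _wobble_partner(mir_base: str, dna: bool) -> str:
    if mir_base == "G":
        return "T" if dna else "U"
    if mir_base == "U":
        return "G"
    raise FixtureError(
        f"miRNA base {mir_base!r} admits no G:U wobble (needs G or U)"
    )


def plant_site(sequence: str, spec: PlantSpec) -> str:
    """Write the 8-nt window implied by ``spec`` into ``sequence``.

    Window position ``w_k`` receives the complement of miRNA position
    ``9 - k`` for the positions the site type requires to pair; w8 is set
    to A for the A1 types and to a non-A, non-pairing base otherwise.
    Positions the type requires to *mismatch* (w1 for 6mer/7mer-A1, w7
    for OS-6mer) receive a base that can pair neither canonically nor by
    wobble.  The result is verified by :func:`classify_window` before it
    is returned.
    """
    if not 1 <= spec.position <= len(sequence) - 7:
        raise FixtureError(
            f"window at {spec.position} does not fit in a "
            f"{len(sequence)}-nt sequence"
        )
    dna = is_dna(sequence)
    seed8 = spec.mirna.seed8
    window = [None] * 8
    paired = _PAIRED_POSITIONS[spec.site_type]
    for w in paired:
        window[w - 1] = in_alphabet(RNA_COMPLEMENT[seed8[8 - w]], dna)
    if spec.site_type in (SiteType.SIX_MER, SiteType.SEVEN_MER_A1):
        window[0] = _mismatch_base(seed8[7], dna)
    if spec.site_type is SiteType.OS_SIX_MER:
        window[6] = _mismatch_base(seed8[1], dna)
    if spec.site_type in _A1_TYPES:
        window[7] = "A"
    else:
        # any non-A base that cannot pair miRNA position 1 keeps the type exact
        window[7] = next(
            b for b in ("C", "G", "T" if dna else "U")
            if bases_pair(b, seed8[0], True, True) is Pairing.NONE
        )
    if spec.gu is not None:
        if spec.gu not in paired:
            raise FixtureError(
                f"G:U at window position {spec.gu} is outside the paired "
                f"stretch of a {spec.site_type.value} site"
            )
        window[spec.gu - 1] = _wobble_partner(seed8[8 - spec.gu], dna)
    planted = "".join(window)
    out = sequence[: spec.position - 1] + planted + sequence[spec.position + 7 :]
    cls = classify_window(planted, spec.mirna, gu_allowed=spec.gu is not None)
    if cls is None or cls.site_type is not spec.site_type or (
        (spec.gu is not None) != cls.gu_used
    ):
        raise FixtureError(
            f"planted window {planted!r} classifies as "
            f"{cls and cls.site_type} instead of {spec.site_type.value}"
        )
    return out


def _derive_target_mirna(
    sequence: str,
    window_start: int,
    site_type: SiteType,
    mirna_id: str,
    rng: random.Random,
) -> MiRNA:
    """Build a miRNA whose seed matches the given window as ``site_type``.

    The inverse of :func:`plant_site`: the seed is read off the sequence
    (complement of the paired window positions), so overlapping windows
    never impose conflicting constraints on the sequence itself.
    """
    win = sequence[window_start - 1 : window_start + 7].upper()
    seed = [None] * 8
    for w in _PAIRED_POSITIONS[site_type]:
        seed[8 - w] = RNA_COMPLEMENT[win[w - 1]]
    if site_type in (SiteType.SIX_MER, SiteType.SEVEN_MER_A1):
        # miRNA position 8 must not pair (even by wobble) with w1
        seed[7] = next(
            b for b in "ACGU" if bases_pair(win[0], b, True, True) is Pairing.NONE
        )
    if site_type is SiteType.OS_SIX_MER:
        seed[1] = next(
            b for b in "ACGU" if bases_pair(win[6], b, True, True) is Pairing.NONE
        )
    if seed[0] is None:  # miRNA position 1 is never a pairing position
        seed[0] = rng.choice("ACGU")
    tail = "".join(rng.choice("ACGU") for _ in range(14))
    return MiRNA(id=mirna_id, sequence="".join(seed) + tail)


@dataclass
class ProjectFixture:
    """A complete synthetic project with ground-truth expectations."""

    sequence: str
    anchors: list[int]
    mirnas: list[MiRNA]
    mirna_fasta: str
    species_code: str
    planted_sites: list[PredictedSite]
    expected_region_count: int
    gu_allowed: bool
    trap_mirna_id: str | None = None
    trap_changes: dict[int, str] | None = None
    trap_anchor: int | None = None


def _resolve_gaps(n_sites: int, spacing) -> list[int]:
    if isinstance(spacing, int):
        return [spacing] * (n_sites - 1)
    gaps = list(spacing)
    if len(gaps) != n_sites - 1:
        raise FixtureError(
            f"{n_sites} sites need {n_sites - 1} spacing gaps, got {len(gaps)}"
        )
    return gaps


_DEFAULT_TYPE_CYCLE = (
    SiteType.SEVEN_MER_M8,
    SiteType.EIGHT_MER,
    SiteType.SEVEN_MER_A1,
    SiteType.SIX_MER,
)


def make_project_fixture(
    n_sites: int,
    spacing,
    trap: bool = False,
    rng_seed: int = 0,
    site_types: list[SiteType] | None = None,
    n_decoys: int = 10,
    species_code: str = "syn",
    strategy: MutationStrategy | None = None,
    gu_allowed: bool = False,
    max_tries: int = 60,
) -> ProjectFixture:
    """Build a screened synthetic project.

    ``spacing`` is the number of intact nucleotides between consecutive
    6-nt site spans — one integer for uniform spacing or a list of
    ``n_sites - 1`` gaps; negative gaps overlap the spans.  The planted
    target miRNAs match their sites and nothing else; decoy miRNAs match
    nothing; the background is re-drawn until the seed predictor confirms
    both.  With ``trap=True`` an extra miRNA is constructed whose seed
    matches exactly one candidate mutation of the last planted site
    (the one obtained by changing the first ``changes_per_site``
    positions of its span to the alphabetically first allowed
    replacements), so a policy banning perfect 7mer-m8/8mer sites must
    reject that candidate and no other in that site's space.
    """
    gaps = _resolve_gaps(n_sites, spacing)
    if site_types is None:
        site_types = [
            _DEFAULT_TYPE_CYCLE[i % len(_DEFAULT_TYPE_CYCLE)] for i in range(n_sites)
        ]
    if strategy is None:
        strategy = MutationStrategy()
    rng = random.Random(rng_seed)

    anchors = [10]
    for g in gaps:
        anchors.append(anchors[-1] + CORE_LENGTH + g)
    if any(a < 2 for a in anchors) or anchors != sorted(anchors):
        raise FixtureError(f"spacing {gaps} produces invalid anchors {anchors}")
    length = anchors[-1] + CORE_LENGTH + 10
    expected_regions = 1 + sum(1 for g in gaps if g >= 7)

    for _ in range(max_tries):
        seq = list("".join(rng.choice("ACGT") for _ in range(length)))
        # Fix the literal w8 bases before deriving any seeds.
        for anchor, st in zip(anchors, site_types):
            w8 = anchor + 6  # window starts at anchor - 1
            seq[w8 - 1] = "A" if st in _A1_TYPES else (
                seq[w8 - 1] if seq[w8 - 1] != "A" else rng.choice("CGT")
            )
        sequence = "".join(seq)

        targets = [
            _derive_target_mirna(
                sequence, anchor - 1, st, f"{species_code}-miR-synth-t{i}", rng
            )
            for i, (anchor, st) in enumerate(zip(anchors, site_types), start=1)
        ]

        trap_mirna = None
        trap_changes: dict[int, str] | None = None
        if trap:
            trap_mirna, trap_changes = _build_trap(
                sequence, anchors[-1], strategy, species_code, rng
            )
            if trap_mirna is None:
                continue

        decoys = _screened_decoys(
            sequence, n_decoys, species_code, rng, gu_allowed
        )

        mirnas = targets + decoys + ([trap_mirna] if trap_mirna else [])
        expected = {
            (m.id, a - 1, st)
            for m, a, st in zip(targets, anchors, site_types)
        }
        found = predict_sites(sequence, mirnas, gu_allowed)
        if {(s.mirna_id, s.window_start, s.site_type) for s in found} != expected:
            continue
        if trap and not _trap_is_unique(
            sequence, anchors[-1], strategy, mirnas, trap_changes, gu_allowed
        ):
            continue
        return ProjectFixture(
            sequence=sequence,
            anchors=anchors,
            mirnas=mirnas,
            mirna_fasta=to_fasta(mirnas),
            species_code=species_code,
            planted_sites=sorted(found, key=lambda s: (s.window_start, s.mirna_id)),
            expected_region_count=expected_regions,
            gu_allowed=gu_allowed,
            trap_mirna_id=trap_mirna.id if trap_mirna else None,
            trap_changes=trap_changes,
            trap_anchor=anchors[-1] if trap else None,
        )
    raise FixtureError(
        f"could not construct a match-free fixture in {max_tries} tries; "
        "enlarge the sequence or reduce the miRNA count"
    )


def _screened_decoys(
    sequence: str,
    n: int,
    species_code: str,
    rng: random.Random,
    gu_allowed: bool,
) -> list[MiRNA]:
    """Decoy miRNAs individually re-drawn until they match nothing."""
    decoys: list[MiRNA] = []
    for k in range(1, n + 1):
        for _ in range(200):
            m = MiRNA(
                id=f"{species_code}-miR-synth-d{k}",
                sequence="".join(rng.choice("ACGU") for _ in range(22)),
            )
            if not predict_sites(sequence, [m], gu_allowed):
                decoys.append(m)
                break
        else:
            raise FixtureError(f"could not screen decoy {k} against the background")
    return decoys


def _trap_candidate_changes(
    anchor: int, strategy: MutationStrategy, sequence: str
) -> dict[int, str] | None:
    """The deterministic candidate the trap is aimed at: first run of the
    site, alphabetically first replacement at each position."""
    site = MutationSite(anchor=anchor)
    run = _site_runs(site, strategy)[0]
    changes: dict[int, str] = {}
    for pos in run:
        choices = _position_choices(pos, strategy, sequence)
        if not choices:
            return None
        changes[pos] = choices[0]
    return changes


def _build_trap(
    sequence: str,
    anchor: int,
    strategy: MutationStrategy,
    species_code: str,
    rng: random.Random,
) -> tuple[MiRNA | None, dict[int, str] | None]:
    """A miRNA whose seed 7mer-m8/8mer-matches one specific mutant window."""
    changes = _trap_candidate_changes(anchor, strategy, sequence)
    if changes is None:
        return None, None
    dna = is_dna(sequence)
    chars = list(sequence)
    for pos, base in changes.items():
        chars[pos - 1] = in_alphabet(base, dna)
    mutant = "".join(chars)
    trap = _derive_target_mirna(
        mutant, anchor - 1, SiteType.SEVEN_MER_M8,
        f"{species_code}-miR-synth-trap", rng,
    )
    if predict_sites(sequence, [trap], True):  # must match nothing in the input
        return None, None
    return trap, changes


def _trap_is_unique(
    sequence: str,
    anchor: int,
    strategy: MutationStrategy,
    mirnas: list[MiRNA],
    trap_changes: dict[int, str],
    gu_allowed: bool,
) -> bool:
    """Exactly one candidate of the trap site creates a banned perfect site."""
    from .validity import InvalidSitePolicy, diff_predictions, is_valid

    policy = InvalidSitePolicy.perfect()
    region = IndependentRegion(region_id=0, sites=(MutationSite(anchor=anchor),))
    input_sites = predict_sites(sequence, mirnas, gu_allowed)
    dna = is_dna(sequence)
    invalid: list[frozenset] = []
    for changes in _enumerate_region(region, strategy, sequence):
        chars = list(sequence)
        for pos, base in changes.items():
            chars[pos - 1] = in_alphabet(base, dna)
        mutant_sites = predict_sites("".join(chars), mirnas, gu_allowed)
        if not is_valid(diff_predictions(input_sites, mutant_sites), policy):
            invalid.append(frozenset(changes.items()))
    return invalid == [frozenset(trap_changes.items())]
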