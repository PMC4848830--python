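"""Illegitimate-site detection and the per-region search loop.

A mutation that disrupts one miRNA's seed site can accidentally create a
seed site for a *different* miRNA — an "illegitimate" site.  A site in
the mutant is illegitimate when no site for the same miRNA at the same
position exists in the input sequence; a site that merely changed type at
the same position (say, 7mer-m8 upgraded to 8mer) is not counted, because
the position was already under that miRNA's influence.  Substitution-only
mutagenesis preserves coordinates, so (miRNA id, window start) is a sound
identity key.

The user's invalid-site policy lists which (site type, wobble class)
combinations are unacceptable in a mutant.  A typical policy bans newly
created perfect 8mer / 7mer-m8 / 7mer-A1 sites while tolerating weaker
6mers and anything requiring a G:U wobble.

``process_region`` runs the search: generate candidate mutations for one
region, re-predict sites over the full mutant sequence, diff against the
input predictions, and keep candidates whose new sites all pass the
policy — stopping once five valid mutants are found or the mutation
space is exhausted.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from .mirna_db import MiRNA
from .mutagenesis import (
    CandidateStream,
    IndependentRegion,
    MutantCandidate,
    MutationStrategy,
    StreamStatus,
    generate_candidates,
)
from .seed_predictor import PredictedSite, SiteType, predict_sites

logger = logging.getLogger(__name__)

#: Search stops once this many valid mutants are found for a region; the
#: same cap bounds how many are displayed.
MAX_VALID_MUTANTS = 5


class WobbleClass(enum.Enum):
    PERFECT = "perfect"
    SINGLE_GU = "single-GU"


def wobble_class(site: PredictedSite) -> WobbleClass:
    return WobbleClass.SINGLE_GU if site.gu_used else WobbleClass.PERFECT


@dataclass(frozen=True)
class InvalidSitePolicy:
    """The set of (site type, wobble class) pairs banned in a mutant.

    Classes not listed are permitted: banning only perfect classes leaves
    single-G:U sites of the same types acceptable.
    """

    invalid_classes: frozenset[tuple[SiteType, WobbleClass]] = frozenset()

    @classmethod
    def perfect(cls, site_types: list[SiteType] | None = None) -> "InvalidSitePolicy":
        """Ban the given types (default: 8mer, 7mer-m8, 7mer-A1) as perfect sites."""
        if site_types is None:
            site_types = [SiteType.EIGHT_MER, SiteType.SEVEN_MER_M8,
                          SiteType.SEVEN_MER_A1]
        return cls(frozenset((t, WobbleClass.PERFECT) for t in site_types))

    @classmethod
    def from_names(
        cls, perfect_names: list[str], gu_names: list[str] = ()
    ) -> "InvalidSitePolicy":
        """Build a policy from site-type labels like "8mer", "7mer-m8"."""
        by_label = {t.value.lower(): t for t in SiteType}

        def lookup(name: str) -> SiteType:
            try:
                return by_label[name.strip().lower()]
            except KeyError:
                raise ValueError(
                    f"unknown site type {name!r}; expected one of "
                    f"{sorted(by_label)}"
                ) from None

        pairs = {(lookup(n), WobbleClass.PERFECT) for n in perfect_names}
        pairs |= {(lookup(n), WobbleClass.SINGLE_GU) for n in gu_names}
        return cls(frozenset(pairs))

    def bans(self, site: PredictedSite) -> bool:
        return (site.site_type, wobble_class(site)) in self.invalid_classes


class RegionStatus(enum.Enum):
    SOLVED = "solved"
    EXHAUSTED = "exhausted"
    EXHAUSTION_UNCERTAIN = "exhaustion_uncertain"


@dataclass(frozen=True)
class ValidMutant:
    candidate: MutantCandidate
    new_sites: tuple[PredictedSite, ...]


@dataclass
class RegionResult:
    region_id: int
    valid_mutants: list[ValidMutant] = field(default_factory=list)
    status: RegionStatus = RegionStatus.EXHAUSTED
    attempts: int = 0

    @property
    def displayed_mutants(self) -> list[ValidMutant]:
        return self.valid_mutants[:MAX_VALID_MUTANTS]


def diff_predictions(
    input_sites: list[PredictedSite],
    mutant_sites: list[PredictedSite],
    strict_type: bool = False,
) -> list[PredictedSite]:
    """Sites present in the mutant but absent from the input — the
    illegitimate set.

    The identity key is (miRNA id, window start); site type and wobble
    usage are carried along for policy checks but do not enter the key,
    so a type change at an already-occupied position is not illegitimate.
    With ``strict_type`` the site type joins the key and such changes are
    flagged too.
    """
    if strict_type:
        input_keys = {(s.mirna_id, s.window_start, s.site_type) for s in input_sites}
        return [
            s for s in mutant_sites
            if (s.mirna_id, s.window_start, s.site_type) not in input_keys
        ]
    input_keys = {s.key for s in input_sites}
    return [s for s in mutant_sites if s.key not in input_keys]


def is_valid(new_sites: list[PredictedSite], policy: InvalidSitePolicy) -> bool:
    """True iff no new site falls in a banned (type, wobble) class."""
    return not any(policy.bans(s) for s in new_sites)


def process_region(
    region: IndependentRegion,
    strategy: MutationStrategy,
    policy: InvalidSitePolicy,
    input_sequence: str,
    mirnas: list[MiRNA],
    gu_allowed: bool = False,
    rng_seed: int = 0,
    input_sites: list[PredictedSite] | None = None,
    strict_type_diff: bool = False,
    max_valid: int = MAX_VALID_MUTANTS,
) -> RegionResult:
    """Search one region for mutants that create no banned new sites.

    Candidates come from :func:`generate_candidates`; each one is
    re-predicted over the full mutant sequence (so windows straddling the
    region boundary are covered), diffed against the input predictions
    with the same ``gu_allowed`` setting, and accepted when every new
    site passes the policy.  The search stops after ``max_valid`` valid
    mutants or when the space is exhausted; deterministic per
    ``rng_seed``.
    """
    if input_sites is None:
        input_sites = predict_sites(input_sequence, mirnas, gu_allowed)
    stream: CandidateStream = generate_candidates(
        region, strategy, input_sequence, rng_seed
    )
    result = RegionResult(region_id=region.region_id)
    for candidate in stream:
        mutant_sites = predict_sites(candidate.full_sequence, mirnas, gu_allowed)
        new = diff_predictions(input_sites, mutant_sites, strict_type=strict_type_diff)
        if is_valid(new, policy):
            result.valid_mutants.append(ValidMutant(candidate, tuple(new)))
            if len(result.valid_mutants) >= max_valid:
                break
    result.attempts = stream.attempts
    if result.valid_mutants:
        result.status = RegionStatus.SOLVED
    elif stream.status is StreamStatus.EXHAUSTION_UNCERTAIN:
        result.status = RegionStatus.EXHAUSTION_UNCERTAIN
        logger.warning(
            "region %d: attempt cap hit with no valid mutant; exhaustion "
            "uncertain — consider a different mutation strategy",
            region.region_id,
        )
    else:
        result.status = RegionStatus.EXHAUSTED
        logger.warning(
            "region %d: mutation space exhausted with no valid mutant; "
            "reprocess with a different mutation strategy",
            region.region_id,
        )
    return result
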