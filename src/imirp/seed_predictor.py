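"""miRNA seed-match prediction by 8-nt sliding window.

The predictor slides an 8-nt window across the target sequence and, for
each miRNA, tests the window against the first eight nucleotides of the
miRNA 5' end (its seed).  Window position ``w_k`` (5'->3' on the mRNA)
pairs antiparallel with miRNA position ``9 - k``, so ``w1`` is opposite
miRNA position 8 and ``w8`` opposite miRNA position 1.

Five canonical site types are recognized:

========== =============================================================
6mer        w2..w7 complementary to miRNA positions 7..2
7mer-A1     6mer with an adenosine at w8 (opposite miRNA position 1)
7mer-m8     w1..w7 complementary to miRNA positions 8..2
8mer        7mer-m8 with an adenosine at w8
OS-6mer     offset 6mer: w1..w6 complementary to miRNA positions 8..3
========== =============================================================

The w8 adenosine test is a literal test on the sequence, not a pairing
test.  Optionally a single G:U wobble pair may substitute for one
Watson-Crick pair anywhere in the complementary stretch; the wobble
budget is one per window and is consumed greedily in evaluation order
(w1, then w2..w6, then w7).

Classification walks a fixed hierarchy of conditions: first w1 vs miRNA
position 8.  If paired, w2..w6 vs positions 7..3 are required (otherwise
no match), and w7 vs position 2 then separates OS-6mer (unpaired) from
8mer/7mer-m8 (paired, split on the w8 adenosine).  If w1 is unpaired,
w2..w7 vs positions 7..2 are required and the w8 adenosine splits
7mer-A1 from 6mer.  Each window start is evaluated independently, and at
most one site is reported per (miRNA, window).

This is deliberately an over-predicting, complementarity-only scan: no
thermodynamics, accessibility or conservation scoring.  Its role here is
to flag any sequence motif with the *potential* to be a functional site.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

from .alphabet import validate_sequence
from .errors import ContractError
from .mirna_db import MiRNA

logger = logging.getLogger(__name__)

WINDOW = 8


class SiteType(enum.Enum):
    EIGHT_MER = "8mer"
    SEVEN_MER_M8 = "7mer-m8"
    SEVEN_MER_A1 = "7mer-A1"
    SIX_MER = "6mer"
    OS_SIX_MER = "OS-6mer"

    def __str__(self) -> str:  # CSV / CLI rendering
        return self.value


# Window positions whose identity the classification of each type depends
# on: the paired stretch plus, for A1 types, the literal w8 adenosine.
TYPE_REQUIRED_WINDOW_POSITIONS: dict[SiteType, tuple[int, ...]] = {
    SiteType.EIGHT_MER: (1, 2, 3, 4, 5, 6, 7, 8),
    SiteType.SEVEN_MER_M8: (1, 2, 3, 4, 5, 6, 7),
    SiteType.SEVEN_MER_A1: (2, 3, 4, 5, 6, 7, 8),
    SiteType.SIX_MER: (2, 3, 4, 5, 6, 7),
    SiteType.OS_SIX_MER: (1, 2, 3, 4, 5, 6),
}


class Pairing(enum.Enum):
    WATSON_CRICK = "WC"
    GU = "GU"
    NONE = "none"


_WC_PAIRS = {
    ("A", "U"), ("A", "T"), ("U", "A"), ("T", "A"),
    ("C", "G"), ("G", "C"),
}


def bases_pair(
    seq_base: str, mir_base: str, gu_allowed: bool, gu_available: bool
) -> Pairing:
    """Pairing outcome between one sequence base and one miRNA base.

    Watson-Crick: A:U(T), U(T):A, C:G, G:C.  A G:U wobble (sequence T/U
    against miRNA G, or sequence G against miRNA U) counts only while the
    caller both allows wobbles and still has the one-per-window budget
    available.  Anything else — including non-ACGTU characters — never
    pairs.
    """
    s, m = seq_base.upper(), mir_base.upper()
    if (s, m) in _WC_PAIRS:
        return Pairing.WATSON_CRICK
    if gu_allowed and gu_available:
        if s in ("T", "U") and m == "G":
            return Pairing.GU
        if s == "G" and m in ("T", "U"):
            return Pairing.GU
    return Pairing.NONE


@dataclass(frozen=True)
class Classification:
    site_type: SiteType
    gu_used: bool
    gu_window_position: int | None


@dataclass(frozen=True)
class PredictedSite:
    """One predicted seed match; ``window_start`` is 1-based inclusive."""

    window_start: int
    mirna_id: str
    site_type: SiteType
    gu_used: bool = False
    gu_window_position: int | None = None

    @property
    def window_end(self) -> int:
        return self.window_start + WINDOW - 1

    @property
    def key(self) -> tuple[str, int]:
        """Identity used for input-vs-mutant diffing: (miRNA, position)."""
        return (self.mirna_id, self.window_start)


def classify_window(
    window8: str, mirna: MiRNA, gu_allowed: bool = False
) -> Classification | None:
    """Classify one 8-nt window against one miRNA seed, or ``None``.

    Implements the condition hierarchy described in the module docstring,
    consuming at most one G:U wobble across the window, greedily in
    evaluation order.  Raises :class:`ContractError` if the window is not
    exactly 8 nt.
    """
    if len(window8) != WINDOW:
        raise ContractError(
            f"classify_window requires an 8-nt window, got {len(window8)} nt"
        )
    return _classify(window8.upper(), mirna.seed8, gu_allowed)


def _classify(win: str, seed8: str, gu_allowed: bool) -> Classification | None:
    gu_pos: int | None = None

    def paired(w: int, m: int) -> bool:
        nonlocal gu_pos
        out = bases_pair(win[w - 1], seed8[m - 1], gu_allowed, gu_pos is None)
        if out is Pairing.GU:
            gu_pos = w
        return out is not Pairing.NONE

    if paired(1, 8):
        # 8mer / 7mer-m8 / OS-6mer branch: w2..w6 vs p7..p3 are mandatory.
        for k in range(2, 7):
            if not paired(k, 9 - k):
                return None
        if paired(7, 2):
            t = SiteType.EIGHT_MER if win[7] == "A" else SiteType.SEVEN_MER_M8
        else:
            t = SiteType.OS_SIX_MER
    else:
        # 7mer-A1 / 6mer branch: w2..w7 vs p7..p2 are mandatory.
        for k in range(2, 8):
            if not paired(k, 9 - k):
                return None
        t = SiteType.SEVEN_MER_A1 if win[7] == "A" else SiteType.SIX_MER
    return Classification(t, gu_pos is not None, gu_pos)


def predict_sites(
    sequence: str, mirnas: list[MiRNA], gu_allowed: bool = False
) -> list[PredictedSite]:
    """Scan ``sequence`` with every miRNA and return all seed matches.

    Every complete 8-nt window (starts 1..L-7) is classified against every
    miRNA independently; output is sorted by (window_start, mirna_id) and
    is deterministic.  Sequences shorter than 8 nt yield an empty result
    with a warning.  Invalid characters raise :class:`SequenceError`
    naming the first offending position.
    """
    seq = validate_sequence(sequence)
    if len(seq) < WINDOW:
        logger.warning(
            "sequence length %d < %d: no complete window, no predictions",
            len(seq), WINDOW,
        )
        return []
    sites: list[PredictedSite] = []
    for m in mirnas:
        seed8 = m.seed8
        for start in range(1, len(seq) - WINDOW + 2):
            cls = _classify(seq[start - 1 : start - 1 + WINDOW], seed8, gu_allowed)
            if cls is not None:
                sites.append(
                    PredictedSite(
                        window_start=start,
                        mirna_id=m.id,
                        site_type=cls.site_type,
                        gu_used=cls.gu_used,
                        gu_window_position=cls.gu_window_position,
                    )
                )
    sites.sort(key=lambda s: (s.window_start, s.mirna_id))
    return sites
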