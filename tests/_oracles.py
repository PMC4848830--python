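"""Independent oracles used by the tests.

These re-derive expected results from the site-type definitions and by
brute-force enumeration, deliberately sharing no code with the package's
own classification hierarchy or candidate generator.
"""

from __future__ import annotations

import itertools

from imirp import SiteType

_WC = {
    ("A", "U"), ("A", "T"), ("U", "A"), ("T", "A"),
    ("C", "G"), ("G", "C"),
}


def _wc(seq_base: str, mir_base: str) -> bool:
    return (seq_base, mir_base) in _WC


def oracle_classify(window8: str, seed8: str) -> SiteType | None:
    """Declarative site-type classification, Watson-Crick only.

    Tests each definition directly (w_k pairs miRNA position 9-k) and
    applies precedence 8mer > 7mer-m8 > OS-6mer and 7mer-A1 > 6mer.
    """
    win = window8.upper()

    def pairs(window_positions) -> bool:
        return all(_wc(win[w - 1], seed8[8 - w]) for w in window_positions)

    m8_stretch = pairs(range(1, 8))        # w1..w7 vs p8..p2
    if m8_stretch and win[7] == "A":
        return SiteType.EIGHT_MER
    if m8_stretch:
        return SiteType.SEVEN_MER_M8
    if pairs(range(1, 7)):                  # w1..w6 vs p8..p3
        return SiteType.OS_SIX_MER
    core = pairs(range(2, 8))               # w2..w7 vs p7..p2
    if core and win[7] == "A":
        return SiteType.SEVEN_MER_A1
    if core:
        return SiteType.SIX_MER
    return None


def oracle_site_count(
    site_seq6: str, allowed: set[str], n_changes: int, adjacency: bool = True
) -> int:
    """Brute-force per-site candidate count over all 4^6 span variants.

    A variant qualifies when it differs from the original at exactly
    ``n_changes`` positions, those positions form one adjacent run (when
    required), and every changed base is in ``allowed``.
    """
    original = site_seq6.upper().replace("U", "T")
    count = 0
    for variant in itertools.product("ACGT", repeat=6):
        diff = [i for i in range(6) if variant[i] != original[i]]
        if len(diff) != n_changes:
            continue
        if adjacency and diff != list(range(diff[0], diff[0] + n_changes)):
            continue
        if any(variant[i] not in allowed for i in diff):
            continue
        count += 1
    return count


def oracle_validate_candidate(
    input_sequence: str,
    mutant_sequence: str,
    site_anchors: list[int],
    allowed: set[str],
    n_changes: int,
    adjacency: bool = True,
) -> bool:
    """Re-check a candidate from the diff alone (no generator internals).

    Derives the changed positions by comparing sequences, checks base
    legality, then searches for one fully-changed admissible run per
    site whose union covers every changed position.
    """
    inp = input_sequence.upper().replace("U", "T")
    mut = mutant_sequence.upper().replace("U", "T")
    if len(inp) != len(mut):
        return False
    changed = {i + 1 for i in range(len(inp)) if inp[i] != mut[i]}
    spans = {p for a in site_anchors for p in range(a, a + 6)}
    if not changed <= spans:
        return False
    if any(mut[p - 1] not in allowed for p in changed):
        return False

    def runs(anchor: int) -> list[frozenset[int]]:
        positions = range(anchor, anchor + 6)
        if adjacency:
            cands = [frozenset(range(a, a + n_changes))
                     for a in range(anchor, anchor + 6 - n_changes + 1)]
        else:
            cands = [frozenset(c)
                     for c in itertools.combinations(positions, n_changes)]
        return [r for r in cands if r <= changed]

    per_site = [runs(a) for a in site_anchors]
    if any(not rs for rs in per_site):
        return False
    for combo in itertools.product(*per_site):
        if set().union(*combo) == changed:
            return True
    return False
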