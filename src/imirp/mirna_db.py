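"""Mature-miRNA database parsing (miRBase mature.fa dialect).

mature.fa is a FASTA file of mature miRNA sequences whose headers look like

    >hsa-miR-7-5p MIMAT0000252 Homo sapiens miR-7-5p

The first whitespace-delimited token is the miRNA id, the second (when
present) the miRBase accession.  The three-letter species code is the first
dash-delimited token of the id (miRBase convention), which is more robust
than parsing the free-text species name at the end of the header.

Sequences are normalized to uppercase RNA (T -> U).  Records shorter than
8 nt are skipped with a warning: they cannot form an 8-nt seed and so can
never produce a seed match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alphabet import VALID_BASES, normalize_rna
from .errors import FastaParseError

logger = logging.getLogger(__name__)

MIN_MIRNA_LENGTH = 8


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA record.

    ``seed8`` is the first eight nucleotides of the sequence — the 5' end
    of the miRNA (positions 1-8), the region that dominates target
    recognition and the only part the seed predictor looks at.
    """

    id: str
    sequence: str
    accession: str | None = None
    species_code: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.species_code:
            object.__setattr__(
                self, "species_code", self.id.split("-", 1)[0].lower()
            )

    @property
    def seed8(self) -> str:
        return self.sequence[:8]


def parse_mature_fasta(text: str) -> list[MiRNA]:
    """Parse mature.fa-dialect FASTA text into a list of :class:`MiRNA`.

    Multi-line sequences are allowed.  Records with a sequence shorter
    than 8 nt are skipped (logged).  Duplicate ids are kept, with a
    warning: prediction keys include the position, so duplicates only
    duplicate reported sites.

    Raises
    ------
    FastaParseError
        If a sequence line precedes any header (names the line number) or
        a sequence contains characters outside A/C/G/T/U case-insensitive
        (names the record id).
    """
    records: list[MiRNA] = []
    header: tuple[str, str | None] | None = None
    chunks: list[str] = []
    seen_ids: set[str] = set()

    def flush() -> None:
        if header is None:
            return
        rid, acc = header
        seq = normalize_rna("".join(chunks))
        bad = set(seq) - VALID_BASES
        if bad:
            raise FastaParseError(
                f"record {rid!r}: invalid sequence character(s) "
                f"{''.join(sorted(bad))!r}"
            )
        if len(seq) < MIN_MIRNA_LENGTH:
            logger.warning(
                "skipping %r: sequence length %d < %d (cannot seed-match)",
                rid, len(seq), MIN_MIRNA_LENGTH,
            )
            return
        if rid in seen_ids:
            logger.warning("duplicate miRNA id %r: keeping both records", rid)
        seen_ids.add(rid)
        records.append(MiRNA(id=rid, sequence=seq, accession=acc))

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            tokens = line[1:].split()
            if not tokens:
                raise FastaParseError(f"line {lineno}: empty FASTA header")
            header = (tokens[0], tokens[1] if len(tokens) > 1 else None)
            chunks = []
        else:
            if header is None:
                raise FastaParseError(
                    f"line {lineno}: sequence data before any FASTA header"
                )
            chunks.append(line)
    flush()
    return records


def filter_species(mirnas: list[MiRNA], species_code: str) -> list[MiRNA]:
    """Retain the records of one species (case-insensitive), in order."""
    code = species_code.lower()
    kept = [m for m in mirnas if m.species_code == code]
    if not kept:
        logger.warning(
            "no miRNAs for species %r: predictions will be empty", species_code
        )
    return kept


def to_fasta(mirnas: list[MiRNA]) -> str:
    """Serialize records back to mature.fa-dialect FASTA."""
    lines = []
    for m in mirnas:
        head = f">{m.id}" + (f" {m.accession}" if m.accession else "")
        lines.append(head)
        lines.append(m.sequence)
    return "\n".join(lines) + ("\n" if lines else "")
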