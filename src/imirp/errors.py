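"""Exception hierarchy for imirp."""


class ImirpError(Exception):
    """Base class for all imirp errors."""


class FastaParseError(ImirpError):
    """Malformed FASTA input (names the offending line or record)."""


class SequenceError(ImirpError):
    """Invalid nucleotide sequence (names the first offending position)."""


class ContractError(ImirpError):
    """A function was called outside its contract (programming error)."""


class UsageError(ImirpError):
    """Invalid user-supplied configuration (bad anchors, empty site list...)."""


class FixtureError(ImirpError):
    """A synthetic fixture could not be constructed under its constraints."""


class AssemblyError(ImirpError):
    """Final assembly failed its global re-verification (internal consistency)."""


class ExhaustedError(ImirpError):
    """The constrained mutation space contains no (further) candidates."""
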