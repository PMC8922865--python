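"""Exception hierarchy shared across the package.

Each error class carries the process exit code the command-line
interface maps it to, so library and CLI behaviour stay in sync.
"""


class RankCutoffError(Exception):
    """Base class for all rankcutoff errors."""

    exit_code = 1


class InputFormatError(RankCutoffError):
    """The input table is malformed (missing columns, bad delimiter...)."""

    exit_code = 2


class ValidationError(RankCutoffError):
    """A record or parameter violates a documented precondition."""

    exit_code = 2


class DegenerateProfileError(RankCutoffError):
    """The ranked profile is flat: the chord is horizontal and no
    bending point exists."""

    exit_code = 3


class SizeError(RankCutoffError):
    """Too few records, or a requested list size exceeds what is
    available."""

    exit_code = 4
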