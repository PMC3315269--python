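"""Error taxonomy shared across the package.

Configuration problems (bad component mapping, malformed config file) and
input-data problems (unreadable tables, non-numeric cells) are distinct so
the command line can map them to distinct exit codes (2 and 3).
"""

from __future__ import annotations

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


class CiScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CiScreenError):
    """Invalid configuration; carries every violation found, not just the first."""

    def __init__(self, problems: list[str] | str):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class InputDataError(CiScreenError):
    """Malformed or unusable input data (fail-fast, names the location)."""
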