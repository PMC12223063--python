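"""Exception hierarchy shared across the pipeline."""

from __future__ import annotations


class PestloadError(Exception):
    """Base class for all package-specific errors."""


class UnitError(PestloadError):
    """Unrecognized or incompatible measurement unit."""


class ConsistencyError(PestloadError):
    """Records that must agree (year, threshold rule, ...) do not."""


class CoverageError(PestloadError):
    """Populated grid cells without a matching exposure record."""

    def __init__(self, missing_cells):
        self.missing_cells = list(missing_cells)
        super().__init__(
            f"{len(self.missing_cells)} populated cell(s) have no exposure record: "
            f"{self.missing_cells[:10]}{'...' if len(self.missing_cells) > 10 else ''}"
        )


class InsufficientDataError(PestloadError):
    """Too few observations for the requested classification or summary."""


class GenerationError(PestloadError):
    """A synthetic-landscape target could not be met within bounded retries."""
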