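"""Exception hierarchy shared across the package."""


class SentifuseError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SentifuseError):
    """A required field or column is missing from an input file."""


class DuplicateIdError(SentifuseError):
    """Record ids are not unique within a corpus."""

    def __init__(self, duplicates):
        self.duplicates = list(duplicates)
        super().__init__(f"duplicate record ids: {self.duplicates}")


class InputError(SentifuseError):
    """A caller-supplied value violates an operation's precondition."""


class TotalConflictError(SentifuseError):
    """Dempster combination degenerated: (almost) all product mass fell on
    empty intersections, so the normalization denominator vanished."""

    def __init__(self, sources=(), step=None):
        self.sources = tuple(sources)
        self.step = step
        where = f" at pairwise step {step}" if step is not None else ""
        who = f" (sources: {', '.join(self.sources)})" if self.sources else ""
        super().__init__(f"total conflict in Dempster combination{where}{who}")


class ZeroCellError(SentifuseError):
    """A 2x2 table cell is zero, so the odds ratio or its Wald interval is
    undefined; pass haldane=True for an explicit 0.5 correction."""


class BackendUnavailableError(SentifuseError):
    """The external classifier adapter has no model attached; use a mock
    classifier (kind='mock') or supply a predict function."""
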