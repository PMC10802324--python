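"""Exception types shared across batchray modules."""


class BatchrayError(Exception):
    """Base class for all batchray errors."""


class MatrixParseError(BatchrayError, ValueError):
    """A matrix or annotation file could not be parsed (malformed header,
    duplicate identifiers, non-numeric cell...)."""


class EmptyMatrixError(BatchrayError, ValueError):
    """A filtering or exclusion step removed every feature."""


class DegenerateDataError(BatchrayError, ValueError):
    """The data carry no usable variation for the requested computation."""


class ZeroWithinDispersionError(DegenerateDataError):
    """Within-group dispersion is exactly zero while group centroids differ,
    so the dispersion separability criterion is unbounded.

    Carries the between-group dispersion as :attr:`db`.
    """

    def __init__(self, db: float):
        self.db = float(db)
        super().__init__(
            f"zero within-group dispersion with non-zero between-group "
            f"dispersion (Db={db!r}); DSC is unbounded"
        )
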