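"""Exception hierarchy.

Every error raised by the library derives from :class:`PanelrocError` so
callers (and the CLI) can map failures to exit codes without string matching.
"""


class PanelrocError(Exception):
    """Base class for all panelroc errors."""


class FormatError(PanelrocError):
    """Malformed input file: missing required columns, bad header, etc."""


class ParseError(FormatError):
    """A signal cell could not be parsed as a number; names row and column."""


class ClassLabelError(PanelrocError):
    """Class column has the wrong number of levels, or labels are missing
    where an operation requires them."""


class GeneSubsetError(PanelrocError):
    """Requested gene subset does not intersect the matrix's genes."""


class DegenerateScaleError(PanelrocError):
    """Min-max rescaling is undefined because the matrix is constant."""


class MarkerMismatchError(PanelrocError):
    """A model's member markers are absent from the table being scored."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"markers absent from table: {', '.join(self.missing)}")


class ThresholdNotFoundError(PanelrocError):
    """No candidate threshold satisfies the min_SE/min_SP constraints."""


class DegenerateCutoffError(PanelrocError):
    """All scores identical: no probability cutoff can split them."""


class DensityError(PanelrocError):
    """A class's pooled signals are degenerate (all equal), so no kernel
    density can be estimated for it."""


class ArgumentError(PanelrocError):
    """Invalid argument combination (e.g. combithr out of range)."""


class SpecError(PanelrocError):
    """Invalid synthetic-data specification."""
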