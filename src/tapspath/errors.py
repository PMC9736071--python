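"""Exception hierarchy shared across the toolkit.

All toolkit failures derive from :class:`TapsError`; ``exit_code`` is what the
command-line layer returns for that class of failure (1 = usage, 2 = runtime).
"""


class TapsError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 2


class InputError(TapsError, ValueError):
    """Invalid argument values or incompatible inputs."""

    exit_code = 1


class DegenerateAlignmentError(InputError):
    """Alignment set too small or collinear: rotation is not unique."""


class DegeneratePathError(InputError):
    """Path with coincident consecutive nodes (zero inter-node gap)."""


class DivergedSimulationError(TapsError):
    """Non-finite energy/gradient encountered during integration."""

    def __init__(self, message, step=None):
        super().__init__(message)
        self.step = step


class NonConvergenceError(TapsError):
    """Iterative procedure failed to reach its tolerance."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class ResolutionConflictError(TapsError):
    """Insertion/deletion bounds oscillate and cannot both be satisfied."""


class DisconnectedHistogramError(TapsError):
    """Umbrella histograms leave an unsampled gap; WHAM constants are gauge-split."""


class EmptySelectionError(InputError):
    """An atom selection matched nothing."""


class ParseError(TapsError):
    """Malformed input file."""

    def __init__(self, message, line=None):
        super().__init__(message)
        self.line = line
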