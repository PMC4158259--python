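"""Exception hierarchy for endograph.

Every failure mode the pipeline can signal maps to one class here so callers
(and the CLI) can distinguish usage errors from geometric/registration
failures that are expected on difficult data.
"""


class EndographError(Exception):
    """Base class for all endograph errors."""


class InvalidInputError(EndographError, ValueError):
    """Malformed argument: wrong shape, wrong length, empty chain, bad path."""


class InvalidParameterError(EndographError, ValueError):
    """Parameter outside its documented range (e.g. lambda not in (0,1))."""


class InsufficientCorrespondencesError(EndographError):
    """Fewer point correspondences than the minimal sample requires."""


class DegenerateGeometryError(EndographError):
    """Collinear/rank-deficient correspondences or a singular transform."""


class InsufficientOverlapError(EndographError):
    """Warped overlap below the minimum fraction; the pair cannot be scored."""


class UndefinedSimilarityError(EndographError):
    """Similarity requested between two frames with no features at all."""


class NoFeaturesError(EndographError):
    """Every sampled frame pair had empty feature sets."""


class NonconvergenceError(EndographError):
    """Iterative threshold search exceeded its iteration budget.

    Carries the final search state on the ``state`` attribute.
    """

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


class NoMatchError(EndographError):
    """Query image could not be grouped to any node in any subgraph."""


class NoPathwayError(EndographError):
    """Destination node unreachable from the source node."""


class InvalidPathwayError(EndographError):
    """A consecutive node pair in a pathway has no stored edge transform."""


class InsufficientTrajectoryError(EndographError):
    """Fewer than two tracked positions for a marker trajectory."""


class PlacementError(EndographError):
    """Could not place non-overlapping phantom markers within retry budget."""


class DegenerateSequenceError(EndographError):
    """Synthetic motion pushed the texture (almost) fully out of frame."""


class GraphFormatError(EndographError):
    """Graph/marker/tracking file violates the documented schema.

    ``field`` names the offending field path when known.
    """

    def __init__(self, message, field=None):
        super().__init__(message)
        self.field = field
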