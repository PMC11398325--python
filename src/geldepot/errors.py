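"""Exception hierarchy used across the pipeline.

All errors derive from :class:`GelDepotError` so callers can catch pipeline
failures without swallowing unrelated exceptions. I/O problems and data
validation problems are distinguished, and an empty segmentation gets its
own type because downstream stages treat "nothing above threshold" very
differently from "the file was unreadable".
"""


class GelDepotError(Exception):
    """Base class for all pipeline errors."""


class FormatError(GelDepotError):
    """A file could not be read or written in the expected format."""


class ValidationError(GelDepotError, ValueError):
    """An in-memory object or parameter violates a documented invariant."""


class EmptySegmentationError(GelDepotError):
    """Thresholding produced no voxels (distinct from an I/O failure)."""


class EmptyMeshError(GelDepotError):
    """A surface mesh with no faces was produced or supplied."""
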