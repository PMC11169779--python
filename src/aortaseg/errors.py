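"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class GeometryError(ValidationError):
    """Two volumes that must share a grid geometry do not."""


class EmptyStructureError(RuntimeError):
    """An anatomical structure expected to be present has no voxels.

    Raised e.g. when a segmentation stage emits an empty mask; the
    pipeline records this per case instead of aborting the cohort.
    """
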