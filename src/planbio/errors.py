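"""Exception types shared across the package."""


class CongruenceError(ValueError):
    """A structure mask and dose grid do not share the same voxel lattice."""


class EmptyStructureError(ValueError):
    """A structure mask selects no voxels."""


class SchemaError(ValueError):
    """A fractionation scheme or config block is missing required fields."""


class CombinationError(ValueError):
    """Two DVHs cannot be combined (different structures or volumes)."""


class ConvergenceError(RuntimeError):
    """An equivalence solver failed to find a positive-dose solution."""


class GeometryError(ValueError):
    """A phantom specification cannot be realised on the requested grid."""
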