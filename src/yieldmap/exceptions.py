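"""Exception hierarchy shared across the package."""


class YieldmapError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(YieldmapError):
    """Input data violates a documented invariant (e.g. yield outside [0, 100])."""


class ConfigurationError(YieldmapError):
    """A configuration value (column map, descriptor kind, grid size, ...) is invalid."""


class FormatError(YieldmapError):
    """A file does not conform to its declared format (CSV schema, XYZ count line)."""


class AssemblyError(YieldmapError):
    """Product assembly failed: no free azole C2-H or no amine N-H."""


class SingularGeometryError(YieldmapError):
    """Two nuclei coincide; distance-based descriptors are undefined."""


class DescriptorAvailabilityError(YieldmapError):
    """A requested descriptor needs per-record inputs (geometry, QM row) that are missing."""


class SchemaError(YieldmapError):
    """Feature columns of a query do not match the columns a model was trained on."""


class CapabilityError(YieldmapError):
    """The requested operation is not supported by this model family or fingerprint kind."""


class ProtocolError(YieldmapError):
    """A cross-validation protocol cannot be carried out (e.g. no valid training set)."""


class PlantingError(YieldmapError):
    """A planted bit is absent from every molecule of the synthetic library."""


class CapacityError(YieldmapError):
    """The fragment grammar cannot produce the requested number of distinct compounds."""


class AmbiguityError(YieldmapError):
    """A structure edit matched zero or multiple sites."""


class DepictionError(YieldmapError):
    """A 2D depiction could not be generated for rendering."""
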