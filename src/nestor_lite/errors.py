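"""Exception types shared across the package."""


class NestorError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(NestorError, ValueError):
    """A numeric argument violates its precondition (e.g. residues_per_bead < 1)."""


class TopologyError(NestorError, ValueError):
    """An assembly topology is internally inconsistent (e.g. duplicate chain ids)."""


class CrosslinkMappingError(NestorError, KeyError):
    """A crosslink refers to a residue that no bead of the topology covers."""


class GenerationError(NestorError, RuntimeError):
    """Synthetic-data generation cannot satisfy its constraints."""


class RunFailureError(NestorError, RuntimeError):
    """A nested-sampling run could not even be initialized; the caller may relaunch."""
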