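"""Exception hierarchy shared across the package."""


class WnsError(Exception):
    """Base class for all errors raised by this package."""


class StructureParseError(WnsError):
    """A PDB/PDBQT record could not be parsed or violates an invariant."""


class TrajectoryFormatError(WnsError):
    """A multi-model trajectory file is internally inconsistent."""


class ParameterLookupError(WnsError, KeyError):
    """An atom type has no entry in the parameter table."""


class DockingError(WnsError):
    """The docking backend cannot operate on the given inputs."""


class DynamicsError(WnsError):
    """The toy dynamics integrator detected an unstable configuration."""
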