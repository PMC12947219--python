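"""Exception hierarchy."""


class PymfccError(Exception):
    """Base class for package errors."""


class StructureFormatError(PymfccError):
    """The input file could not be parsed under the requested standard."""


class SelectionError(PymfccError):
    """A ligand or residue selector did not resolve to anything."""


class ParameterizationError(PymfccError):
    """A charge/LJ parameter lookup failed or a charge sum is inconsistent."""


class GeometryError(PymfccError):
    """Degenerate geometry (coincident or near-singular atom pairs)."""


class FragmentationError(PymfccError):
    """Invalid fragmentation request (e.g. capping the ligand)."""


class EnergyParseError(PymfccError):
    """No usable energy could be recovered from a QM engine log."""


class GenerationError(PymfccError):
    """The synthetic-complex generator could not satisfy its constraints."""
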