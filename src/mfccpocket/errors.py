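"""Exception hierarchy shared across the package."""


class MfccPocketError(Exception):
    """Base class for all package errors."""


class FormatError(MfccPocketError):
    """A structure file does not parse under the named standard."""


class SelectionError(MfccPocketError):
    """A ligand/residue selector matched zero or several groups."""


class ParameterizationError(MfccPocketError):
    """A parameter table does not cover every atom."""


class ConnectivityError(MfccPocketError):
    """Backbone atoms needed for cleavage or capping are missing."""


class FragmentationError(MfccPocketError):
    """A residue cannot be fragmented (ligand, lone residue, bridged side chain)."""


class ClashError(MfccPocketError):
    """Two atoms closer than the hard-sphere floor of the pair energy."""


class BackendError(MfccPocketError):
    """An energy backend failed on a fragment system."""


class AwaitingEnergiesError(BackendError):
    """QM inputs were emitted but no runner is configured to produce energies."""


class QmParseError(MfccPocketError):
    """No final-energy line matched in a QM output file."""


class ChargeAssignmentError(MfccPocketError):
    """Summed partial charges are too far from an integer to round safely."""


class GenerationError(MfccPocketError):
    """A synthetic fixture request is infeasible."""
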