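"""Exception hierarchy shared across the package."""


class TsmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TsmrError, ValueError):
    """A user-supplied setting (column map, threshold, option) is invalid."""


class InputError(TsmrError, ValueError):
    """An input file or record list cannot be used (missing, empty, unparseable)."""


class AnalysisError(TsmrError, RuntimeError):
    """An analysis step cannot proceed on the given data.

    Typical causes: no overlapping instruments after harmonization, or fewer
    instruments than an estimator's minimum.
    """


class InsufficientInstrumentsError(AnalysisError):
    """An estimator or diagnostic needs more SNPs than the harmonized set holds."""
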