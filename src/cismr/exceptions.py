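"""Exception hierarchy for the cismr package."""


class CisMRError(Exception):
    """Base class for all cismr errors."""


class ConfigurationError(CisMRError):
    """Invalid configuration, e.g. a mandatory column missing from a column map."""


class EmptyInputError(CisMRError):
    """An input table contained no valid rows."""


class IncompatibleSourcesError(CisMRError):
    """Datasets that must share a trait scale or name do not."""


class MonomorphicVariantError(CisMRError):
    """A reference-panel variant has zero dosage variance."""


class MissingLDError(CisMRError):
    """A variant required by an LD-aware step is absent from the LD matrix."""


class NoOverlapError(CisMRError):
    """Exposure and outcome datasets share no variants."""


class InsufficientInstrumentsError(CisMRError):
    """Fewer variants than the estimator's minimum."""


class CollinearInstrumentsError(CisMRError):
    """Degenerate design, e.g. all instrument strengths equal after orientation."""


class IllConditionedError(CisMRError):
    """A matrix inversion failed; typically fixed by choosing a smaller kappa."""


class ScaleMismatchError(CisMRError):
    """A presentation direction incompatible with the exposure's measurement scale."""
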