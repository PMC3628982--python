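"""Exception hierarchy shared across the pipeline stages."""


class IrisGradientError(Exception):
    """Base class for all pipeline errors."""


class CatalogError(IrisGradientError):
    """Malformed transcript catalog (duplicate ids, bad lengths, bad GO ids)."""


class CatalogMismatchError(IrisGradientError):
    """Counts refer to transcripts absent from the catalog."""


class InvalidLibraryError(IrisGradientError):
    """Library with non-positive total mapped reads or inconsistent counts."""


class CutoffEstimationError(IrisGradientError):
    """Detection-threshold estimation failed (e.g. empty null-transcript set)."""


class SchemaError(IrisGradientError):
    """Input table missing required columns or conditions."""


class OntologyError(IrisGradientError):
    """GO graph unusable for annotation propagation (e.g. cyclic)."""


class StandardCurveError(IrisGradientError):
    """qPCR standard curve cannot be fit or is not invertible."""


class SampleSizeError(IrisGradientError):
    """Too few replicates for the requested statistical test."""


class DesignError(IrisGradientError):
    """Factorial design unbalanced or incomplete."""


class SimulationSpecError(IrisGradientError):
    """Inconsistent synthetic-data specification."""


class ParseError(IrisGradientError):
    """Malformed input file; carries the offending path and line if known."""

    def __init__(self, message: str, path=None, line=None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
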