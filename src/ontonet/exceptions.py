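"""Exception hierarchy for ontonet."""


class OntonetError(Exception):
    """Base class for all ontonet errors."""


class GmtParseError(OntonetError):
    """Raised when a GMT gene-set file is malformed."""


class GeneListError(OntonetError):
    """Raised when a gene-list CSV is malformed or empty."""


class ConfigError(OntonetError):
    """Raised when a run configuration is inconsistent."""
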