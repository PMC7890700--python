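"""Exception hierarchy for starmsa."""


class StarMsaError(Exception):
    """Base class for all starmsa errors."""


class SequenceValidationError(StarMsaError, ValueError):
    """Raised when input sequences fail the legality check."""


class ContractViolationError(StarMsaError, ValueError):
    """Raised when an operation is called outside its contract,
    e.g. scoring an unfilled DP matrix or merging a foreign alignment."""
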