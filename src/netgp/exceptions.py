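"""Exception hierarchy for netgp."""


class NetgpError(Exception):
    """Base class for all netgp errors."""


class ValidationError(NetgpError, ValueError):
    """Invalid argument, configuration or data shape."""


class EmptyPanelError(NetgpError):
    """Quality control removed every marker."""


class ParseError(NetgpError):
    """Malformed input file; message carries the offending line number."""


class TrainingDivergedError(NetgpError):
    """Training objective became non-finite (learning rate too large)."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(
            f"training diverged at iteration {iteration}: "
            "objective is non-finite; reduce the learning rate"
        )


class UndefinedCorrelationError(NetgpError):
    """Pearson correlation requested for a constant vector."""
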