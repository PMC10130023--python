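"""Package exception hierarchy."""


class FocalspikeError(Exception):
    """Base class for focalspike errors."""


class SchemaError(FocalspikeError):
    """An input file does not match the expected schema (channels, columns, tokens)."""


class CapacityError(FocalspikeError):
    """A sampling/packing request cannot be satisfied by the available data."""


class ContractError(FocalspikeError):
    """An inter-module contract (shape, sampling rate, class count) is violated."""


class DivergenceError(FocalspikeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at training epoch {epoch}")
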