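"""Exception hierarchy shared across the package."""


class TdrlKitError(Exception):
    """Base class for all tdrlkit errors."""


class InputFormatError(TdrlKitError):
    """Malformed gene-order or constraint input (CLI exit code 3)."""


class GeneSetMismatchError(TdrlKitError):
    """Two orders (or an order and a constraint) use different gene sets."""


class DistanceExceededError(TdrlKitError):
    """The two orders differ by more than one TDRL (CLI exit code 2)."""

    def __init__(self, d_forward: int, d_backward: int):
        self.d_forward = d_forward
        self.d_backward = d_backward
        super().__init__(
            "orders differ by more than one TDRL "
            f"(forward distance {d_forward}, backward distance {d_backward})"
        )
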