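"""Exception hierarchy for tugseg."""


class TugsegError(Exception):
    """Base class for all tugseg errors."""


class ValidationError(TugsegError):
    """A domain object or configuration violates an invariant."""


class MissingChannelError(TugsegError):
    """A required (site, quantity) channel is absent from a recording."""

    def __init__(self, site: str, quantity: str, context: str = "") -> None:
        self.site = site
        self.quantity = quantity
        msg = f"missing {site} {quantity}"
        if context:
            msg += f" (required for {context})"
        super().__init__(msg)

    @classmethod
    def many(cls, pairs: list[tuple[str, str]], context: str = "") -> "MissingChannelError":
        err = cls(*pairs[0], context=context)
        if len(pairs) > 1:
            extra = ", ".join(f"{s} {q}" for s, q in pairs[1:])
            err.args = (f"{err.args[0]}; also missing: {extra}",)
        return err


class DegenerateSignalError(TugsegError):
    """A signal is unusable for the requested operation (e.g. all zeros)."""


class AmbiguousEventError(TugsegError):
    """An activity event cannot be classified (zero derivative at the peak)."""


class SegmentationError(TugsegError):
    """Trial segmentation failed (missing events or non-monotone transitions)."""
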