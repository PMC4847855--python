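"""Exception hierarchy shared across vennkit modules."""


class VennError(Exception):
    """Base class for all vennkit errors."""


class CapabilityError(VennError):
    """A request exceeds a documented capability bound (e.g. set count limits)."""


class InputError(VennError):
    """Malformed or inconsistent user input (bad labels, duplicate names, ...)."""
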