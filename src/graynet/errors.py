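"""Exception hierarchy shared by all graynet modules."""


class GraynetError(Exception):
    """Base class for all graynet errors."""


class InputError(GraynetError):
    """Invalid user input (bad file, bad parameter, violated precondition)."""

    exit_code = 2


class NumericalError(GraynetError):
    """A numerical procedure failed irrecoverably."""

    exit_code = 3
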