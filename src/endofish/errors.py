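"""Exception hierarchy shared across the package."""


class EndofishError(Exception):
    """Base class for all package errors."""


class InvalidAlphabetError(EndofishError, ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""

    def __init__(self, char: str, position: int, context: str = ""):
        self.char = char
        self.position = position
        msg = f"invalid nucleotide {char!r} at position {position}"
        if context:
            msg += f" in {context}"
        super().__init__(msg)


class InvalidParameterError(EndofishError, ValueError):
    """A configuration or function parameter violates its contract."""


class InvalidInputError(EndofishError, ValueError):
    """An input object (sequence set, image, group) violates a precondition."""


class GenerationError(EndofishError, RuntimeError):
    """A synthetic fixture could not be generated within bounded attempts."""


class UndefinedDensityError(EndofishError, ZeroDivisionError):
    """Density requested over a mask with zero area."""
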