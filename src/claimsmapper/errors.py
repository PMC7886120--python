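"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration value is missing, malformed, or inconsistent."""


class ClaimsFormatError(ValueError):
    """A claims input file violates the expected format (bad row/column)."""


class UndefinedIndexError(ArithmeticError):
    """A rule index (confidence or lift) has a zero denominator.

    Raised instead of emitting NaN so that callers must decide how to
    treat rules whose antecedent or consequent never occurs.
    """
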