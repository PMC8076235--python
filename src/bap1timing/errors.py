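"""Exception types shared across the pipeline."""


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class UnfittedCurveError(RuntimeError):
    """Raised when a curve that failed to fit is evaluated or inverted."""


class SchemaError(InvalidInputError):
    """Raised when tabular input violates the expected schema.

    Carries an itemized list of offending rows/columns in ``problems``.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "input validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )
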