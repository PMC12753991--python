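"""Exception types shared across the toolkit."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class DependencyError(RuntimeError):
    """A pipeline stage was requested without its upstream artifact."""

    def __init__(self, stage: str, missing: str):
        self.stage = stage
        self.missing = missing
        super().__init__(f"stage '{stage}' requires upstream artifact '{missing}'")


class SeparationError(RuntimeError):
    """Complete separation in a logistic regression, naming the culprit."""

    def __init__(self, variable: str):
        self.variable = variable
        super().__init__(
            f"complete separation: variable '{variable}' perfectly predicts the outcome"
        )
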