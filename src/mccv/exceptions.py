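"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class MethodNotFoundError(KeyError):
    """A classifier name does not resolve in the registry."""

    def __init__(self, name: str, available: list[str]):
        self.name = name
        self.available = sorted(available)
        super().__init__(
            f"unknown classifier {name!r}; available: {', '.join(self.available)}"
        )

    def __str__(self) -> str:  # KeyError.__str__ adds quotes around args[0]
        return self.args[0]


class DegenerateSplitError(RuntimeError):
    """A training set contains a single outcome class, so no classifier can be fit."""


class ConfigError(ValueError):
    """A configuration file is malformed or inconsistent."""
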