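"""Exception hierarchy shared across the package."""


class NutricontrolError(Exception):
    """Base class for all package errors."""


class DomainError(NutricontrolError, ValueError):
    """An input violates a physical or mathematical precondition."""


class ValidationError(NutricontrolError, ValueError):
    """A composite object violates one of its invariants."""


class UnknownFoodError(NutricontrolError, LookupError):
    """A food_id does not resolve against the food table in use."""

    def __init__(self, food_id: str):
        super().__init__(f"unknown food_id: {food_id!r}")
        self.food_id = food_id


class ConflictError(NutricontrolError):
    """A log event conflicts with one already recorded (e.g. double confirmation)."""


class KlmParseError(NutricontrolError, ValueError):
    """An operator string does not match the KLM grammar."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position
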