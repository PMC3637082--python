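"""Exception hierarchy.

Three branches map onto the CLI's distinct exit codes: validation problems
(bad records, bad rule files), I/O problems, and domain-rule violations
(state-machine or gate errors during care).
"""


class MatcareError(Exception):
    """Base class for all package errors."""


class ValidationError(MatcareError):
    """Input or record fails an invariant; carries a list of issues."""

    def __init__(self, message, issues=None):
        super().__init__(message)
        self.issues = list(issues or [])


class RuleSetError(ValidationError):
    """Rule file could not be loaded: unknown code, bad key, cyclic include."""


class StoreIOError(MatcareError):
    """Reading or writing the patient store failed; carries the path."""

    def __init__(self, message, path=None):
        super().__init__(message)
        self.path = path


class DomainError(MatcareError):
    """A clinically-meaningful operation was attempted out of order."""


class DuplicatePatientId(DomainError):
    pass


class VisitOrderError(DomainError):
    pass


class ItemStateError(DomainError):
    pass


class PendingCriticalItems(DomainError):
    def __init__(self, item_ids):
        super().__init__(
            "cannot finalize visit; critical items still pending: "
            + ", ".join(sorted(item_ids))
        )
        self.item_ids = tuple(sorted(item_ids))


class DischargeTooEarly(DomainError):
    def __init__(self, remaining_hours):
        super().__init__(
            f"discharge gate: {remaining_hours:.2f} h of the postpartum "
            "observation window remain"
        )
        self.remaining_hours = remaining_hours


class UnknownKeyError(MatcareError):
    """Unknown translation key; suggests the nearest known keys."""

    def __init__(self, key, suggestions):
        msg = f"unknown message key {key!r}"
        if suggestions:
            msg += "; nearest known keys: " + ", ".join(suggestions)
        super().__init__(msg)
        self.key = key
        self.suggestions = tuple(suggestions)
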