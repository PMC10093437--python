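"""Exception hierarchy.

Two failure families are distinguished because they map to distinct CLI exit
codes: bad user input (exit 2) and a classifier that violates the fit/predict
contract (exit 3).
"""


class ECValidateError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(ECValidateError):
    """A dataset, configuration value or operation precondition is invalid."""

    exit_code = 2


class ClassifierContractError(ECValidateError):
    """The supplied classifier does not honour the fit/predict contract."""

    exit_code = 3
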