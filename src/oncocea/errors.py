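"""Exception types shared across the package."""


class OncoceaError(Exception):
    """Base class for package errors."""


class ValidationError(OncoceaError, ValueError):
    """Input violates a model invariant.

    Carries the full list of findings so a caller can report every problem
    at once rather than the first one hit.
    """

    def __init__(self, findings):
        self.findings = list(findings)
        msg = "; ".join(f"{f.severity}: {f.message}" for f in self.findings)
        super().__init__(f"invalid inputs ({len(self.findings)} finding(s)): {msg}")


class FormatError(OncoceaError, ValueError):
    """A structured parameter file could not be parsed."""


class DegenerateDataError(OncoceaError, ValueError):
    """Time-to-event sample too small or carrying no events to fit."""


class FitConvergenceError(OncoceaError, RuntimeError):
    """Likelihood optimiser failed to converge; carries the last iterate."""

    def __init__(self, message, last_params=None, last_loglik=None):
        super().__init__(message)
        self.last_params = last_params
        self.last_loglik = last_loglik


class PsaSpecError(OncoceaError, ValueError):
    """A probabilistic-sensitivity distribution cannot be moment-matched."""
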