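"""Exception hierarchy shared across the package."""


class KneeflexError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(KneeflexError, ValueError):
    """An input value violates a physical or numerical precondition."""


class SolverError(KneeflexError, RuntimeError):
    """The fiber-tendon equilibrium solver could not bracket a root."""


class CalibrationError(KneeflexError, RuntimeError):
    """Tendon slack length calibration failed to reach its target."""


class ConfigError(KneeflexError, ValueError):
    """A model/scenario configuration is missing or inconsistent."""


class ProtocolError(KneeflexError, ValueError):
    """A dynamometry trial set violates the measurement protocol."""


class ScenarioError(KneeflexError, RuntimeError):
    """A simulation scenario failed; carries muscle/pose context."""
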