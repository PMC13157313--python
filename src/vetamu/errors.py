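"""Exception hierarchy.

Every lookup or precondition failure raises an explicit, typed error;
nothing defaults silently.
"""


class VetamuError(Exception):
    """Base class for all package errors."""


class UnknownSubstanceError(VetamuError, KeyError):
    """An active ingredient has no entry in the relevant conversion table."""


class UnitError(VetamuError, ValueError):
    """A strength or quantity carries an unsupported or inconsistent unit."""


class AuditError(VetamuError, ValueError):
    """Audit visit sequence violates the estimator's preconditions."""


class InfeasibleFixtureError(VetamuError, ValueError):
    """A requested inspection fixture cannot exist (union/column-sum bounds)."""


class ConfigError(VetamuError, ValueError):
    """Invalid run or simulation configuration."""
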