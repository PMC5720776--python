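"""Exception hierarchy shared by all stages.

Each error carries the CLI exit code of the stage that raises it, so the
command-line front end can map failures onto stable process exit codes
(0 ok, 2 configuration, 3 gating failure, 4 solver failure).
"""


class SelfGateError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(SelfGateError):
    """Invalid acquisition, phantom, or run configuration."""

    exit_code = 2


class FormatError(SelfGateError):
    """Raw container or array layout does not match the expected format."""

    exit_code = 2


class GatingFailureError(SelfGateError):
    """Motion-signal extraction could not find usable gating information."""

    exit_code = 3


class SolverError(SelfGateError):
    """Iterative reconstruction diverged or failed."""

    exit_code = 4
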