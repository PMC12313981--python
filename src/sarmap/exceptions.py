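"""Exception hierarchy for sarmap."""


class SarmapError(Exception):
    """Base class for all sarmap errors."""


class ConfigurationError(SarmapError):
    """Invalid design, panel, layout, or scheme configuration."""


class MissingChannelError(SarmapError):
    """A required channel is absent from an event table or file.

    Parameters
    ----------
    missing : list of str
        Channel names that could not be resolved.
    """

    def __init__(self, missing, message=None):
        self.missing = list(missing)
        super().__init__(message or f"missing channels: {', '.join(self.missing)}")


class ScaleError(SarmapError):
    """Operation applied on the wrong intensity scale (raw vs arcsinh)."""


class FitConvergenceError(SarmapError):
    """Dose-response optimisation failed to converge from every start.

    Carries the per-start diagnostics so the failure can be inspected
    rather than silently extrapolated.
    """

    def __init__(self, message, diagnostics=None):
        self.diagnostics = diagnostics
        super().__init__(message)
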