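"""Exception hierarchy for ruralfv."""


class RuralFVError(Exception):
    """Base class for all package errors."""


class ConfigError(RuralFVError):
    """A configuration value violates an invariant (bad marginal, count, area...)."""


class NoFVSourceError(RuralFVError):
    """The community contains no healthy (fruit/vegetable-selling) outlet."""


class DomainError(RuralFVError, ValueError):
    """An argument lies outside its mathematical domain (negative distance...)."""


class SimulationSpecError(RuralFVError):
    """A simulation specification is internally inconsistent."""
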