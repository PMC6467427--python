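"""Exception hierarchy."""


class SpecificationError(ValueError):
    """A model, design, or problem specification is inconsistent."""


class SimulationError(RuntimeError):
    """The reference ODE integrator failed.

    Carries the experiment id and the time at which integration broke down.
    """

    def __init__(self, message, experiment_id=None, time_h=None):
        super().__init__(message)
        self.experiment_id = experiment_id
        self.time_h = time_h


class SolverError(RuntimeError):
    """The NLP backend failed or returned an unusable status."""
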