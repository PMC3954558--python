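import pytest

from asmgrowth import ModelParams, StimulusSpec, make_schedule, simulate


@pytest.fixture
def default_params():
    return ModelParams()


@pytest.fixture
def scenario():
    """Run a standard-scenario simulation from the healthy initial state.

    Parameters are the normalised ratios of the growth survey: event
    magnitude a/mu1, frequency omega/lambda_p and resolution rate IR.
    """

    def _run(a_rel, omega_rel, ir, mode="periodic", seed=None, sample_dt=None, horizon=300.0):
        params = ModelParams.from_ratios(ir=ir)
        spec = StimulusSpec(
            mode=mode,
            magnitude=a_rel * params.mu1,
            omega=omega_rel * params.lambda_p,
            horizon=horizon,
            seed=seed,
        )
        return simulate(params, make_schedule(spec), horizon=horizon, sample_dt=sample_dt)

    return _run
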