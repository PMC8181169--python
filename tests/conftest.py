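import pytest

from biohybrid.bees import BeeController, BeeModel, BeeParams, BeeSchedule
from biohybrid.core import SimulationClock, run_replicate


@pytest.fixture
def quiet_bee_params() -> BeeParams:
    """Noise-free bee parameters with temperatures pinned (no passive decay),
    so resting times are exactly constant in fixed-target runs."""
    return BeeParams(
        sigma_bees=0.0, sigma_beecasu=0.0, lambda_passive_cooling=0.0
    )


def run_fixed_bee(params, t_target_r, t_target_l, t_end, seed=0, **schedule_kwargs):
    """Convenience: fixed-target bee run starting pre-heated at the targets."""
    schedule = BeeSchedule(
        t_target_r=t_target_r, t_target_l=t_target_l, **schedule_kwargs
    )
    model = BeeModel(params=params, schedule=schedule, controller=BeeController())
    return run_replicate(model, SimulationClock(1.0, t_end), seed)
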