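"""Shared fixtures: desk-scale parameter sets and cached simulation runs."""

import pytest

from agarcolony import SimulationParams, engine


def desk_params(**kw) -> SimulationParams:
    """Standard physical parameters on a desk-scale computational box."""
    defaults = dict(L=100.0, a=48.0, b=32.0, uniform_spacing=4.0,
                    grid_mode="uniform")
    defaults.update(kw)
    return SimulationParams(**defaults)


@pytest.fixture
def params() -> SimulationParams:
    return desk_params(seed=0)


def _run_until_buckled(seed: int):
    p = desk_params(seed=seed)

    def stop(state):
        N = state.count
        hf = state.height_field()
        cx = float(state.r[:N, 0].mean())
        cy = float(state.r[:N, 1].mean())
        return hf.height_at(cx, cy) > 2.0 * p.w0

    return engine.run(p, t_max=8.5, snapshot_interval=0.25,
                      stop_when=stop, validate=True)


@pytest.fixture(scope="session")
def standard_runs():
    """Three standard-parameter colony runs (seeds 1-3) from a single cell,
    each stopped shortly after the buckling transition.  Shared by the
    growth-rate, buckling-onset, and monolayer-persistence checks."""
    return {seed: _run_until_buckled(seed) for seed in (1, 2, 3)}
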