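import numpy as np
import pytest

from cnflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ToyModelParams,
    make_toy_model,
)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model(ToyModelParams())


@pytest.fixture()
def forced_toy(toy_model):
    """Toy model with equality-forced HCO3/NO3 uptake, all demands open."""

    def _force(u_c, u_n):
        m = toy_model.copy()
        m.set_bounds("EX_hco3_e", -u_c, -u_c)
        m.set_bounds("EX_no3_e", -u_n, -u_n)
        return m

    return _force


@pytest.fixture()
def s1_toy(forced_toy):
    """Scenario-1 configuration: DMSP + nitrate storage open, TAG/chryso closed."""

    def _force(u_c, u_n=0.5):
        m = forced_toy(u_c, u_n)
        m.set_bounds("DM_tag_c", 0, 0)
        m.set_bounds("DM_chryso_c", 0, 0)
        return m

    return _force


@pytest.fixture(scope="session")
def line_model():
    """1-D flux polytope: two coupled reactions, v1 = v2 in [-1, 1]."""
    return MetabolicModel(
        "line",
        [Metabolite("A_c", "", "c")],
        [
            Reaction("R1", {"A_c": 1.0}, -1, 1),
            Reaction("R2", {"A_c": -1.0}, -1, 1),
        ],
        objective_id="R1",
    )


@pytest.fixture(scope="session")
def triangle_model():
    """2-D flux polytope: v_in = v_a + v_b, v_a, v_b >= 0, v_a + v_b <= 1."""
    return MetabolicModel(
        "triangle",
        [Metabolite("A_c", "", "c")],
        [
            Reaction("Rin", {"A_c": 1.0}, -1, 1),
            Reaction("Ra", {"A_c": -1.0}, 0, 1),
            Reaction("Rb", {"A_c": -1.0}, 0, 1),
        ],
        objective_id="Rin",
    )


def triangle_rejection_sample(n, seed):
    """Uniform rejection sampling of the triangle polytope marginals."""
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n:
        a, b = rng.uniform(0, 1, 2)
        if a + b <= 1:
            pts.append((a, b))
    pts = np.asarray(pts)
    return {"Ra": pts[:, 0], "Rb": pts[:, 1], "Rin": pts.sum(axis=1)}
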