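import numpy as np
import pytest

from marshrisk.database_io import IndexPoint, IndexPointDB
from marshrisk.gia_rates import RSLCurve
from marshrisk.monotone_pspline import (
    ModelConfig,
    fit_tendency_model,
    probability_curve,
)
from marshrisk.synthetic_data import default_recovery_dataset


def make_point(i, tendency="positive", contact="gradual", age=5000.0, region="r1"):
    return IndexPoint(
        point_id=f"p{i}",
        region_id=region,
        lat=52.0,
        lon=-1.0,
        age=age,
        tendency=tendency,
        contact=contact,
    )


@pytest.fixture
def tiny_db():
    """Five points: three gradual (pos/neg/none), two erosional."""
    return IndexPointDB(
        [
            make_point(0, "positive", "gradual"),
            make_point(1, "negative", "gradual"),
            make_point(2, "none", "gradual"),
            make_point(3, "positive", "erosional"),
            make_point(4, "negative", "erosional"),
        ]
    )


@pytest.fixture
def linear_curve():
    """Constant-slope curve: RSL rises 10 mm/yr toward present."""
    return RSLCurve("lin", t=[0.0, 1000.0, 2000.0, 3000.0], rsl=[0.0, -10.0, -20.0, -30.0])


QUICK_MCMC = dict(chains=2, iterations=3000, burn_in=1500, thin=3)


@pytest.fixture(scope="session")
def recovery_fit():
    """Default parameter-recovery experiment, shared across tests.

    n = 800 gradual-contact points with tendencies drawn from the
    logistic(-1.5 + 0.5x) truth, fitted with the default monotone model.
    """
    data, truth, table = default_recovery_dataset(seed=1)
    post = fit_tendency_model(data, ModelConfig(seed=1))
    grid = np.linspace(data.x.min(), data.x.max(), 1001)
    curve = probability_curve(post, grid)
    return {"data": data, "truth": truth, "post": post, "curve": curve}
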