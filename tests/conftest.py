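import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from refugia import (
    Field,
    Landscape,
    Roost,
    SynthesisConfig,
    generate_landscape,
)


def make_field(
    fid: str,
    x0: float,
    y0: float,
    w: float,
    h: float,
    crop: str = "pasture",
    use: int = 0,
) -> Field:
    """Axis-aligned rectangular field with lower-left corner (x0, y0)."""
    return Field(
        id=fid,
        boundary=Polygon([(x0, y0), (x0 + w, y0), (x0 + w, y0 + h), (x0, y0 + h)]),
        crop=crop,
        historic_use_years=use,
    )


def make_landscape(fields, roosts=None) -> Landscape:
    if roosts is None:
        roosts = [Roost("r1", Point(0.0, 0.0), "coast")]
    return Landscape(fields=list(fields), roosts=list(roosts))


@pytest.fixture(scope="session")
def small_landscape() -> Landscape:
    """20 synthetic fields in a 2.5 km extent — the smoke-scale fixture."""
    return generate_landscape(
        SynthesisConfig(n_fields=20, extent_m=2500.0), seed=42
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dense_landscape() -> Landscape:
    """5x4 grid of near-touching 95 m squares: every grid neighbour is
    within the 20 m adjacency threshold, so merging is exercised."""
    fields = []
    k = 0
    for i in range(5):
        for j in range(4):
            k += 1
            fields.append(
                make_field(
                    f"g{k:02d}",
                    100.0 * i,
                    100.0 * j,
                    95.0,
                    95.0,
                    crop="pasture" if k % 3 else "stubble",
                    use=k % 5,
                )
            )
    return make_landscape(fields)
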