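import numpy as np
import pytest

from ordertrans import RatingScale, RatingSeries


@pytest.fixture
def scale06() -> RatingScale:
    return RatingScale(0, 6)


@pytest.fixture
def scale17() -> RatingScale:
    return RatingScale(1, 7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_series(values, scale, subject="s1", items=None) -> RatingSeries:
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    items = items or [f"i{j+1}" for j in range(values.shape[1])]
    return RatingSeries(
        subject_id=subject,
        items=items,
        scales={it: scale for it in items},
        values=values,
    )


@pytest.fixture
def series_factory():
    return make_series
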