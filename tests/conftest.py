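import numpy as np
import pytest

from phenopam.segmentation import ROILayout, make_roi_grid
from phenopam.synthetic import (
    SyntheticPlantSpec,
    SyntheticSceneSpec,
    exact_trajectories,
)


@pytest.fixture
def small_layout() -> ROILayout:
    """1x2 grid of 50-px ROIs on a 140x300 frame: cheap but realistic."""
    return make_roi_grid(
        n_rows=1, n_cols=2, origin=(70, 70), spacing=140, radius=50,
        image_shape=(140, 300),
    )


@pytest.fixture
def scene_factory(small_layout):
    """Build a small scene with exactly-representable trajectories."""

    def build(
        n_steps: int = 5,
        noise_sd: float = 0.0,
        seed: int = 0,
        radius: float = 18.0,
        defects=(),
        n_plants: int = 2,
        texture_sd: float = 0.0,  # pristine leaves: exact-inversion fixtures
    ):
        plants = []
        for pos in range(1, n_plants + 1):
            fo, fv, yii_t, npq_t = exact_trajectories(
                n_steps, np.random.default_rng(100 + pos)
            )
            plants.append(
                SyntheticPlantSpec(
                    roi_position=pos,
                    center=small_layout.centers[pos - 1],
                    radius=radius,
                    fo_level=fo,
                    fvfm_true=fv,
                    yii_trajectory=yii_t,
                    npq_trajectory=npq_t,
                    genotype=f"g{pos}",
                )
            )
        return SyntheticSceneSpec(
            plants=plants,
            layout=small_layout,
            image_shape=small_layout.image_shape,
            noise_sd=noise_sd,
            texture_sd=texture_sd,
            defects=list(defects),
            seed=seed,
        )

    return build
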