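import numpy as np
import pytest

from petquant import PhantomConfig, SegmentationMask, SuvVolume


def make_volume(values, spacing=(1, 1, 1), origin=(0, 0, 0), patient_id="p1"):
    return SuvVolume(patient_id=patient_id, values=np.asarray(values, float),
                     spacing=spacing, origin=origin)


def make_mask(values, spacing=(1, 1, 1), origin=(0, 0, 0), patient_id="p1",
              reader_id="A"):
    return SegmentationMask(patient_id=patient_id, reader_id=reader_id,
                            values=np.asarray(values), spacing=spacing,
                            origin=origin)


@pytest.fixture
def small_config():
    """A fast phantom configuration for unit tests (not the study defaults)."""
    return PhantomConfig(
        n_patients=3,
        seed=7,
        grid_shape=(32, 32, 48),
        spacing_mm=(4.0, 4.0, 4.0),
        lesion_count_mean=3.0,
        radius_range_mm=(5.0, 18.0),
        suv_peak_range=(8.0, 20.0),
    )
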