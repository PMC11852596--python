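import numpy as np
import pytest

from colmorph.synthetic import (FilamentSpec, ImageSpec, generate_dataset,
                                render_image)


@pytest.fixture(scope="session")
def preset_specs():
    """Collagen-monomer simulation conditions used across the suite."""
    return FilamentSpec(), ImageSpec()


@pytest.fixture(scope="session")
def three_filament_image(preset_specs):
    """One seeded 512 px image holding exactly 3 separated filaments."""
    fspec, ispec = preset_specs
    ispec3 = ImageSpec(filaments_per_image=(3, 3))
    ds = generate_dataset(fspec, ispec3, 1, seed=7)
    assert ds.n_dropped == 0
    return ds


@pytest.fixture(scope="session")
def small_dataset(preset_specs):
    """Three seeded preset images with ground truth (several molecules)."""
    fspec, ispec = preset_specs
    return generate_dataset(fspec, ispec, 3, seed=11)


@pytest.fixture(scope="session")
def straight_image():
    """A single noise-free, axis-aligned 300 nm filament (with tip blur)."""
    ispec = ImageSpec(noise_sigma=0.0)
    y = (256 + 0.5) * ispec.pixel_size  # through pixel centres
    poly = np.column_stack([np.linspace(362.0, 662.0, 101), np.full(101, y)])
    img = render_image([poly], ispec, id="straight")
    return img, poly
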