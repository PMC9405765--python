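import pytest

from mmrecur import segment, synth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom with one 8 mm spherical lesion, seeded noise."""
    spec = synth.spherical_lesion_spec(8.0, seed=7)
    study, truth = synth.generate_phantom(spec)
    return spec, study, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Same geometry with zero noise (quantized tissue intensities)."""
    from dataclasses import replace

    spec = synth.spherical_lesion_spec(
        8.0, seed=7, noise_sd={vt: 0.0 for vt in synth.VOLUME_TYPES}
    )
    study, truth = synth.generate_phantom(spec)
    return spec, study, truth


@pytest.fixture(scope="session")
def segmented_noisy(noisy_phantom):
    spec, study, truth = noisy_phantom
    masks, report = segment.segment_study(study, seed=7)
    return study, truth, masks


@pytest.fixture(scope="session")
def small_cohort():
    return synth.generate_cohort(synth.CohortSpec(n=400, n_imaging=60, seed=11))
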