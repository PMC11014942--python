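import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def sediment_measurements():
    """Three sediment records whose delta18O mean is 4.6 permil and whose
    measured anomalies average 1.3 permil."""
    from nitrokit import IsotopeMeasurement, SampleType

    return [
        IsotopeMeasurement("sed_01", SampleType.sediment, d18O=3.6, D17O=1.0),
        IsotopeMeasurement("sed_02", SampleType.sediment, d18O=4.6, D17O=1.3),
        IsotopeMeasurement("sed_03", SampleType.sediment, d18O=5.6, D17O=1.6),
    ]


@pytest.fixture
def mimic_annotation():
    """Annotation table where anammox markers are undetected and every
    other nitrogen-cycle process has positive signal."""
    from nitrokit import SimSpec, gen_annotation_table

    table, truth = gen_annotation_table(SimSpec(seed=11))
    return table, truth
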