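import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from cooccur.grid import ArmDefinition, build_grid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_arms():
    return [
        ArmDefinition("1", "p", 0, 1_000_000),
        ArmDefinition("1", "q", 1_200_000, 2_200_000),
    ]


@pytest.fixture
def small_grid(two_arms):
    return build_grid(two_arms, spacing=20_000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# hg18 autosomal arm lengths (bp), p-arms of acrocentrics excluded: the 39
# usable arms of a human autosomal genome.
HG18_ARM_LENGTHS = {
    "1_p": 124_300_000, "1_q": 122_924_563, "2_p": 93_300_000, "2_q": 149_439_604,
    "3_p": 91_000_000, "3_q": 108_429_320, "4_p": 50_400_000, "4_q": 140_873_276,
    "5_p": 48_400_000, "5_q": 132_457_375, "6_p": 61_000_000, "6_q": 109_748_318,
    "7_p": 59_900_000, "7_q": 98_738_763, "8_p": 45_600_000, "8_q": 100_674_022,
    "9_p": 49_000_000, "9_q": 91_273_430, "10_p": 40_300_000, "10_q": 95_074_747,
    "11_p": 52_900_000, "11_q": 81_552_006, "12_p": 35_400_000, "12_q": 96_949_895,
    "13_q": 96_168_633, "14_q": 88_289_540, "15_q": 84_264_906,
    "16_p": 38_200_000, "16_q": 50_627_896, "17_p": 22_200_000, "17_q": 56_574_750,
    "18_p": 17_300_000, "18_q": 58_797_047, "19_p": 28_500_000, "19_q": 35_311_216,
    "20_p": 27_100_000, "20_q": 35_335_290, "21_q": 37_044_342, "22_q": 35_154_566,
}


@pytest.fixture(scope="session")
def hg18_arms():
    arms = []
    for name, length in HG18_ARM_LENGTHS.items():
        chrom, arm = name.rsplit("_", 1)
        if arm == "q" and f"{chrom}_p" in HG18_ARM_LENGTHS:
            start = HG18_ARM_LENGTHS[f"{chrom}_p"]
        else:
            start = 0
        arms.append(ArmDefinition(chrom, arm, start, start + length))
    return arms
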