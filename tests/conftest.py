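import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gbspop.vcfio import GenotypeCall, MISSING, PopulationVCF, VariantRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_record(chrom, pos, gts, ref="A", alts=("T",), gqs=None, dps=None):
    """Build a record from dosage-style genotype specs.

    Each entry of ``gts`` is None (missing) or a pair of allele indices.
    """
    calls = []
    for i, gt in enumerate(gts):
        calls.append(
            GenotypeCall(
                gt,
                gq=gqs[i] if gqs else None,
                dp=dps[i] if dps else None,
            )
        )
    return VariantRecord(chrom, pos, ref, alts, calls)


@pytest.fixture
def toy_pop():
    """3 samples x 2 sites with a missing call and mixed genotypes."""
    records = [
        make_record("1", 100, [(0, 0), (0, 1), (1, 1)], gqs=[50, 40, 30]),
        make_record("1", 200, [(0, 1), None, (0, 0)], gqs=[60, None, 20]),
    ]
    return PopulationVCF(["S1", "S2", "S3"], records)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
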