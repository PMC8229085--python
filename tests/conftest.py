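import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from coipop.rflp import extract_amplicon
from coipop.simulate import generate_population, medq1_config, medq2_config


@pytest.fixture(scope="session")
def medq1_pop():
    """Survey-structured MEDQ1-like population (n=31, 13 haplotypes)."""
    return generate_population(medq1_config(seed=11))


@pytest.fixture(scope="session")
def medq2_pop():
    """MEDQ2-like population (n=23, 3 haplotypes at 19/3/1)."""
    return generate_population(medq2_config(seed=11))


def amplicons_of(pop):
    return [
        (
            r.specimen_id,
            extract_amplicon(
                r.sequence, pop.fwd_primer, pop.rev_primer,
                specimen_id=r.specimen_id,
            ).sequence,
        )
        for r in pop.records
    ]


@pytest.fixture(scope="session")
def medq1_amplicons(medq1_pop):
    return amplicons_of(medq1_pop)


@pytest.fixture(scope="session")
def medq2_amplicons(medq2_pop):
    return amplicons_of(medq2_pop)
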