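"""Shared fixtures: toy references and a module-scoped simulated cohort."""

from __future__ import annotations

import pytest

from mtsomatic.reference import GeneAnnotation, MtReference
from mtsomatic.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_reference,
)


@pytest.fixture(scope="session")
def toy_reference() -> MtReference:
    """60 bp circular genome with one heavy-strand gene covering 1..60."""
    seq = "ATGGCCTGGAAACGTTACGATTGCATCGAACTGGGTCATAAGTTCCCAGGATCCGTTTAA"
    return MtReference(sequence=seq, genes=[GeneAnnotation("g1", 1, 60, "heavy")])


@pytest.fixture(scope="session")
def two_strand_reference() -> MtReference:
    """Genome with a heavy-strand and a light-strand gene plus non-coding gaps."""
    seq = (
        "TTTTTTTTTT"
        "ATGGCCTGGAAACGTTACGATTGCATCGAA"  # heavy gene 11..40
        "TTTTTTTTTT"
        "CATCATCATCATCATCATCATCATCATCAT"  # light gene 51..80 (coding = revcomp)
        "TTTTTTTTTT"
    )
    genes = [
        GeneAnnotation("hv", 11, 40, "heavy"),
        GeneAnnotation("lt", 51, 80, "light"),
    ]
    return MtReference(sequence=seq, genes=genes)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11, indel_rate_per_year=0.002)


@pytest.fixture(scope="session")
def cohort(sim_config):
    ref = simulate_reference(sim_config)
    return simulate_cohort(sim_config, ref)


@pytest.fixture(scope="session")
def cohort_dir(cohort, tmp_path_factory):
    from mtsomatic.simulate import write_cohort

    path = tmp_path_factory.mktemp("cohort")
    write_cohort(cohort, path)
    return path
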