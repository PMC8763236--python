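"""Shared fixtures: small synthetic genomes with known planted truth."""

from __future__ import annotations

import pytest

from isburst._util import revcomp
from isburst.simulate import ISFamilySpec, generate_genome


@pytest.fixture(scope="session")
def nine_copy_genome():
    """Genome with one IS family at nine copies (one intact) plus background
    genes; the canonical census substrate."""
    spec = ISFamilySpec(
        "ISAm1", element_length=1513, copy_number=9, intact_copies=1,
        divergence=0.005, itr_length=14, tsd_length=8,
    )
    genome, planted = generate_genome(
        3, [20_000, 20_000, 20_000],
        gc_coding=0.475, gc_noncoding=0.415,
        family_specs=[spec], seed=11,
    )
    return genome, planted, spec


@pytest.fixture(scope="session")
def caller_genome():
    """Small genome (2 element copies, 1 intact) plus the donor element
    sequence, for insertion-calling simulations."""
    spec = ISFamilySpec(
        "ISAm1", element_length=1200, copy_number=2, intact_copies=1,
        divergence=0.0, itr_length=14, tsd_length=8,
    )
    genome, planted = generate_genome(1, [8000], family_specs=[spec], seed=5)
    donor = next(p for p in planted if p.intact)
    elem = genome.contigs[donor.contig][donor.start:donor.end]
    if donor.strand == "-":
        elem = revcomp(elem)
    return genome, planted, elem
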