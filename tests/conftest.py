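import numpy as np
import pytest

from structmotif.compare import NullModel
from structmotif.fixtures import (FixtureSpec, PlantedContact,
                                  closed_loop_fixture, make_complex,
                                  make_motif_db)
from structmotif.structure import parse_complex


@pytest.fixture(scope="session")
def motif_db():
    """Small random motif database with a fixed seed."""
    pwms, text = make_motif_db(10, widths=(8, 10), seed=42)
    return pwms


@pytest.fixture(scope="session")
def null_model(motif_db):
    return NullModel(motif_db, m_null=200, seed=7)


@pytest.fixture(scope="session")
def helix_complex():
    spec = FixtureSpec(seed=2, n_residues=10, dna_length=12,
                       protein_mode="helix")
    return parse_complex(make_complex(spec), source_id="helix12")


@pytest.fixture(scope="session")
def planted_complex():
    """One residue planted 10 A from the only step of a 2-bp duplex; the
    other residues sit far from the DNA."""
    spec = FixtureSpec(seed=5, n_residues=3, dna_length=2,
                       planted_contacts=[PlantedContact(0, 0, 10.0)])
    return parse_complex(make_complex(spec), source_id="planted")


@pytest.fixture(scope="session")
def closed_loop():
    """(complex, contacts, planted table, consensus) parameter-recovery
    fixture."""
    return closed_loop_fixture(seed=3, dna_length=8)
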