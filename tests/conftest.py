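"""Shared fixtures: handcrafted records and session-scoped synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sglut.dataset_prep import balance_dataset
from sglut.seq_data import ProteinRecord, Site, SiteFragment, site_fragments
from sglut.synthetic import MotifSpec, SyntheticConfig, generate_records

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_fragment(
    residues: str, label: str = "positive", accession: str = "P1", position: int = 50
) -> SiteFragment:
    """Fragment from a raw window string (length must be odd, centre 'C')."""
    return SiteFragment(
        accession=accession, position=position, residues=residues,
        label=label, n=(len(residues) - 1) // 2,
    )


def random_fragment(rng: np.random.Generator, n: int = 10, label: str = "positive",
                    accession: str = "P1") -> SiteFragment:
    aas = np.array(list("GAVLIPFMWSTCYNQDEKRH"))
    window = rng.choice(aas, size=2 * n + 1)
    window[n] = "C"
    return SiteFragment(accession=accession, position=n + 1 + int(rng.integers(100)),
                        residues="".join(window), label=label, n=n)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture
def simple_protein() -> ProteinRecord:
    rec = ProteinRecord(
        accession="P1",
        sequence="MCKDECAAAC",
        sites=[Site(2, "positive"), Site(6, "negative")],
    )
    rec.validate()
    return rec


#: Study conditions of the two-subpopulation experiments: two distinct
#: residue motifs (K/R at -6, D/E at +8), exclusive carriage, default
#: context tilt, 300 positive and 300 negative labelled sites.
TWO_MOTIF_CONFIG = SyntheticConfig(
    n_proteins=150,
    positives_per_protein=2,
    negatives_per_protein=2,
    motifs=(
        MotifSpec(-6, residues="KR", penetrance=1.0),
        MotifSpec(8, residues="DE", penetrance=1.0),
    ),
    seed=0,
)


@pytest.fixture(scope="session")
def two_motif_data():
    return generate_records(TWO_MOTIF_CONFIG)


@pytest.fixture(scope="session")
def two_motif_dataset(two_motif_data):
    return balance_dataset(two_motif_data.proteins, seed=0)


@pytest.fixture(scope="session")
def two_motif_positives(two_motif_data):
    return [f for f in site_fragments(two_motif_data.proteins) if f.label == "positive"]
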