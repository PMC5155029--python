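"""Shared fixtures: one seeded synthetic study reused across the suite."""

from __future__ import annotations

import pytest

from bcrmrd.repertoire_io import GermlineDB, Repertoire, SampleMeta
from bcrmrd.synthetic_repertoire import (
    SimConfig,
    simulate_clone,
    simulate_germline,
    simulate_healthy,
)


@pytest.fixture(scope="session")
def cfg() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Lighter healthy repertoires for tests that need several of them."""
    return SimConfig(seed=11, healthy_cells=400)


@pytest.fixture(scope="session")
def db(cfg) -> GermlineDB:
    return simulate_germline(cfg)


@pytest.fixture(scope="session")
def healthy(cfg, db):
    """One full-size healthy repertoire plus its truth table."""
    return simulate_healthy(cfg, db, sample_id="H1")


@pytest.fixture(scope="session")
def healthy_panel(small_cfg, db):
    """Six smaller healthy repertoires standing in for a donor panel."""
    return [
        simulate_healthy(small_cfg, db, sample_id=f"HP{i + 1}", salt=i)[0]
        for i in range(6)
    ]


@pytest.fixture(scope="session")
def clone(cfg, db):
    return simulate_clone(cfg, db)


def make_meta(sample_id="S1", patient_id="P1", day=0, **kw) -> SampleMeta:
    return SampleMeta(
        sample_id=sample_id,
        patient_id=patient_id,
        day=day,
        tissue=kw.pop("tissue", "synthetic"),
        template=kw.pop("template", "RNA"),
        **kw,
    )


def make_rep(counts: dict[str, int], **kw) -> Repertoire:
    return Repertoire.from_counts(make_meta(**kw), counts)
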