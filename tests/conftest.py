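from __future__ import annotations

import pytest

from serrata.cohort_sim import SimConfig, simulate_cohort, write_cohort
from serrata.resources import load_id_catalog, load_sbs_catalog


@pytest.fixture(scope="session")
def sbs_catalog():
    return load_sbs_catalog()


@pytest.fixture(scope="session")
def id_catalog():
    return load_id_catalog()


@pytest.fixture(scope="session")
def cohort():
    """One full default synthetic cohort, shared across the session."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_dir(cohort, tmp_path_factory):
    path = tmp_path_factory.mktemp("cohort") / "c1"
    write_cohort(cohort, path)
    return path


def make_variant(**kwargs):
    """Terse AnnotatedVariant factory for unit tests."""
    from serrata.types import AnnotatedVariant

    defaults = dict(
        chrom="chr1", pos=100, ref="A", alt="G", gene="GENE1",
        consequence="missense", impact="missense",
    )
    defaults.update(kwargs)
    return AnnotatedVariant(**defaults)


def verdicts(n_deleterious: int, n_unavailable: int = 0) -> dict[str, str]:
    from serrata.types import PREDICTOR_TOOLS

    out = {}
    for i, tool in enumerate(PREDICTOR_TOOLS):
        if i < n_deleterious:
            out[tool] = "deleterious"
        elif i < n_deleterious + n_unavailable:
            out[tool] = "unavailable"
        else:
            out[tool] = "tolerated"
    return out
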