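"""Shared fixtures.

The expensive artefacts (the full scaffold enumeration and the
200-embedding conformer run for the nine mesyl–pyrimidine compounds)
are computed once per session and shared across test modules.
"""

from __future__ import annotations

import time

import pytest

import exitvec
from exitvec import conformers, elaboration


@pytest.fixture(scope="session")
def scaffolds26():
    return exitvec.enumerate_scaffolds()


@pytest.fixture(scope="session")
def scaffolds27(scaffolds26):
    return exitvec.augment_with_tropane(scaffolds26)


@pytest.fixture(scope="session")
def blocks():
    return exitvec.load_registry("building_blocks")


@pytest.fixture(scope="session")
def nine_mapping(scaffolds27, blocks):
    mapping, virtual_only = exitvec.match_named_blocks(scaffolds27, blocks)
    return mapping, virtual_only


@pytest.fixture(scope="session")
def pyrimidinyl():
    return next(e for e in exitvec.load_registry("fragments") if e.id == "pyrimidin-5-yl")


@pytest.fixture(scope="session")
def caps():
    return exitvec.load_registry("caps")


@pytest.fixture(scope="session")
def mesyl_cap(caps):
    return next(e for e in caps if e.id == "mesyl")


@pytest.fixture(scope="session")
def mesyl_series(nine_mapping, pyrimidinyl, mesyl_cap):
    """The nine pyrimidine methanesulfonamides: library, ensembles, table, wall time."""
    mapping, _ = nine_mapping
    nine = [mapping[k] for k in sorted(mapping)]
    library = elaboration.enumerate_library(nine, [pyrimidinyl], [mesyl_cap])
    t0 = time.time()
    ensembles = {c.compound_id: conformers.embed_and_minimize(c) for c in library}
    elapsed = time.time() - t0
    table = exitvec.vectors_for_library(library, ensembles)
    return dict(library=library, ensembles=ensembles, table=table, conformer_seconds=elapsed)
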