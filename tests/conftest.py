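import logging

import pandas as pd
import pytest

from panelkit import GenotypeMatrix, make_paper_like_fixture

logging.getLogger("panelkit").setLevel(logging.ERROR)


def gm(rows: dict[str, list[str]], loci: list[str] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {sample_id: [codes...]}."""
    first = next(iter(rows.values()))
    loci = loci or [f"L{j+1}" for j in range(len(first))]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=loci)
    df.index.name = "sample_id"
    return GenotypeMatrix(df)


@pytest.fixture(scope="session")
def paper_fixture():
    """Canonical four-subpopulation study-condition dataset (seed 1):
    read counts, truth set and sample metadata."""
    return make_paper_like_fixture(seed=1)


@pytest.fixture(scope="session")
def truth_matrix(paper_fixture):
    return paper_fixture[1].genotypes


@pytest.fixture(scope="session")
def fixture_meta(paper_fixture):
    return paper_fixture[2]
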