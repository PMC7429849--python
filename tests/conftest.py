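import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lacsig import count_contexts, normalize_signatures
from lacsig.data import load_context_table, load_reference, load_signatures


@pytest.fixture(scope="session")
def ref():
    """The bundled synthetic 3096 bp lacZ-like reference."""
    return load_reference()


@pytest.fixture(scope="session")
def raw_sigs():
    return load_signatures()


@pytest.fixture(scope="session")
def human_contexts():
    return load_context_table("human")


@pytest.fixture(scope="session")
def lacz_contexts(ref):
    return count_contexts(ref)


@pytest.fixture(scope="session")
def norm_sigs(raw_sigs, lacz_contexts, human_contexts):
    """The bundled signature set normalized into lacZ context space."""
    return normalize_signatures(raw_sigs, lacz_contexts, human_contexts)


def make_catalog(rows):
    """Build a MutationCatalog from (animal, position, ref, alt[, class, source]) tuples."""
    from lacsig import MutationCatalog
    from lacsig.catalog import COLUMNS

    records = []
    for row in rows:
        animal, position, ref_, alt = row[:4]
        cls = row[4] if len(row) > 4 else "SNV"
        source = row[5] if len(row) > 5 else "NGS"
        records.append(
            {
                "animal": animal,
                "agent": "test",
                "tissue": "bone marrow",
                "position": position,
                "ref": ref_,
                "alt": alt,
                "class": cls,
                "source": source,
            }
        )
    return MutationCatalog(pd.DataFrame(records, columns=COLUMNS))
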