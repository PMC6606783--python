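import csv
from importlib import resources

import pytest

from peptaibolkit import catalog as catalog_mod
from peptaibolkit import chem
from peptaibolkit.io import load_packaged_table


@pytest.fixture(scope="session")
def registry():
    return chem.default_registry()


@pytest.fixture(scope="session")
def tables():
    """All packaged compound records keyed by group letter."""
    return {g: load_packaged_table(g) for g in "ABC"}


@pytest.fixture(scope="session")
def all_records(tables):
    return [r for g in "ABC" for r in tables[g]]


@pytest.fixture(scope="session")
def by_name(all_records):
    return {r.name: r for r in all_records}


@pytest.fixture(scope="session")
def catalogue():
    return catalog_mod.load_catalog()


@pytest.fixture(scope="session")
def catalogue_by_name(catalogue):
    return {e.name: e for e in catalogue}


@pytest.fixture(scope="session")
def golden_matches():
    path = resources.files("peptaibolkit.data") / "golden_matches.tsv"
    with open(str(path)) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


@pytest.fixture
def paracelsin_b(registry):
    return chem.PeptaibolSequence.from_string(
        "Ac-Aib-Ala-Aib-Ala-Aib-Ala-Gln-Aib-Lxx-Aib-Gly-Aib-Aib-Pro-Vxx-"
        "Aib-Aib-Gln-Gln-Pheol", name="Paracelsin B", registry=registry)


@pytest.fixture
def brevicelsin_i(registry):
    return chem.PeptaibolSequence.from_string(
        "Ac-Aib-Ala-Aib-Ala-Aib-Gln-Aib-Lxx-Aib-Gly-Aib-Aib-Pro-Vxx-Aib-"
        "Aib-Gln-Gln-Pheol", name="Brevicelsin-I", registry=registry)
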