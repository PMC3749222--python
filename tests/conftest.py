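import sys
from decimal import Decimal
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ystrkit.catalog import MINHT_LOCI, default_catalog
from ystrkit.classify import load_tree
from ystrkit.profiles import StrProfile


@pytest.fixture(scope="session")
def catalog():
    return default_catalog(extra_loci=["DYS385a/b"])


@pytest.fixture(scope="session")
def tree():
    return load_tree()


def make_profile(sample_id="s1", population="Peru", region="Andes",
                 haplogroup=None, **allele_overrides):
    """A complete minHt profile; override loci by keyword (values may be
    scalars or tuples for multi-allele loci)."""
    base = dict(zip(MINHT_LOCI, (13, 13, 16, 24, 10, 14, 13)))
    base.update(allele_overrides)
    alleles = {}
    for locus, v in base.items():
        if v is None:
            continue
        vals = v if isinstance(v, tuple) else (v,)
        alleles[locus.replace("_", "")] = tuple(Decimal(str(x)) for x in vals)
    return StrProfile(sample_id=sample_id, population=population,
                      region=region, alleles=alleles, haplogroup=haplogroup)


@pytest.fixture
def profile():
    return make_profile()
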