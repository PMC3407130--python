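import numpy as np
import pytest

from ytopo.haplogroups import load_default_tree
from ytopo.strprofiles import (NUMERIC_LOCI, NumericHaplotype, YfilerProfile,
                               load_default_panel)


@pytest.fixture(scope="session")
def tree():
    return load_default_tree()


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_numeric(values, missing=None):
    """15-locus numeric haplotype from a value list (None = missing)."""
    vals, miss = [], []
    for v in values:
        if v is None:
            vals.append(float("nan"))
            miss.append(True)
        else:
            vals.append(float(v))
            miss.append(False)
    return NumericHaplotype(values=tuple(vals), missing=tuple(miss))


BASE15 = (14, 13, 16, 24, 10, 13, 13, 15, 12, 12, 19, 15, 16, 23, 12)


def base_haplotype(**offsets):
    """The modal 15-locus haplotype with per-locus repeat offsets."""
    vals = dict(zip(NUMERIC_LOCI, BASE15))
    for locus, off in offsets.items():
        locus = locus.replace("_", "-") if locus.startswith("Y") else locus
        vals[locus] += off
    return make_numeric([vals[l] for l in NUMERIC_LOCI])


def full_profile(**overrides):
    """A complete raw Yfiler profile (17 alleles) for parsing/prep tests."""
    alleles = {
        "DYS19": 14.0, "DYS389I": 13.0, "DYS389II": 29.0, "DYS390": 24.0,
        "DYS391": 10.0, "DYS392": 13.0, "DYS393": 13.0, "DYS437": 15.0,
        "DYS438": 12.0, "DYS439": 12.0, "DYS448": 19.0, "DYS456": 15.0,
        "DYS458": 16.0, "DYS635": 23.0, "Y-GATA-H4": 12.0,
    }
    dys385 = overrides.pop("dys385", frozenset({11.0, 14.0}))
    duplicated = overrides.pop("duplicated", frozenset())
    alleles.update(overrides)
    return YfilerProfile(alleles=alleles, dys385=dys385, duplicated=duplicated)
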