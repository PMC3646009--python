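"""Shared fixtures: one default synthetic bundle (and its SASA analysis)
is built once per session because construction involves loop-closure
optimization (~seconds)."""

from __future__ import annotations

import numpy as np
import pytest

from srpatch.sasa import sasa
from srpatch.synth import BundleSpec, PlantSpec, build_bundle, plant_conservation


@pytest.fixture(scope="session")
def bundle_spec() -> BundleSpec:
    return BundleSpec()


@pytest.fixture(scope="session")
def bundle(bundle_spec):
    return build_bundle(bundle_spec)


@pytest.fixture(scope="session")
def bundle_sasa(bundle):
    return sasa(bundle)


@pytest.fixture(scope="session")
def planted_centre(bundle_sasa) -> int:
    exposed = sorted(bundle_sasa.exposed_set())
    # an exposed residue in the middle helix: mid-surface, room for a patch
    return next(i for i in exposed if 24 <= i <= 34)


@pytest.fixture(scope="session")
def planted_grades(bundle, bundle_sasa, planted_centre):
    return plant_conservation(bundle, bundle_sasa, PlantSpec(planted_centre, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
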