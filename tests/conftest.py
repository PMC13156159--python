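"""Shared fixtures: seeded libraries and one expensive discovery run."""

import numpy as np
import pytest

import satellitome as st
from satellitome.discover import DiscoveryParams

BASES = np.array(list("ACGT"))


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, length))


@pytest.fixture(scope="session")
def five_family_specs():
    """Five planted monomers, 24-200 bp, abundances >= 0.1%."""
    return [
        st.PlantedFamilySpec("f24", 24, 0.60, 0.012, 8.0),
        st.PlantedFamilySpec("f42", 42, 0.55, 0.008, 5.0),
        st.PlantedFamilySpec("f63", 63, 0.50, 0.005, 5.0),
        st.PlantedFamilySpec("f120", 120, 0.58, 0.0015, 4.0),
        st.PlantedFamilySpec("f200", 200, 0.52, 0.002, 3.0),
    ]


@pytest.fixture(scope="session")
def five_family_library(five_family_specs):
    """A 15 Mb genome sampled at ~0.6x: the full discovery workload."""
    lib, truth = st.build_library(
        five_family_specs, genome_size=15_000_000, coverage=0.6, seed=7)
    return lib, truth


@pytest.fixture(scope="session")
def five_family_discovery(five_family_library):
    lib, _ = five_family_library
    return st.iterate_discovery(lib, DiscoveryParams(seed=3))


@pytest.fixture(scope="session")
def background_library():
    """Pure random background, no planted families (negative control)."""
    lib, _ = st.build_library([], genome_size=5_000_000, coverage=0.6,
                              seed=2)
    return lib


@pytest.fixture(scope="session")
def small_planted_library():
    """One 42 bp family at 1% in a 5 Mb genome (fast single-family case)."""
    specs = [st.PlantedFamilySpec("fam42", 42, 0.55, 0.01,
                                  copy_divergence_mean=5.0)]
    lib, truth = st.build_library(specs, genome_size=5_000_000,
                                  coverage=0.6, seed=11)
    return lib, truth


@pytest.fixture(scope="session")
def quant_library():
    """Two families at 1% / 0.5% with planted divergences 2% and 12%."""
    specs = [st.PlantedFamilySpec("low", 42, 0.55, 0.01, 2.0),
             st.PlantedFamilySpec("high", 120, 0.50, 0.005, 12.0)]
    lib, truth = st.build_library(specs, genome_size=2_000_000,
                                  coverage=1.5, seed=9)
    return lib, truth


@pytest.fixture(scope="session")
def serrasalmid_scenario():
    """Three-species scenario with the published tree shape.

    Two lineages split 34.9 Mya nested inside a 40 Mya root, six shared
    families drifting at 1.85e-8 substitutions/site/year.
    """
    truth = st.ScenarioTruth(
        species_labels=["Myl", "Col", "Pia"],
        divergence_time_years={("Myl", "Col"): 40e6, ("Myl", "Pia"): 40e6,
                               ("Col", "Pia"): 34.9e6},
        substitution_rate=1.85e-8,
        shared_family_labels=["s1", "s2", "s3", "s4", "s5", "s6"],
        private_family_labels={"Myl": ["pm1"], "Col": ["pc1"],
                               "Pia": ["pp1"]},
    )
    return st.make_species_scenario(truth, seed=42), truth
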