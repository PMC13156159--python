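"""Cross-species comparison: conserved pairs, distances, turnover rates."""

import math

import numpy as np
import pytest

import satellitome as st
from satellitome.catalog import SatFamily, name_catalog
from satellitome.compare import (consensus_turnover_rate, ctr_per_myr,
                                 find_conserved, three_way_table)
from satellitome.errors import ConfigError, EmptyCatalogError, \
    InvalidInputError

from conftest import random_dna


def _catalog(seqs, prefix, rng=None):
    fams = [SatFamily.from_consensus(s, 0.01 / (i + 1))
            for i, s in enumerate(seqs)]
    return name_catalog(fams, prefix)


class TestCTRClosedForm:
    def test_published_extreme_pair(self):
        assert round(ctr_per_myr(2.53, 40.0), 4) == 0.0316

    def test_published_species_pair_means(self):
        assert round(ctr_per_myr(1.59, 40.0), 4) == 0.0199
        assert round(ctr_per_myr(1.40, 34.9), 4) == 0.0201
        assert round(ctr_per_myr(1.28, 40.0), 4) == 0.0160

    def test_zero_distance_zero_rate(self):
        assert consensus_turnover_rate(0.0, 4e7) == 0.0

    def test_units_consistent(self):
        assert ctr_per_myr(1.0, 10.0) == pytest.approx(
            consensus_turnover_rate(1.0, 10e6) * 1e6)

    def test_domain_validation(self):
        with pytest.raises(InvalidInputError):
            consensus_turnover_rate(1.0, 0.0)
        with pytest.raises(InvalidInputError):
            consensus_turnover_rate(-1.0, 1e6)


class TestFindConserved:
    def test_identical_catalogs_fully_matched(self):
        rng = np.random.default_rng(1)
        seqs = [random_dna(120, rng) for _ in range(4)]
        found = find_conserved(_catalog(seqs, "Aaa"), _catalog(seqs, "Bbb"))
        assert len(found.pairs) == 4
        assert all(p.similarity == 100.0 for p in found.pairs)
        assert found.private_a == [] and found.private_b == []

    def test_moderate_drift_scenario_exact_pairs(self):
        """5 shared + 3 private per species, moderate drift: 5 pairs."""
        truth = st.ScenarioTruth(
            species_labels=["Aaa", "Bbb"],
            divergence_time_years={("Aaa", "Bbb"): 5e6},
            substitution_rate=1.85e-8,
            shared_family_labels=["s1", "s2", "s3", "s4", "s5"],
            private_family_labels={"Aaa": ["pa1", "pa2", "pa3"],
                                   "Bbb": ["pb1", "pb2", "pb3"]},
        )
        scen = st.make_species_scenario(truth, seed=5)
        found = find_conserved(scen.catalogs["Aaa"], scen.catalogs["Bbb"])
        assert len(found.pairs) == 5
        assert len(found.private_a) == 3 and len(found.private_b) == 3
        origins = scen.family_origins
        for p in found.pairs:
            assert origins["Aaa"][p.family_a.name] == \
                origins["Bbb"][p.family_b.name]

    def test_heavy_drift_counted_private(self):
        """A shared family drifted beyond recognition becomes private."""
        truth = st.ScenarioTruth(
            species_labels=["Aaa", "Bbb"],
            divergence_time_years={("Aaa", "Bbb"): 4e7},
            substitution_rate=2e-7,            # ~16 substitutions per site
            shared_family_labels=["s1"],
            private_family_labels={},
        )
        scen = st.make_species_scenario(truth, seed=3)
        found = find_conserved(scen.catalogs["Aaa"], scen.catalogs["Bbb"])
        assert found.pairs == []
        assert len(found.private_a) == 1 and len(found.private_b) == 1

    def test_one_to_one_matching(self):
        """Greedy resolution never assigns a family to two partners."""
        rng = np.random.default_rng(2)
        s = random_dna(100, rng)
        cat_a = _catalog([s], "Aaa")
        cat_b = _catalog([s, s[1:] + s[:1]], "Bbb")
        found = find_conserved(cat_a, cat_b)
        assert len(found.pairs) == 1
        assert len(found.conflicts) >= 1
        many = find_conserved(cat_a, cat_b, allow_many_to_one=True)
        assert len(many.pairs) == 2

    def test_empty_catalog_rejected(self):
        with pytest.raises(EmptyCatalogError):
            find_conserved([], [])


class TestFillDistances:
    def test_missing_time_is_config_error(self):
        rng = np.random.default_rng(3)
        s = random_dna(80, rng)
        pair = find_conserved(_catalog([s], "Aaa"),
                              _catalog([s], "Bbb")).pairs
        with pytest.raises(ConfigError):
            st.fill_distances(pair, {("Aaa", "Ccc"): 1e6})

    def test_zero_drift_zero_everything(self):
        rng = np.random.default_rng(4)
        s = random_dna(80, rng)
        pairs = find_conserved(_catalog([s], "Aaa"),
                               _catalog([s], "Bbb")).pairs
        filled = st.fill_distances(pairs, {("Aaa", "Bbb"): 4e7})
        assert filled[0].k == 0.0
        assert filled[0].ctr_per_myr == 0.0

    def test_ctr_symmetric_in_species_order(self):
        rng = np.random.default_rng(5)
        anc = random_dna(150, rng)
        der = st.evolve_sequence(anc, 2e-9, 4e7, seed=9)
        cat_a, cat_b = _catalog([anc], "Aaa"), _catalog([der], "Bbb")
        times = {("Aaa", "Bbb"): 4e7}
        ab = st.fill_distances(find_conserved(cat_a, cat_b).pairs, times)
        ba = st.fill_distances(find_conserved(cat_b, cat_a).pairs, times)
        assert ab[0].ctr_per_myr == pytest.approx(ba[0].ctr_per_myr)


class TestSummaries:
    def test_single_pair_summary(self):
        rng = np.random.default_rng(6)
        anc = random_dna(200, rng)
        der = st.evolve_sequence(anc, 1e-9, 4e7, seed=2)
        pairs = st.fill_distances(
            find_conserved(_catalog([anc], "Aaa"),
                           _catalog([der], "Bbb")).pairs,
            {("Aaa", "Bbb"): 4e7})
        summaries, overall = st.summarize_pairs(pairs)
        assert len(summaries) == 1
        assert summaries[0].n_pairs == 1
        assert summaries[0].k2p_sd == 0.0
        assert overall.k2p_mean == pytest.approx(pairs[0].k)

    def test_bookkeeping_mean_is_exact(self):
        """30 synthetic distances: group and overall means are exact."""
        rng = np.random.default_rng(7)
        pairs = []
        values = []
        for i in range(30):
            prefix_b = ("Bbb", "Ccc")[i % 2]
            anc = random_dna(300, rng)
            pair = find_conserved(_catalog([anc], "Aaa"),
                                  _catalog([anc], prefix_b)).pairs[0]
            filled = st.fill_distances(
                [pair], {("Aaa", "Bbb"): 4e7, ("Aaa", "Ccc"): 3e7})[0]
            pairs.append(filled)
            values.append(filled.k)
        _, overall = st.summarize_pairs(pairs)
        assert overall.k2p_mean == pytest.approx(np.mean(values))
        assert overall.n_pairs == 30

    def test_ctr_parameter_recovery(self, serrasalmid_scenario):
        """Three-species drift at 1.85e-8/site/yr: CTR within +/-25%."""
        scen, truth = serrasalmid_scenario
        pairs = []
        for a, b in (("Myl", "Col"), ("Myl", "Pia"), ("Col", "Pia")):
            pairs.extend(st.pairs_from_scenario(scen, a, b))
        assert len(pairs) == 18                # 6 shared x 3 species pairs
        filled = st.fill_distances(pairs, truth.divergence_time_years)
        summaries, overall = st.summarize_pairs(filled)
        planted = truth.substitution_rate
        assert overall.ctr_mean * 1e-6 == pytest.approx(planted, rel=0.25)
        for s in summaries:
            assert s.ctr_mean * 1e-6 == pytest.approx(planted, rel=0.25)


class TestThreeWay:
    def test_subset_sharing_counts(self):
        """3 families in all species, 2 with B only, 1 with C only."""
        truth = st.ScenarioTruth(
            species_labels=["Aaa", "Bbb", "Ccc"],
            divergence_time_years={("Aaa", "Bbb"): 5e6,
                                   ("Aaa", "Ccc"): 5e6,
                                   ("Bbb", "Ccc"): 3e6},
            substitution_rate=1e-8,
            shared_family_labels={
                "x1": ("Aaa", "Bbb", "Ccc"), "x2": ("Aaa", "Bbb", "Ccc"),
                "x3": ("Aaa", "Bbb", "Ccc"), "y1": ("Aaa", "Bbb"),
                "y2": ("Aaa", "Bbb"), "z1": ("Aaa", "Ccc")},
            private_family_labels={"Aaa": ["pa"], "Bbb": ["pb"],
                                   "Ccc": ["pc"]},
        )
        scen = st.make_species_scenario(truth, seed=11)
        table = three_way_table(scen.catalogs)
        assert table.shared_with_both == 3
        assert table.shared_with_exactly_one == 3

    def test_disjoint_catalogs_all_dashes(self):
        rng = np.random.default_rng(8)
        catalogs = {p: _catalog([random_dna(150, rng)], p)
                    for p in ("Aaa", "Bbb", "Ccc")}
        table = three_way_table(catalogs)
        assert table.shared_with_both == 0
        assert table.shared_with_exactly_one == 0
        assert all(m1 is None and m2 is None for _, m1, m2 in table.rows)

    def test_identical_catalogs_full_matrix(self):
        rng = np.random.default_rng(9)
        seqs = [random_dna(90, rng) for _ in range(3)]
        catalogs = {p: _catalog(seqs, p) for p in ("Aaa", "Bbb", "Ccc")}
        table = three_way_table(catalogs)
        assert table.shared_with_both == 3
        assert all(s == 100.0 for s in table.similarities.values())
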