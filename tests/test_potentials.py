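"""Statistical-potential construction, smoothing, redundancy filtering and
Z-score scoring."""

import numpy as np
import pytest

from structmotif.contacts import (ALL_CLASSES, AA_ALPHABET, ContactTable,
                                  DINUCLEOTIDES, extract_contacts)
from structmotif.fixtures import closed_loop_fixture
from structmotif.potentials import (FamilyConfig, Potential,
                                    _log_odds_scores, build_potential,
                                    contact_identity, filter_redundancy,
                                    load_family_configs, score_complex,
                                    taylor_smooth, taylor_smooth_counts,
                                    zscore_contact)


def _uniform_table(count=2.0, distance=5.0):
    table = ContactTable()
    for aa in AA_ALPHABET:
        for dn in DINUCLEOTIDES:
            for env in ALL_CLASSES:
                table.add_record(aa, dn, env, distance, "pdb", count)
    return table


class TestBuild:
    def test_uniform_table_gives_flat_scores(self):
        pot = build_potential(_uniform_table(),
                              FamilyConfig(binning="bins", radius=30.0,
                                           contacts_db="pdb"))
        bin5 = pot.scores[:, :, :, 4]
        assert np.allclose(bin5, bin5.flat[0])

    def test_enriched_triple_has_minimum_score(self):
        table = _uniform_table()
        env = ALL_CLASSES[7]
        table.add_record("R", "AC", env, 5.0, "pdb", 18.0)  # 10x enriched
        pot = build_potential(table, FamilyConfig(binning="bins",
                                                  radius=30.0,
                                                  contacts_db="pdb"))
        bin5 = pot.scores[:, :, :, 4]
        assert bin5.min() == pot.score("R", "AC", env, 4.5)

    def test_cumulative_equals_summed_interval_bins(self):
        rng = np.random.default_rng(6)
        table = ContactTable()
        for _ in range(300):
            table.add_record(AA_ALPHABET[rng.integers(20)],
                             DINUCLEOTIDES[rng.integers(16)],
                             ALL_CLASSES[rng.integers(48)],
                             float(rng.uniform(0.5, 21.9)), "pdb")
        cfg = FamilyConfig(binning="acc", radius=22.0, contacts_db="pdb")
        pot_acc = build_potential(table, cfg)
        # independent construction: sum interval bins up to the radius
        interval = table.counts("pdb")[:, :, :, :22]
        summed = interval.sum(axis=3, keepdims=True)
        expected = _log_odds_scores(summed)
        np.testing.assert_allclose(pot_acc.scores, expected)

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            Potential(np.zeros((20, 16, 48, 30)))

    def test_json_round_trip(self):
        pot = build_potential(_uniform_table(),
                              FamilyConfig(binning="acc", radius=15.0,
                                           contacts_db="pdb"))
        back = Potential.from_json(pot.to_json())
        np.testing.assert_allclose(back.scores, pot.scores)
        assert back.binning == "acc" and back.max_radius == 15.0


class TestTaylorSmoothing:
    def _counts(self, profile):
        counts = np.zeros((1, 1, 1, len(profile)))
        counts[0, 0, 0, :] = profile
        return counts

    def test_fully_observed_profile_unchanged(self):
        counts = self._counts([3.0, 5.0, 2.0, 8.0])
        np.testing.assert_array_equal(taylor_smooth_counts(counts), counts)

    def test_hole_between_equal_bins_imputed_to_that_value(self):
        counts = self._counts([4.0, 0.0, 4.0])
        out = taylor_smooth_counts(counts)
        assert out[0, 0, 0, 1] == pytest.approx(4.0, abs=1e-9)
        assert out[0, 0, 0, 0] == 4.0 and out[0, 0, 0, 2] == 4.0

    def test_planted_quadratic_recovered_through_hole(self):
        x = np.arange(10.0)
        log_y = 0.3 + 0.25 * x - 0.02 * x ** 2  # planted polynomial
        profile = np.exp(log_y)
        profile[4] = 0.0  # hole
        out = taylor_smooth_counts(self._counts(profile))
        assert out[0, 0, 0, 4] == pytest.approx(np.exp(log_y[4]), abs=1e-6)

    def test_observed_bins_never_overwritten(self):
        rng = np.random.default_rng(2)
        counts = rng.uniform(0, 4, size=(3, 4, 2, 8))
        counts[counts < 1.0] = 0.0
        out = taylor_smooth_counts(counts)
        mask = counts > 0
        np.testing.assert_array_equal(out[mask], counts[mask])
        assert np.all(out[~mask] >= 0)

    def test_smoothed_potential_flag(self):
        table = _uniform_table()
        pot = build_potential(table, FamilyConfig(binning="bins",
                                                  radius=30.0,
                                                  contacts_db="pdb"))
        assert taylor_smooth(pot).smoothing is True


class TestRedundancyFilter:
    def _table_with_cells(self, cells, weight=1.0):
        """Cells are integers < 9600 mapped injectively to table entries."""
        table = ContactTable()
        for i in cells:
            table.add_record(AA_ALPHABET[i % 20],
                             DINUCLEOTIDES[(i // 20) % 16],
                             ALL_CLASSES[0],
                             (i // 320) % 30 + 0.5, "pdb", weight)
        return table

    def test_identical_tfs_keep_one(self):
        a = self._table_with_cells(range(20))
        b = self._table_with_cells(range(20))
        assert filter_redundancy({"A": a, "B": b}, mode="family") == ["A"]

    def test_disjoint_tfs_all_kept(self):
        tables = {"A": self._table_with_cells(range(0, 20)),
                  "B": self._table_with_cells(range(20, 40)),
                  "C": self._table_with_cells(range(40, 60))}
        assert sorted(filter_redundancy(tables, "family")) == ["A", "B", "C"]

    def test_greedy_chain_keeps_a_and_c(self):
        # A~B at 75%, B~C at 75%, A~C at 10%; cutoff 0.70
        a = self._table_with_cells(range(0, 20), weight=3.0)  # visited first
        b = self._table_with_cells(list(range(5, 20)) + list(range(100, 105)),
                                   weight=2.0)
        c = self._table_with_cells([18, 19] + list(range(101, 104)) +
                                   list(range(200, 215)))
        fa, fb, fc = (t.fingerprint() for t in (a, b, c))
        assert contact_identity(fa, fb) == pytest.approx(0.75)
        assert contact_identity(fa, fc) == pytest.approx(0.10)
        assert filter_redundancy({"A": a, "B": b, "C": c},
                                 "family") == ["A", "C"]

    def test_general_mode_uses_lower_cutoff(self):
        a = self._table_with_cells(range(0, 20), weight=2.0)
        b = self._table_with_cells(list(range(10, 20)) + list(range(50, 60)))
        assert filter_redundancy({"A": a, "B": b}, "family") == ["A", "B"]
        assert filter_redundancy({"A": a, "B": b}, "general") == ["A"]

    def test_idempotent(self):
        tables = {"A": self._table_with_cells(range(0, 30), weight=3.0),
                  "B": self._table_with_cells(range(10, 40), weight=2.0),
                  "C": self._table_with_cells(range(35, 70))}
        kept = filter_redundancy(tables, "family")
        again = filter_redundancy({k: tables[k] for k in kept}, "family")
        assert again == kept


class TestZScores:
    def test_flat_context_gives_zero_z(self):
        pot = build_potential(_uniform_table(),
                              FamilyConfig(binning="bins", radius=30.0,
                                           contacts_db="pdb"))
        assert np.allclose(pot.zscores[:, :, :, 4], 0.0)

    def test_z_has_mean_zero_sd_one_over_substitutions(self, closed_loop):
        _, _, table, _ = closed_loop
        pot = build_potential(table, FamilyConfig(binning="bins",
                                                  radius=30.0,
                                                  contacts_db="pdb"))
        z = pot.zscores
        sd = pot.scores.std(axis=0)
        live = sd > 0
        mean_over_aa = z.mean(axis=0)
        sd_over_aa = z.std(axis=0)
        assert np.allclose(mean_over_aa[live], 0.0, atol=1e-9)
        assert np.allclose(sd_over_aa[live], 1.0, atol=1e-9)

    def test_z_matches_hand_computed_formula(self, closed_loop):
        _, contacts, table, _ = closed_loop
        pot = build_potential(table, FamilyConfig(binning="bins",
                                                  radius=30.0,
                                                  contacts_db="pdb"))
        c = contacts[0]
        from structmotif.contacts import aa_index, class_index, dinuc_index
        s = pot.scores[:, dinuc_index(c.dinucleotide),
                       class_index(c.env), pot.bin_of(c.distance)]
        expected = (s[aa_index(c.aa)] - s.mean()) / s.std()
        assert zscore_contact(pot, c) == pytest.approx(expected)


class TestComplexScore:
    def test_empty_contact_list_scores_zero(self):
        pot = build_potential(_uniform_table(),
                              FamilyConfig(binning="bins", radius=30.0,
                                           contacts_db="pdb"))
        assert score_complex(pot, []) == {"ES3DC_dd": 0.0, "ZES3DC_dd": 0.0}

    def test_additive_over_disjoint_subsets(self, closed_loop):
        _, contacts, table, _ = closed_loop
        pot = build_potential(table, FamilyConfig(binning="bins",
                                                  radius=30.0,
                                                  contacts_db="pdb"))
        whole = score_complex(pot, contacts)
        part1 = score_complex(pot, contacts[:3])
        part2 = score_complex(pot, contacts[3:])
        for key in whole:
            assert whole[key] == pytest.approx(part1[key] + part2[key])

    def test_single_contact_equals_its_score(self, closed_loop):
        _, contacts, table, _ = closed_loop
        pot = build_potential(table, FamilyConfig(binning="bins",
                                                  radius=30.0,
                                                  contacts_db="pdb"))
        c = contacts[0]
        res = score_complex(pot, [c])
        assert res["ES3DC_dd"] == pytest.approx(
            pot.score(c.aa, c.dinucleotide, c.env, c.distance))


class TestFamilyConfigs:
    def test_default_config_table_loads(self):
        cfgs = load_family_configs()
        assert "general" in cfgs and "Homeodomain" in cfgs
        hd = cfgs["Homeodomain"]
        assert (hd.contacts_db, hd.specificity, hd.taylor, hd.binning,
                hd.radius, hd.threshold) == ("pbm", "family", False, "acc",
                                             22.0, 0.84)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            FamilyConfig(radius=17.0)

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            FamilyConfig(threshold=0.5)
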