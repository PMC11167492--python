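"""PBM 8-mer classification, placement into the binding site and contact
transfer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from structmotif.contacts import ContactTable, extract_contacts
from structmotif.fixtures import (FixtureSpec, PbmSpec, PlantedContact,
                                  make_complex, make_pbm)
from structmotif.pbm import (HomologMap, PbmExperiment, align_8mer_to_site,
                             build_homolog_map, classify_8mers,
                             extend_contacts, placement_score_floor,
                             read_pbm, sequence_identity)
from structmotif.pwm import Pwm, reverse_complement
from structmotif.structure import parse_complex


def _peaked_pwm(consensus, p=0.9):
    m = np.full((len(consensus), 4), (1 - p) / 3)
    for j, b in enumerate(consensus):
        m[j, "ACGT".index(b)] = p
    return Pwm(m, id="peaked")


class TestClassification:
    def test_thresholds_at_045_and_037(self):
        exp = PbmExperiment("tf", {"AAAAAAAA": 0.46, "CCCCCCCC": 0.30,
                                   "GGGGGGGG": 0.40})
        pos, neg, disc = classify_8mers(exp)
        assert pos == {"AAAAAAAA"}
        assert neg == {"CCCCCCCC"}
        assert disc == {"GGGGGGGG"}

    def test_all_at_max_score_are_positive(self):
        exp = PbmExperiment("tf", {k: 0.50 for k in
                                   ("AAAAAAAA", "ACGTACGT")})
        pos, neg, disc = classify_8mers(exp)
        assert len(pos) == 2 and not neg and not disc

    def test_empty_experiment_gives_three_empty_sets(self):
        pos, neg, disc = classify_8mers(PbmExperiment("tf", {}))
        assert pos == neg == disc == set()

    def test_boundary_scores_are_discarded(self):
        exp = PbmExperiment("tf", {"AAAAAAAA": 0.45, "CCCCCCCC": 0.37})
        pos, neg, disc = classify_8mers(exp)
        assert disc == {"AAAAAAAA", "CCCCCCCC"}

    @given(st.lists(st.floats(min_value=-0.5, max_value=0.5,
                              allow_nan=False), min_size=0, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_classes_partition_the_records(self, scores):
        kmers = {"".join("ACGT"[(i >> (2 * j)) & 3] for j in range(8)): s
                 for i, s in enumerate(scores)}
        exp = PbmExperiment("tf", kmers)
        pos, neg, disc = classify_8mers(exp)
        assert pos | neg | disc == set(kmers)
        assert not (pos & neg or pos & disc or neg & disc)

    def test_out_of_range_escore_rejected(self):
        with pytest.raises(ValueError):
            PbmExperiment("tf", {"AAAAAAAA": 0.51})

    def test_read_pbm_tolerates_header_and_extra_columns(self):
        text = "8mer\tE-score\nACGTACGT\t0.47\textra\nTTTTAAAA\t-0.2\n"
        exp = read_pbm(text)
        assert exp.records == {"ACGTACGT": 0.47, "TTTTAAAA": -0.2}


class TestPlacement:
    def test_consensus_selfmatch_at_offset_zero_forward(self):
        pwm = _peaked_pwm("ACGTACGT")
        pl = align_8mer_to_site("ACGTACGT", pwm, "ACGTACGT")
        assert pl.offset == 0 and pl.strand == "+"
        assert pl.placed_sequence == "ACGTACGT"

    def test_reverse_complement_placed_on_minus_strand(self):
        pwm = _peaked_pwm("ACGTACGG")
        rc = reverse_complement("ACGTACGG")
        pl = align_8mer_to_site(rc, pwm, "ACGTACGG")
        assert pl.strand == "-"
        assert pl.placed_sequence == "ACGTACGG"

    def test_site_length_mismatch_is_error(self):
        pwm = _peaked_pwm("ACGTACGT")
        with pytest.raises(ValueError, match="length"):
            align_8mer_to_site("ACGTACGT", pwm, "ACGTACGTAA")

    def test_matches_exhaustive_placement_oracle(self):
        rng = np.random.default_rng(4)
        site = "".join("ACGT"[i] for i in rng.integers(0, 4, 12))
        pwm = _peaked_pwm(site)
        for _ in range(20):
            kmer = "".join("ACGT"[i] for i in rng.integers(0, 4, 8))
            pl = align_8mer_to_site(kmer, pwm, site)
            # independent enumeration of all offsets x strands
            best = max(
                (sum(np.log(pwm.matrix[o + i, "ACGT".index(b)] + 1e-9)
                     for i, b in enumerate(seq)), strand == "+", -o)
                for strand, seq in (("+", kmer),
                                    ("-", reverse_complement(kmer)))
                for o in range(pwm.width - 7))
            assert pl.score == pytest.approx(best[0], abs=1e-9)

    def test_floor_rejects_poor_placements(self):
        pwm = _peaked_pwm("AAAAAAAA", p=0.97)
        floor = placement_score_floor(pwm)
        assert align_8mer_to_site("CCCCCCCC", pwm, "AAAAAAAA",
                                  floor=floor) is None
        assert align_8mer_to_site("AAAAAAAA", pwm, "AAAAAAAA",
                                  floor=floor) is not None


class TestHomologMapping:
    def test_identity_map_covers_every_residue(self):
        m = HomologMap.identity("tf", "MKRQW")
        assert m.mapping == {0: "M", 1: "K", 2: "R", 3: "Q", 4: "W"}
        assert not m.interface_gap

    def test_gap_inside_interface_invalidates_map(self):
        template = "MKRLLQWFDESA"
        target = "MKRQWFDESA"  # two-residue deletion at positions 3-4
        m = build_homolog_map("t", template, "h", target,
                              interface_positions=[3, 4])
        assert m.interface_gap

    def test_gap_outside_interface_is_tolerated(self):
        template = "MKRLLQWFDESA"
        target = "MKRQWFDESA"
        m = build_homolog_map("t", template, "h", target,
                              interface_positions=[8, 9])
        assert not m.interface_gap

    def test_sequence_identity_of_point_mutant(self):
        a = "MKRQWFDESAMKRQWFDESA"
        b = a[:10] + "G" + a[11:]
        assert sequence_identity(a, b) == pytest.approx(95.0)


class TestExtension:
    def _template(self):
        planted = [PlantedContact(k, k, 6.5 + k, aa="RKDE"[k % 4])
                   for k in range(7)]
        spec = FixtureSpec(seed=11, n_residues=7, dna_length=8,
                           dna_sequence="ACGTACGT",
                           planted_contacts=planted)
        cx = parse_complex(make_complex(spec))
        contacts = [c for c in extract_contacts(cx, 30.0)
                    if c.distance < 7.6 + c.step_index
                    and c.distance > 5.4 + c.step_index]
        return cx, contacts

    def test_identity_extension_duplicates_template_counts(self):
        cx, contacts = self._template()
        pwm = _peaked_pwm(cx.dna_sequence)
        idmap = HomologMap.identity("tf", "A" * 10)
        # map template residues by their contact order
        idmap.mapping = {i: c.aa for i, c in enumerate(contacts)}
        table = ContactTable()
        placements = [align_8mer_to_site(cx.dna_sequence, pwm,
                                         cx.dna_sequence)] * 3
        added = extend_contacts(contacts, placements, [idmap], table)
        assert added == 3 * len(contacts)
        assert table.counts("pbm").sum() == added
        assert table.counts("pdb").sum() == 0

    def test_gapped_map_contributes_nothing(self):
        cx, contacts = self._template()
        pwm = _peaked_pwm(cx.dna_sequence)
        gapped = HomologMap("t", "h", {}, interface_gap=True)
        table = ContactTable()
        pl = align_8mer_to_site(cx.dna_sequence, pwm, cx.dna_sequence)
        assert extend_contacts(contacts, [pl], [gapped], table) == 0

    def test_variable_position_diversifies_only_its_step(self):
        cx, contacts = self._template()
        pwm = _peaked_pwm(cx.dna_sequence)
        idmap = HomologMap.identity("tf", "A" * 10)
        idmap.mapping = {i: c.aa for i, c in enumerate(contacts)}
        kmers = [cx.dna_sequence[:4] + b + cx.dna_sequence[5:]
                 for b in "ACGT"]  # vary only position 4 (steps 3 and 4)
        table = ContactTable()
        placements = [align_8mer_to_site(k, pwm, cx.dna_sequence)
                      for k in kmers]
        extend_contacts(contacts, placements, [idmap], table)
        arr = table.counts("pbm")
        # steps other than 3/4 contribute one dinucleotide each; the
        # varied position yields 4 distinct dinucleotides at its steps
        per_dinuc = (arr.sum(axis=(0, 2, 3)) > 0)
        assert per_dinuc.sum() > len(set(
            cx.dna_sequence[k:k + 2] for k in range(7)))

    def test_extension_never_removes_pdb_counts(self):
        cx, contacts = self._template()
        table = ContactTable()
        table.add_contacts(contacts, "pdb")
        before = table.counts("pdb").copy()
        pwm = _peaked_pwm(cx.dna_sequence)
        idmap = HomologMap.identity("tf", "A" * 10)
        idmap.mapping = {i: c.aa for i, c in enumerate(contacts)}
        pl = align_8mer_to_site(cx.dna_sequence, pwm, cx.dna_sequence)
        extend_contacts(contacts, [pl], [idmap], table)
        np.testing.assert_array_equal(table.counts("pdb"), before)
        assert table.total > before.sum()


class TestPbmFixture:
    def test_classification_recovers_planted_partition(self):
        pwm = _peaked_pwm("ACGTGCAT")
        spec = PbmSpec(seed=3, n_positive=12, n_negative=40, n_discarded=5)
        exp = make_pbm(spec, pwm)
        pos, neg, disc = classify_8mers(exp)
        assert (len(pos), len(neg), len(disc)) == (12, 40, 5)
        assert pwm.consensus in pos

    def test_zero_positive_spec(self):
        pwm = _peaked_pwm("ACGTGCAT")
        exp = make_pbm(PbmSpec(seed=3, n_positive=0, n_negative=5), pwm)
        pos, _, _ = classify_8mers(exp)
        assert pos == set()
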