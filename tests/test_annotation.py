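"""Reference loading, isoform classification, closest-family matching."""

import pandas as pd
import pytest

from mirisoform import (
    ReferenceSet,
    annotate_sequence,
    closest_family_counts,
    family_report,
    load_reference,
)
from mirisoform.annotation import (
    ENTRY_ISOFORM,
    HAIRPIN_ISOFORM,
    UNCHARACTERIZED,
    best_occurrence,
    match_mature_names,
)
from mirisoform.isoform_counting import IsoformCountMatrix
from tests.conftest import make_read


def oracle_best_occurrence(needle, hay, max_mm):
    """Naive all-offsets scanner; N matches nothing."""
    best = None
    for offset in range(len(hay) - len(needle) + 1):
        mm = sum(a != b or a == "N" or b == "N"
                 for a, b in zip(needle, hay[offset:offset + len(needle)]))
        if mm <= max_mm and (best is None or mm < best[0]):
            best = (mm, offset)
    return best


def oracle_matches(seq, ref_seq, max_mm):
    if len(seq) <= len(ref_seq):
        return oracle_best_occurrence(seq, ref_seq, max_mm) is not None
    return oracle_best_occurrence(ref_seq, seq, max_mm) is not None


class TestLoadReference:
    def test_rna_fasta_canonicalized(self, tmp_path):
        mature = tmp_path / "mature.fa"
        mature.write_text(">hsa-miR-30e-5p\nuguaaacauccuugacuggaag\n")
        ref = load_reference(mature)
        assert ref.mature["hsa-miR-30e-5p"] == "TGTAAACATCCTTGACTGGAAG"

    def test_duplicate_names_rejected(self, tmp_path):
        mature = tmp_path / "dup.fa"
        mature.write_text(">x\nACGT\n>x\nACGG\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_reference(mature)

    def test_empty_fasta_rejected(self, tmp_path):
        empty = tmp_path / "empty.fa"
        empty.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            load_reference(empty)

    def test_mixed_case_uppercased(self, tmp_path):
        mature = tmp_path / "m.fa"
        mature.write_text(">x\nacgTGca\n")
        assert load_reference(mature).mature["x"] == "ACGTGCA"


class TestAnnotateSequence:
    def test_exact_entry_sequence(self, tiny_reference):
        seq = tiny_reference.mature["mir-alpha-5p"]
        record = annotate_sequence(seq, tiny_reference)
        assert record.status == ENTRY_ISOFORM
        assert record.matched_names == ("mir-alpha-5p",)
        assert record.n_mismatches_best == 0

    def test_templated_3prime_extension_is_entry_isoform(self, tiny_reference):
        seq = tiny_reference.mature["mir-alpha-5p"] + "C"
        assert annotate_sequence(seq, tiny_reference).status == ENTRY_ISOFORM

    def test_shorter_trimmed_isoform_is_entry_isoform(self, tiny_reference):
        seq = tiny_reference.mature["mir-alpha-5p"][:-3]
        assert annotate_sequence(seq, tiny_reference).status == ENTRY_ISOFORM

    def test_hairpin_interior_with_one_substitution(self, tiny_reference):
        hairpin = tiny_reference.hairpins["mir-alpha"]
        window = hairpin[30:50]
        mutated = window[:7] + ("A" if window[7] != "A" else "C") + window[8:]
        record = annotate_sequence(mutated, tiny_reference,
                                   max_hairpin_mismatch=1)
        assert record.status == HAIRPIN_ISOFORM
        assert record.n_mismatches_best == 1
        assert oracle_best_occurrence(mutated, hairpin, 1) is not None

    def test_unrelated_sequence_uncharacterized(self, tiny_reference):
        record = annotate_sequence("GCGCGCGCGCGCGCGCGCGC", tiny_reference)
        assert record.status == UNCHARACTERIZED
        assert record.matched_names == ()

    def test_adding_hairpins_never_changes_entry_status(self, tiny_reference):
        seq = tiny_reference.mature["mir-beta-3p"][2:]
        with_hp = annotate_sequence(seq, tiny_reference)
        without_hp = annotate_sequence(
            seq, ReferenceSet(dict(tiny_reference.mature), {}))
        assert with_hp.status == without_hp.status == ENTRY_ISOFORM

    def test_uncharacterized_shrinks_as_references_grow(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(50)]
        small = ReferenceSet({"a": seqs[0]}, {})
        large = ReferenceSet({"a": seqs[0], "b": seqs[1]},
                             {"hp": seqs[2] + seqs[3]})
        unchar_small = {s for s in seqs
                        if annotate_sequence(s, small).status == UNCHARACTERIZED}
        unchar_large = {s for s in seqs
                        if annotate_sequence(s, large).status == UNCHARACTERIZED}
        assert unchar_large <= unchar_small


def test_best_occurrence_matches_oracle_on_random_pairs(rng):
    bases = list("ACGTN")
    for _ in range(1000):
        needle_len = int(rng.integers(5, 25))
        hay_len = int(rng.integers(needle_len, 60))
        probs = [0.24, 0.24, 0.24, 0.24, 0.04]
        needle = "".join(rng.choice(bases, needle_len, p=probs))
        hay = "".join(rng.choice(bases, hay_len, p=probs))
        if rng.random() < 0.5:  # plant a near-match so hits are frequent
            pos = int(rng.integers(0, hay_len - needle_len + 1))
            planted = list(needle)
            for p in rng.choice(needle_len, int(rng.integers(0, 3)),
                                replace=False):
                planted[p] = str(rng.choice(list("ACGT")))
            hay = hay[:pos] + "".join(planted) + hay[pos + needle_len:]
        max_mm = int(rng.integers(0, 3))
        got = best_occurrence(needle, hay, max_mm)
        want = oracle_best_occurrence(needle, hay, max_mm)
        if want is None:
            assert got is None
        else:
            assert got is not None and got[0] == want[0]


class TestClosestFamilyCounts:
    def test_read_identical_to_one_entry(self, tiny_reference):
        read = make_read(tiny_reference.mature["mir-beta-3p"])
        counts, n_mapped = closest_family_counts([read], tiny_reference, 1)
        assert n_mapped == 1
        assert counts["mir-beta-3p"] == 1

    def test_straddling_read_credits_both_family_members(self, mir30):
        ref, _reads, _ratio = mir30
        # 30a and 30e entries differ by a single base, so a read equal to
        # the 30e entry matches both under a 1-mismatch tolerance
        read_30e = ref.mature["hsa-miR-30e-5p"]
        names = set(match_mature_names(read_30e, ref, max_mismatch=1))
        assert {"hsa-miR-30e-5p", "hsa-miR-30a-5p"} <= names
        assert all(oracle_matches(read_30e, ref.mature[n], 1) for n in names)
        counts, n_mapped = closest_family_counts(
            [make_read(read_30e)], ref, 1)
        assert n_mapped == 1
        assert counts["hsa-miR-30e-5p"] == counts["hsa-miR-30a-5p"] == 1

    def test_unmatched_read_not_counted(self, tiny_reference):
        counts, n_mapped = closest_family_counts(
            [make_read("GCGCGCGCGCGCGCGCGCGC")], tiny_reference, 1)
        assert n_mapped == 0 and not counts

    def test_zero_mismatch_on_exact_entry_reads_reproduces_tally(
            self, tiny_reference):
        reads = ([make_read(tiny_reference.mature["mir-alpha-5p"])] * 5
                 + [make_read(tiny_reference.mature["mir-beta-3p"])] * 3)
        counts, n_mapped = closest_family_counts(reads, tiny_reference, 0)
        assert counts["mir-alpha-5p"] == 5
        assert counts["mir-beta-3p"] == 3
        assert n_mapped == 8


class TestFamilyReport:
    def test_fixture_isoforms_match_bruteforce_scanner(self, mir30, rng):
        ref, _reads, _ratio = mir30
        # 20 generated isoforms around the family entries
        isoforms = []
        for _ in range(20):
            name = list(ref.mature)[int(rng.integers(0, 4))]
            entry = ref.mature[name]
            start = int(rng.integers(0, 3))
            end = len(entry) - int(rng.integers(0, 3))
            iso = list(entry[start:end])
            if rng.random() < 0.5:
                p = int(rng.integers(0, len(iso)))
                iso[p] = str(rng.choice(list("ACGT")))
            isoforms.append("".join(iso))
        isoforms = sorted(set(isoforms))
        frame = pd.DataFrame({"s1": [1] * len(isoforms)}, index=isoforms)
        matrix = IsoformCountMatrix(frame, pd.Series({"s1": 100}))
        report = family_report(matrix, ref, max_mismatch=1)
        for _, row in report.iterrows():
            got = set(row["family_members"].split(";")) - {""}
            want = {n for n, e in ref.mature.items()
                    if oracle_matches(row["sequence"], e, 1)}
            assert got == want

    def test_single_unambiguous_sequence(self, tiny_reference):
        seq = tiny_reference.mature["mir-alpha-5p"]
        matrix = IsoformCountMatrix(
            pd.DataFrame({"s1": [2]}, index=[seq]), pd.Series({"s1": 10}))
        report = family_report(matrix, tiny_reference)
        assert len(report) == 1
        assert not report.iloc[0]["ambiguous"]

    def test_empty_matrix_empty_report(self, tiny_reference):
        matrix = IsoformCountMatrix(
            pd.DataFrame({"s1": []}, index=pd.Index([], dtype=object),
                         dtype="int64"),
            pd.Series({"s1": 10}))
        assert len(family_report(matrix, tiny_reference)) == 0


def test_n_in_read_never_matches_reference(tiny_reference):
    entry = tiny_reference.mature["mir-alpha-5p"]
    with_n = "N" + entry[1:]
    record = annotate_sequence(with_n, tiny_reference,
                               max_hairpin_mismatch=0)
    assert record.status != ENTRY_ISOFORM
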