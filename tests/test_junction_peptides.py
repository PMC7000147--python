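"""Junction windows, three-frame translation, database assembly, decoys."""

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq

from splicescope import (
    DatabaseEntry,
    JunctionPeptide,
    JunctionWindow,
    SpliceJunction,
    assemble_database,
    build_junction_entries,
    dedupe_entries,
    extract_window,
    make_decoys,
    translate_novel_region,
    translate_window,
    validate_junction_peptide,
    windows_for_junction,
)
from tests.conftest import codon_free_of_stops


def revcomp(s):
    return str(Seq(s).reverse_complement())


@pytest.fixture()
def genome(stopfree_seq):
    return {"chr1": stopfree_seq}


# intron placed on a codon boundary so frame 0 of the window stays in the
# stop-free reading frame of the backbone sequence
JUNC = SpliceJunction("chr1", 301, 600, "+", unique_reads=50)


class TestWindowExtraction:
    def test_interior_window_geometry(self, genome):
        w = extract_window(JUNC, genome, "+", flank=66)
        assert len(w.window) == 132
        assert w.junction_offset_nt == 66
        assert not w.clipped
        assert w.window == genome["chr1"][234:300] + genome["chr1"][600:666]

    def test_clipped_at_chromosome_start(self, genome):
        j = SpliceJunction("chr1", 11, 300, "+")
        w = extract_window(j, genome, "+", flank=66)
        assert len(w.upstream_flank) == 10
        assert len(w.window) == 76
        assert w.clipped

    def test_minus_strand_is_reverse_complement(self, genome):
        plus = extract_window(JUNC, genome, "+", flank=66)
        minus = extract_window(JUNC, genome, "-", flank=66)
        assert minus.window == revcomp(plus.window)
        assert minus.junction_offset_nt == \
            len(plus.window) - plus.junction_offset_nt

    def test_missing_chromosome(self, genome):
        with pytest.raises(KeyError, match="chrX"):
            extract_window(SpliceJunction("chrX", 100, 200, "+"), genome, "+")

    def test_unstranded_junction_gives_both_windows(self, genome):
        j = SpliceJunction("chr1", 301, 600, ".")
        windows = windows_for_junction(j, genome)
        assert len(windows) == 2
        assert {w.strand for w in windows} == {"+", "-"}
        stranded = windows_for_junction(JUNC, genome)
        assert len(stranded) == 1


def make_window(up, down, strand="+"):
    return JunctionWindow(("chr1", 1, 2, strand), up, down, strand)


class TestTranslation:
    def test_stopfree_132nt_window(self, genome):
        w = extract_window(JUNC, genome, "+", flank=66)
        peps = {p.frame: p for p in translate_window(w)}
        assert len(peps[0].sequence) == 44
        assert peps[0].junction_offset_aa == 22

    def test_frame_lengths_invariant(self):
        """Frame 0 of an unclipped window with no stop in any frame has
        exactly (2*66)/3 = 44 aa; frames 1 and 2 have 43."""
        # GCA repeats are stop-free in every frame (A / Q / S)
        w = extract_window(JUNC, {"chr1": "GCA" * 400}, "+", flank=66)
        lengths = {p.frame: len(p.sequence) for p in translate_window(w)}
        assert lengths[0] == 44 and lengths[1] == 43 and lengths[2] == 43

    def test_stop_before_junction_removes_frame(self, rng):
        up = codon_free_of_stops(rng, 11) + "TAA" + codon_free_of_stops(rng, 10)
        down = codon_free_of_stops(rng, 22)
        assert len(up) == 66
        frames = {p.frame for p in translate_window(make_window(up, down))}
        assert 0 not in frames

    def test_stop_after_junction_truncates(self, rng):
        up = codon_free_of_stops(rng, 22)
        down = codon_free_of_stops(rng, 3) + "TGA" + codon_free_of_stops(rng, 18)
        peps = {p.frame: p for p in translate_window(make_window(up, down))}
        p0 = peps[0]
        assert len(p0.sequence) == 25  # truncated 3 aa after the junction
        assert p0.junction_offset_aa == 22
        assert not validate_junction_peptide(p0)  # only 3 aa downstream

    def test_hand_translated_fixture(self):
        # ATG GCT AAA | CCC GGG TGA  ->  M A K P G *
        peps = {p.frame: p for p in
                translate_window(make_window("ATGGCTAAA", "CCCGGGTGA"))}
        assert peps[0].sequence == "MAKPG"
        assert peps[0].junction_offset_aa == 3

    def test_n_codon_translates_to_x(self):
        peps = {p.frame: p for p in
                translate_window(make_window("ATGNNN", "GCTGCT"))}
        assert peps[0].sequence == "MXAA"

    def test_too_short_window_logged_empty(self, caplog):
        with caplog.at_level("WARNING", logger="splicescope"):
            assert translate_window(make_window("A", "C")) == []


class TestNovelRegion:
    def test_length_threshold(self, rng):
        assert translate_novel_region(codon_free_of_stops(rng, 6))[0:1] == []
        peps = translate_novel_region(codon_free_of_stops(rng, 7))
        assert len(peps) == 1 and len(peps[0].sequence) == 7

    def test_leading_stop_dropped(self, rng):
        seq = "TAA" + codon_free_of_stops(rng, 2)
        assert all(p.frame != 0 for p in translate_novel_region(seq))

    def test_minus_strand_reads_reverse_complement(self, rng):
        seq = codon_free_of_stops(rng, 10)
        fwd = translate_novel_region(revcomp(seq), strand="-")
        direct = translate_novel_region(seq, strand="+")
        assert {p.sequence for p in fwd} == {p.sequence for p in direct}


class TestValidation:
    @pytest.mark.parametrize("length, offset, ok", [
        (44, 22, True),
        (44, 0, False),    # not junction-spanning
        (30, 20, False),   # only 10 aa after the junction
        (44, 23, False),   # junction starts too late
        (23, 1, True),     # 1 aa before, 22 after
    ])
    def test_22_22_rule(self, length, offset, ok):
        pep = JunctionPeptide("A" * length, 0, ("chr1", 1, 2, "+"),
                              junction_offset_aa=offset)
        assert validate_junction_peptide(pep) is ok

    def test_novel_region_peptides_never_validate(self):
        pep = JunctionPeptide("A" * 50, 0, "src", kind="novel-exon",
                              junction_offset_aa=None)
        assert not validate_junction_peptide(pep)

    def test_emitted_entries_all_span_their_junction(self, rng):
        """Randomized property: every database entry produced from random
        genomes (stops included) passes the junction-position rule."""
        for trial in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=3000))
            genome = {"chr1": seq}
            junctions = []
            for _ in range(10):
                s = int(rng.integers(200, 2000))
                e = s + 60 + int(rng.integers(0, 600))
                junctions.append(SpliceJunction(
                    "chr1", s, e, rng.choice(["+", "-", "."]),
                    unique_reads=10))
            entries = build_junction_entries(junctions, genome)
            for entry in entries:
                off = int(dict(
                    kv.split("=") for kv in entry.accession.split("|")[2:]
                )["off"])
                assert 1 <= off <= 22
                assert len(entry.sequence) - off >= 22


class TestDatabase:
    def _entries(self, seqs, category="reference"):
        return [DatabaseEntry(f"p{i}", s, category)
                for i, s in enumerate(seqs)]

    def test_dedupe_collapses_exact_duplicates(self):
        entries = self._entries(["MKVLA", "MKVLA", "MKVLG"])
        out = dedupe_entries(entries)
        assert [e.sequence for e in out] == ["MKVLA", "MKVLG"]
        assert out[0].accession == "p0"  # first seen wins
        assert dedupe_entries(out) == out  # idempotent

    def test_decoys_preserve_composition_and_length(self):
        targets = self._entries(["PEPTIDE", "M", "AAAKKK"])
        decoys = make_decoys(targets, seed=5)
        assert len(decoys) == len(targets)
        for t, d in zip(targets, decoys):
            assert len(d.sequence) == len(t.sequence)
            assert Counter(d.sequence) == Counter(t.sequence)
            assert d.accession == "decoy_" + t.accession
            assert d.paired_target == t.accession
        assert decoys[1].sequence == "M"

    def test_decoys_deterministic_under_seed(self):
        targets = self._entries(["PEPTIDEPEPTIDE", "MKVLAMKVLA"])
        assert make_decoys(targets, 7) == make_decoys(targets, 7)

    def test_global_residue_composition_conserved(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        targets = self._entries(
            ["".join(rng.choice(aas, size=int(rng.integers(7, 60))))
             for _ in range(40)])
        decoys = make_decoys(targets, 3)
        assert Counter("".join(e.sequence for e in targets)) == \
            Counter("".join(e.sequence for e in decoys))

    def test_assemble_counts(self):
        refs = self._entries([f"REF{i}PEPTIDEAAA" for i in range(10)])
        conts = self._entries(["KERATIN", "TRYPSIN"], "contaminant")
        juncs = self._entries(["JPEPA", "JPEPB", "JPEPC"], "junction")
        entries, summary = assemble_database(refs, conts, juncs, seed=1)
        assert summary["targets"] == 15
        assert summary["decoy"] == 15
        assert summary["total"] == 2 * summary["targets"]
        assert len(entries) == 30

    def test_duplicate_collapsed_before_decoys(self):
        refs = self._entries(["MKVLAPEPTIDE"])
        dup = [DatabaseEntry("jnc|x", "MKVLAPEPTIDE", "junction")]
        entries, summary = assemble_database(refs, junction_entries=dup, seed=1)
        assert summary["targets"] == 1 and summary["decoy"] == 1

    def test_empty_target_set_is_error(self):
        with pytest.raises(ValueError):
            assemble_database([], seed=0)


class TestReverseStrandConsistency:
    def test_peptides_identical_on_mirrored_genome(self, stopfree_seq):
        """Building from the reverse-complemented genome with flipped
        coordinates and strand yields identical peptides."""
        genome = {"chr1": stopfree_seq}
        L = len(stopfree_seq)
        j = SpliceJunction("chr1", 301, 600, "+", unique_reads=10)
        mirrored = {"chr1": revcomp(stopfree_seq)}
        j_m = SpliceJunction("chr1", L - 600 + 1, L - 301 + 1, "-",
                             unique_reads=10)
        fwd = build_junction_entries([j], genome)
        rev = build_junction_entries([j_m], mirrored)
        assert {e.sequence for e in fwd} == {e.sequence for e in rev}
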