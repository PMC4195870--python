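"""Assembly reading/writing, contig concatenation and flank extraction."""
import gzip

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polystr import (
    Assembly,
    Config,
    ConfigError,
    DataError,
    ParseError,
    SequenceRecord,
    concat_with_spacer,
    extract_flanks,
    read_assembly,
    write_assembly,
)
from polystr.str_scanner import StrLocus

names = st.text(alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd")), min_size=1, max_size=8)
sequences = st.text(alphabet="ACGTN", min_size=1, max_size=120)


@st.composite
def assemblies(draw):
    n = draw(st.integers(1, 5))
    recs = []
    used = set()
    for i in range(n):
        name = draw(names) + str(i)  # enforce uniqueness
        assert name not in used
        used.add(name)
        recs.append(SequenceRecord(name, draw(sequences)))
    return Assembly(recs)


class TestReadAssembly:
    def test_minimal_fasta(self, tmp_path):
        path = tmp_path / "a.fa"
        path.write_text(">c1\nACGTACGT\n")
        asm = read_assembly(path)
        assert len(asm) == 1 and asm.records[0].name == "c1" and len(asm.records[0]) == 8

    def test_multiline_fasta_joined_and_uppercased(self, tmp_path):
        path = tmp_path / "a.fa"
        path.write_text(">c1 some description\nacgt\nACGT\n")
        rec = read_assembly(path, "fasta").records[0]
        assert rec.sequence == "ACGTACGT"

    def test_tab_dialect(self, tmp_path):
        path = tmp_path / "a.txt"
        path.write_text("c1\tACGT\nc2\tGGGG\n")
        asm = read_assembly(path, "tab")
        assert [r.name for r in asm] == ["c1", "c2"]
        assert asm.records[1].sequence == "GGGG"

    def test_auto_sniffs_both_dialects(self, tmp_path):
        fa, tab = tmp_path / "a.fa", tmp_path / "a.txt"
        fa.write_text(">x\nAC\n")
        tab.write_text("x\tAC\n")
        assert read_assembly(fa, "auto").dialect == "fasta"
        assert read_assembly(tab, "auto").dialect == "tab"

    def test_gzip_transparent(self, tmp_path):
        path = tmp_path / "a.fa.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(">c1\nACGT\n")
        assert read_assembly(path).records[0].sequence == "ACGT"

    @pytest.mark.parametrize(
        "content,dialect,err",
        [
            (">c1\nACGT\n>c1\nGGGG\n", "fasta", DataError),      # duplicate name
            (">c1\nACXT\n", "fasta", DataError),                  # illegal character
            ("junk\n>c1\nACGT\n", "fasta", ParseError),           # no leading '>'
            ("c1\tAC\tGT\n", "tab", ParseError),                  # two tabs
            ("c1 ACGT\n", "tab", ParseError),                     # no tab at all
            ("", "auto", ParseError),                             # empty file
        ],
    )
    def test_malformed_inputs_rejected(self, tmp_path, content, dialect, err):
        path = tmp_path / "bad.txt"
        path.write_text(content)
        with pytest.raises(err):
            read_assembly(path, dialect)

    def test_tab_error_names_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("c1\tACGT\nc2 GGGG\n")
        with pytest.raises(ParseError, match="line 2"):
            read_assembly(path, "tab")


@settings(max_examples=50, derandomize=True, deadline=None)
@given(assemblies(), st.sampled_from(["fasta", "tab"]))
def test_roundtrip_identity(tmp_path_factory, asm, dialect):
    """Writing then reading an assembly reproduces every record exactly."""
    path = tmp_path_factory.mktemp("rt") / "a.txt"
    write_assembly(asm, path, dialect)
    back = read_assembly(path, dialect)
    assert [(r.name, r.sequence) for r in back] == [(r.name, r.sequence) for r in asm]


class TestConcat:
    def test_combined_length(self):
        asm = Assembly([SequenceRecord("c1", "A" * 1000), SequenceRecord("c2", "G" * 1000)])
        cat = concat_with_spacer(asm, 100)
        assert len(cat.records[0]) == 2100

    def test_coordinate_map_bijection_endpoints(self):
        asm = Assembly([SequenceRecord("c1", "ACGT" * 250), SequenceRecord("c2", "GGCC" * 250)])
        cat = concat_with_spacer(asm, 100)
        cmap = cat.coordinate_map
        assert cmap.to_contig(0) == ("c1", 0)
        assert cmap.to_contig(999) == ("c1", 999)
        assert cmap.to_contig(1000) is None  # first spacer base
        assert cmap.to_contig(1099) is None  # last spacer base
        assert cmap.to_contig(1100) == ("c2", 0)
        assert cmap.to_concat("c2", 0) == 1100

    def test_junction_is_all_n(self):
        asm = Assembly([SequenceRecord("c1", "ACGT"), SequenceRecord("c2", "TTAA")])
        cat = concat_with_spacer(asm, 30, config=Config(unit_sizes={2}, min_units=5))
        assert cat.records[0].sequence[4:34] == "N" * 30

    def test_short_spacer_rejected(self):
        asm = Assembly([SequenceRecord("c1", "ACGT"), SequenceRecord("c2", "TTAA")])
        with pytest.raises(ConfigError):
            concat_with_spacer(asm, 10)  # default config needs >= 5*5

    def test_empty_assembly_rejected(self):
        with pytest.raises(Exception):
            concat_with_spacer(Assembly([]), 100)


class TestExtractFlanks:
    def _locus(self, contig, start, end, motif="ATC"):
        return StrLocus(contig=contig, start=start, end=end, motif=motif)

    def test_interior_locus_complete(self):
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 700)])
        asm = Assembly([SequenceRecord("c1", seq)])
        left, right, complete = extract_flanks(asm, self._locus("c1", 320, 350), 300)
        assert complete and len(left) == len(right) == 300
        assert left == seq[20:320] and right == seq[350:650]

    def test_truncation_reported_via_flag(self):
        asm = Assembly([SequenceRecord("c1", "ACGT" * 100)])
        left, right, complete = extract_flanks(asm, self._locus("c1", 10, 40), 300)
        assert not complete and len(left) == 10

    def test_reconstruction_property(self):
        rng = np.random.default_rng(6)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        asm = Assembly([SequenceRecord("c1", seq)])
        for _ in range(25):
            start = int(rng.integers(0, 1950))
            end = int(rng.integers(start + 3, min(start + 50, 2000)))
            locus = self._locus("c1", start, end)
            left, right, _ = extract_flanks(asm, locus, 300)
            lo, hi = max(0, start - 300), min(2000, end + 300)
            assert left + seq[start:end] + right == seq[lo:hi]
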