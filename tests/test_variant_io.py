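"""VCF parsing, multi-allelic splitting and indel left-normalization."""
import numpy as np
import pytest

from polystr import (
    Assembly,
    DataError,
    ParseError,
    SequenceRecord,
    Variant,
    normalize_indel,
    parse_vcf,
    select_indels,
    write_vcf,
)
from polystr.variant_io import AlleleSupport

HEADER = """##fileformat=VCFv4.2
##contig=<ID=c1,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpopA\tpopB
"""


def _write(tmp_path, body):
    path = tmp_path / "x.vcf"
    path.write_text(HEADER + body)
    return path


class TestParseVcf:
    def test_single_snp_with_allele_depths(self, tmp_path):
        path = _write(tmp_path, "c1\t101\t.\tA\tT\t50\tPASS\t.\tGT:AD\t0/1:12,9\t0/0:20,0\n")
        (v,) = parse_vcf(path)
        assert v.kind == "SNP" and v.qual == 50
        assert (v.samples["popA"].ref_count, v.samples["popA"].alt_count) == (12, 9)
        assert v.samples["popB"].alt_fraction == 0.0

    def test_insertion_length_delta(self, tmp_path):
        path = _write(tmp_path, "c1\t200\t.\tA\tAATCATC\t99\tPASS\t.\tGT\t0/1\t0/1\n")
        (v,) = parse_vcf(path)
        assert v.kind == "INDEL" and v.length_delta == 6

    def test_missing_qual_is_none(self, tmp_path):
        path = _write(tmp_path, "c1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/1\n")
        assert parse_vcf(path)[0].qual is None

    def test_symbolic_alt_skipped(self, tmp_path):
        path = _write(
            tmp_path,
            "c1\t10\t.\tA\t<DEL>\t50\tPASS\t.\tGT\t0/1\t0/1\n"
            "c1\t20\t.\tA\tT\t50\tPASS\t.\tGT\t0/1\t0/1\n",
        )
        variants = parse_vcf(path)
        assert len(variants) == 1 and variants[0].pos == 20

    def test_missing_chrom_header_rejected(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("c1\t10\t.\tA\tT\t50\tPASS\t.\n")
        with pytest.raises(ParseError):
            parse_vcf(path)

    def test_multiallelic_split_reslices_ad(self, tmp_path):
        """Each alternate becomes its own variant; AD re-sliced per alternate."""
        rng = np.random.default_rng(9)
        lines, expected = [], []
        pos = 100
        for _ in range(50):
            n_alts = int(rng.integers(2, 4))
            alts = ["A" + "ATC" * (i + 1) for i in range(n_alts)]
            ads = {s: [int(x) for x in rng.integers(0, 30, n_alts + 1)] for s in ("popA", "popB")}
            cols = "\t".join(f"0/1:{','.join(map(str, ads[s]))}" for s in ("popA", "popB"))
            lines.append(f"c1\t{pos}\t.\tA\t{','.join(alts)}\t60\tPASS\t.\tGT:AD\t{cols}")
            for i, alt in enumerate(alts):
                expected.append(
                    (pos, alt, ads["popA"][0], ads["popA"][i + 1], ads["popB"][0], ads["popB"][i + 1])
                )
            pos += 10
        path = _write(tmp_path, "\n".join(lines) + "\n")
        variants = parse_vcf(path)
        got = [
            (
                v.pos, v.alt,
                v.samples["popA"].ref_count, v.samples["popA"].alt_count,
                v.samples["popB"].ref_count, v.samples["popB"].alt_count,
            )
            for v in variants
        ]
        assert got == expected
        # deltas of the split records share (contig,pos)
        assert all(v.contig == "c1" for v in variants)

    def test_roundtrip_loss_free(self, tmp_path):
        variants = [
            Variant(
                "c1", 11, "A", "AATC", 77.0,
                {
                    "popA": AlleleSupport(12, 9, 24, (0, 1)),
                    "popB": AlleleSupport(20, 0, 21, (0, 0)),
                },
            ),
            Variant(
                "c1", 50, "GAT", "G", 31.0,
                {
                    "popA": AlleleSupport(0, 15, 15, (1, 1)),
                    "popB": AlleleSupport(7, 8, 16, (0, 1)),
                },
            ),
        ]
        path = tmp_path / "rt.vcf"
        write_vcf(variants, path, ["popA", "popB"], {"c1": 10_000})
        back = parse_vcf(path)
        for orig, new in zip(variants, back):
            assert (orig.contig, orig.pos, orig.ref, orig.alt) == (new.contig, new.pos, new.ref, new.alt)
            assert new.qual == pytest.approx(orig.qual)
            for s in ("popA", "popB"):
                a, b = orig.samples[s], new.samples[s]
                assert (a.ref_count, a.alt_count, a.depth, a.genotype) == (
                    b.ref_count, b.alt_count, b.depth, b.genotype,
                )


class TestSelectIndels:
    def test_mixed_list(self):
        snp = Variant("c", 1, "A", "T", 1.0, {})
        ins = Variant("c", 2, "A", "AAT", 1.0, {})
        dele = Variant("c", 3, "ATT", "A", 1.0, {})
        assert select_indels([snp, ins, snp, dele, snp]) == [ins, dele]

    def test_empty(self):
        assert select_indels([]) == []


class TestNormalizeIndel:
    @pytest.fixture()
    def assembly(self):
        return Assembly([SequenceRecord("c1", "GGGGG" + "ATC" * 10 + "GGTTT")])

    def test_deletion_shifts_to_run_start(self, assembly):
        v = Variant("c1", 8, "CATC", "C", 50.0, {})  # mid-run placement
        n = normalize_indel(v, assembly)
        assert (n.pos, n.ref, n.alt) == (5, "GATC", "G")

    def test_insertion_shifts_to_run_start(self, assembly):
        v = Variant("c1", 9, "A", "ATCA", 50.0, {})
        n = normalize_indel(v, assembly)
        assert (n.pos, n.ref, n.alt) == (5, "G", "GATC")

    def test_idempotent(self, assembly):
        v = normalize_indel(Variant("c1", 8, "CATC", "C", 50.0, {}), assembly)
        assert normalize_indel(v, assembly) == v

    def test_snp_rejected(self, assembly):
        with pytest.raises(DataError):
            normalize_indel(Variant("c1", 8, "C", "G", 50.0, {}), assembly)

    def test_ref_mismatch_is_hard_error(self, assembly):
        with pytest.raises(DataError, match="does not match"):
            normalize_indel(Variant("c1", 9, "CATC", "C", 50.0, {}), assembly)

    def test_semantic_equivalence_random_runs(self):
        """Applying ref->alt before and after normalization edits identically."""
        rng = np.random.default_rng(12)
        motifs = ["AT", "ATC", "AAGT", "ATCGA"]
        for _ in range(60):
            motif = motifs[int(rng.integers(len(motifs)))]
            units = int(rng.integers(5, 12))
            pre = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
            post = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
            seq = pre + motif * units + post
            asm = Assembly([SequenceRecord("c1", seq)])
            # place a unit insertion or deletion at a random in-run phase point
            offset = int(rng.integers(0, units - 2)) * len(motif)
            pos0 = 30 + offset
            if rng.random() < 0.5:
                unit = seq[pos0 + 1 : pos0 + 1 + len(motif)]
                v = Variant("c1", pos0 + 1, seq[pos0], seq[pos0] + unit, 1.0, {})
            else:
                v = Variant("c1", pos0 + 1, seq[pos0 : pos0 + 1 + len(motif)], seq[pos0], 1.0, {})
            n = normalize_indel(v, asm)

            def apply(var):
                p = var.pos - 1
                return seq[:p] + var.alt + seq[p + len(var.ref) :]

            assert apply(v) == apply(n)
            assert normalize_indel(n, asm) == n
            assert n.pos <= v.pos
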