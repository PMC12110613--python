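"""Channel classification, SSM parsing and catalog construction."""

import numpy as np
import pandas as pd
import pytest

from mutsig.catalog_io import (
    ContextError,
    MutationCatalog,
    MutationKind,
    MutationRecord,
    SsmFormatError,
    build_catalog,
    classify,
    classify_dbs,
    classify_indel,
    classify_sbs,
    read_ssm,
    read_ssm_with_report,
    write_ssm,
)
from mutsig.channels import (
    BASES,
    ChannelScheme,
    DBS78_LABELS,
    ID83_LABELS,
    SBS96_LABELS,
    revcomp,
)
from oracles import oracle_dbs, oracle_indel, oracle_sbs

_CTX = "ACGTACGTAC"  # neutral 10-mer with no homopolymer runs


def _snv(ref, alt, c5=_CTX, c3=_CTX, sample="S1"):
    return MutationRecord(sample, "chr1", 100, ref, alt, MutationKind.SNV, c5, c3)


def _rand_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


class TestChannelLabels:
    def test_scheme_sizes(self):
        assert len(SBS96_LABELS) == 96
        assert len(DBS78_LABELS) == 78
        assert len(ID83_LABELS) == 83

    def test_labels_unique(self):
        for labels in (SBS96_LABELS, DBS78_LABELS, ID83_LABELS):
            assert len(set(labels)) == len(labels)


class TestClassifySbs:
    @pytest.mark.parametrize(
        "ref,alt,c5,c3,expected",
        [
            ("C", "A", _CTX[:-1] + "A", "A" + _CTX[1:], "A[C>A]A"),
            ("G", "T", _CTX[:-1] + "T", "C" + _CTX[1:], "G[C>A]A"),
        ],
    )
    def test_examples(self, ref, alt, c5, c3, expected):
        assert classify_sbs(_snv(ref, alt, c5, c3)) == expected

    def test_rejects_non_snv(self):
        rec = MutationRecord("S1", "chr1", 5, "-", "C", MutationKind.INS, _CTX, _CTX)
        with pytest.raises(TypeError):
            classify_sbs(rec)

    def test_histogram_matches_oracle_on_random_snvs(self, rng):
        """10,000 random SNVs: channel histogram equals the exhaustive
        192-case lookup oracle, and every label is canonical."""
        mine, oracle = {}, {}
        for _ in range(10_000):
            ref = str(rng.choice(list(BASES)))
            alt = str(rng.choice([b for b in BASES if b != ref]))
            c5, c3 = _rand_seq(rng, 10), _rand_seq(rng, 10)
            lab = classify_sbs(_snv(ref, alt, c5, c3))
            assert lab in SBS96_LABELS
            assert lab == oracle_sbs(c5[-1], ref, alt, c3[0])
            mine[lab] = mine.get(lab, 0) + 1
        assert sum(mine.values()) == 10_000

    def test_strand_invariance(self, rng):
        for _ in range(500):
            ref = str(rng.choice(list(BASES)))
            alt = str(rng.choice([b for b in BASES if b != ref]))
            rec = _snv(ref, alt, _rand_seq(rng, 10), _rand_seq(rng, 10))
            assert classify_sbs(rec) == classify_sbs(rec.reverse_complemented())


class TestClassifyDbs:
    @pytest.mark.parametrize("ref,alt,expected", [("CC", "AA", "CC>AA"), ("GG", "TT", "CC>AA")])
    def test_examples(self, ref, alt, expected):
        rec = MutationRecord("S1", "chr1", 9, ref, alt, MutationKind.DNV, _CTX, _CTX)
        assert classify_dbs(rec) == expected

    def test_shared_base_rejected(self):
        rec = MutationRecord("S1", "chr1", 9, "CC", "CA", MutationKind.DNV, _CTX, _CTX)
        with pytest.raises(ValueError, match="shared base"):
            classify_dbs(rec)

    def test_matches_oracle_on_random_dnvs(self, rng):
        for _ in range(10_000):
            ref = _rand_seq(rng, 2)
            alt = "".join(str(rng.choice([b for b in BASES if b != r])) for r in ref)
            rec = MutationRecord("S1", "chr1", 9, ref, alt, MutationKind.DNV, _CTX, _CTX)
            lab = classify_dbs(rec)
            assert lab in DBS78_LABELS
            assert lab == oracle_dbs(ref, alt)

    def test_strand_invariance(self, rng):
        for _ in range(500):
            ref = _rand_seq(rng, 2)
            alt = "".join(str(rng.choice([b for b in BASES if b != r])) for r in ref)
            rec = MutationRecord("S1", "chr1", 9, ref, alt, MutationKind.DNV, _CTX, _CTX)
            assert classify_dbs(rec) == classify_dbs(rec.reverse_complemented())


def _random_indel(rng, sample="S1"):
    kind = MutationKind.DEL if rng.random() < 0.5 else MutationKind.INS
    L = int(rng.integers(1, 7))
    seq = _rand_seq(rng, L)
    # random context; short alphabets would raise run/repeat frequency but
    # plain ACGT already hits every channel family across 10k draws
    c5 = _rand_seq(rng, 12)
    c3 = _rand_seq(rng, max(12, 5 * L + 2))
    if kind is MutationKind.DEL:
        return MutationRecord(sample, "chr1", 500, seq, "-", kind, c5, c3)
    return MutationRecord(sample, "chr1", 500, "-", seq, kind, c5, c3)


class TestClassifyIndel:
    def test_saturated_homopolymer_deletion(self):
        rec = MutationRecord(
            "S1", "chr1", 50, "T", "-", MutationKind.DEL, "ACGTACGTAC", "TTTTTAGCAT"
        )
        # deleted T + 5 more 3' = 6 copies -> saturated bin
        assert classify_indel(rec) == "1:Del:T:5"

    def test_insertion_with_no_preexisting_run(self):
        rec = MutationRecord(
            "S1", "chr1", 50, "-", "C", MutationKind.INS, "ACGTACGTAT", "GTACGTACGT"
        )
        assert classify_indel(rec) == "1:Ins:C:0"

    def test_microhomology_deletion(self):
        rec = MutationRecord(
            "S1", "chr1", 50, "ACCT", "-", MutationKind.DEL,
            "GGGGGGGGGG", "ACGGGGGGGGGGGGGGGGGGGG",
        )
        assert classify_indel(rec) == "4:Del:M:2"

    def test_insufficient_context_raises(self):
        with pytest.raises(ContextError):
            classify_indel(
                MutationRecord("S1", "chr1", 50, "ACGTA", "-", MutationKind.DEL, _CTX, _CTX)
            )

    def test_matches_naive_scanner_on_random_indels(self, rng):
        """10,000 random indels in random sequence: channels equal the
        independent naive string-scanning oracle."""
        seen = set()
        for _ in range(10_000):
            rec = _random_indel(rng)
            seq = rec.ref if rec.kind is MutationKind.DEL else rec.alt
            lab = classify_indel(rec)
            assert lab in ID83_LABELS
            assert lab == oracle_indel(rec.kind.value, seq, rec.context5, rec.context3)
            seen.add(lab)
        assert len(seen) > 40  # random sequence exercises a broad channel range

    def test_1bp_strand_invariance(self, rng):
        for _ in range(500):
            base = str(rng.choice(list(BASES)))
            kind = MutationKind.DEL if rng.random() < 0.5 else MutationKind.INS
            ref, alt = (base, "-") if kind is MutationKind.DEL else ("-", base)
            rec = MutationRecord(
                "S1", "chr1", 50, ref, alt, kind, _rand_seq(rng, 12), _rand_seq(rng, 12)
            )
            assert classify_indel(rec) == classify_indel(rec.reverse_complemented())


class TestBuildCatalog:
    def test_single_channel_counting(self):
        recs = [_snv("C", "A", _CTX[:-1] + "A", "A" + _CTX[1:]) for _ in range(3)]
        cat = build_catalog(recs, ChannelScheme.SBS96)
        frame = cat.to_frame()
        assert frame.loc["S1", "A[C>A]A"] == 3
        assert frame.loc["S1"].sum() == 3

    def test_two_samples_disjoint_blocks(self, rng):
        recs = []
        for sample, n in (("A", 7), ("B", 4)):
            for _ in range(n):
                ref = str(rng.choice(list(BASES)))
                alt = str(rng.choice([b for b in BASES if b != ref]))
                recs.append(_snv(ref, alt, _rand_seq(rng, 10), _rand_seq(rng, 10), sample))
        cat = build_catalog(recs, ChannelScheme.SBS96)
        assert cat.sample_ids == ["A", "B"]
        assert cat.counts[0].sum() == 7 and cat.counts[1].sum() == 4

    def test_other_kinds_ignored_and_totals_conserved(self, rng):
        recs = [_random_indel(rng) for _ in range(50)]
        recs += [_snv("C", "T") for _ in range(20)]
        cat = build_catalog(recs, ChannelScheme.ID83)
        assert cat.counts.sum() == 50

    def test_catalog_tsv_roundtrip(self, tmp_path, small_cohort):
        cat, _ = small_cohort
        cat.to_tsv(tmp_path / "cat.tsv")
        back = MutationCatalog.from_tsv(tmp_path / "cat.tsv", ChannelScheme.SBS96)
        assert back.sample_ids == cat.sample_ids
        assert (back.counts == cat.counts).all()


class TestSsmIO:
    def _write_basic(self, path, rows, header=None):
        header = header or (
            "icgc_sample_id\tchromosome\tchromosome_start\tchromosome_end\t"
            "reference_genome_allele\tmutated_to_allele\tcontext5\tcontext3"
        )
        path.write_text(header + "\n" + "\n".join(rows) + "\n")

    def test_snv_row_maps_to_record(self, tmp_path):
        p = tmp_path / "ssm.tsv"
        self._write_basic(p, [f"S1\tchr1\t100\t100\tC\tA\t{_CTX}\t{_CTX}"])
        (rec,) = read_ssm(p)
        assert rec.kind is MutationKind.SNV and rec.ref == "C" and rec.alt == "A"
        assert rec.position == 100

    def test_null_allele_insertion(self, tmp_path):
        p = tmp_path / "ssm.tsv"
        self._write_basic(p, [f"S1\tchr1\t100\t100\t-\tCT\t{_CTX}\t{_CTX}"])
        (rec,) = read_ssm(p)
        assert rec.kind is MutationKind.INS and rec.event_length == 2

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "ssm.tsv"
        p.write_text("icgc_sample_id\tchromosome\tchromosome_start\n")
        with pytest.raises(SsmFormatError, match="chromosome_end"):
            read_ssm(p)

    def test_malformed_rows_counted_not_fatal(self, tmp_path):
        p = tmp_path / "ssm.tsv"
        self._write_basic(
            p,
            [
                f"S1\tchr1\t100\t100\tC\tA\t{_CTX}\t{_CTX}",
                f"S1\tchr1\tnotanint\t100\tC\tA\t{_CTX}\t{_CTX}",
                f"S1\tchr1\t100\t100\tN\tA\t{_CTX}\t{_CTX}",
            ],
        )
        records, report = read_ssm_with_report(p)
        assert len(records) == 1
        assert report.total == 2

    def test_500_row_roundtrip(self, tmp_path, rng):
        records = []
        for i in range(500):
            kind = rng.choice(["snv", "dnv", "indel"])
            sample = f"S{int(rng.integers(1, 6))}"
            if kind == "snv":
                ref = str(rng.choice(list(BASES)))
                alt = str(rng.choice([b for b in BASES if b != ref]))
                rec = MutationRecord(
                    sample, "chr1", 10 + i, ref, alt, MutationKind.SNV,
                    _rand_seq(rng, 10), _rand_seq(rng, 10),
                )
            elif kind == "dnv":
                ref = _rand_seq(rng, 2)
                alt = "".join(str(rng.choice([b for b in BASES if b != r])) for r in ref)
                rec = MutationRecord(
                    sample, "chr1", 10 + i, ref, alt, MutationKind.DNV,
                    _rand_seq(rng, 10), _rand_seq(rng, 10),
                )
            else:
                rec = _random_indel(rng, sample)
            records.append(rec)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_ssm(records, p1)
        back = read_ssm(p1)
        assert back == records
        write_ssm(back, p2)
        assert read_ssm(p2) == records

    def test_context_from_fasta(self, tmp_path, rng):
        pyfaidx = pytest.importorskip("pyfaidx")
        seq = _rand_seq(np.random.default_rng(7), 200)
        fasta_path = tmp_path / "ref.fa"
        fasta_path.write_text(">chrT\n" + seq + "\n")
        pos = 100  # 1-based; reference base seq[99]
        ref, candidates = seq[pos - 1], [b for b in BASES if b != seq[pos - 1]]
        p = tmp_path / "ssm.tsv"
        p.write_text(
            "icgc_sample_id\tchromosome\tchromosome_start\tchromosome_end\t"
            "reference_genome_allele\tmutated_to_allele\n"
            f"S1\tchrT\t{pos}\t{pos}\t{ref}\t{candidates[0]}\n"
            f"S1\tchrT\t3\t3\t{seq[2]}\t{[b for b in BASES if b != seq[2]][0]}\n"
        )
        fasta = pyfaidx.Fasta(str(fasta_path))
        records, report = read_ssm_with_report(p, fasta)
        assert len(records) == 1  # second row's 5' window exceeds the chromosome start
        assert report.out_of_bounds == 1
        rec = records[0]
        assert rec.context5 == seq[pos - 11 : pos - 1]
        assert rec.context3 == seq[pos : pos + 10]

    def test_fasta_required_without_context_columns(self, tmp_path):
        p = tmp_path / "ssm.tsv"
        p.write_text(
            "icgc_sample_id\tchromosome\tchromosome_start\tchromosome_end\t"
            "reference_genome_allele\tmutated_to_allele\nS1\tchr1\t100\t100\tC\tA\n"
        )
        with pytest.raises(SsmFormatError, match="FASTA"):
            read_ssm(p)
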