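"""Reading and harmonizing GWAS summary tables."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmr import harmonize, read_summary_stats
from tsmr.exceptions import AnalysisError, ConfigurationError, InputError
from tsmr.summary_io import ALL_ACTIONS, KEPT_ACTIONS

from conftest import make_record

HEADER = "snp\tchr\tpos\tea\toa\teaf\tbeta\tse\tp\tn"


def _write(tmp_path, rows, header=HEADER, sep="\t", name="stats.tsv"):
    path = tmp_path / name
    text = header.replace("\t", sep) + "\n"
    text += "\n".join(sep.join(str(v) for v in row) for row in rows) + "\n"
    path.write_text(text)
    return path


ROWS = [
    ["rs1", "1", 1000, "a", "g", 0.25, 0.1, 0.02, 1e-9, 10000],
    ["rs2", "2", 2000, "C", "T", 0.5, -0.05, 0.01, 1e-7, 10000],
    ["rs3", "3", 3000, "G", "A", 0.9, 0.2, 0.05, 1e-6, 10000],
]


def test_reads_well_formed_tsv_and_uppercases_alleles(tmp_path):
    records = read_summary_stats(_write(tmp_path, ROWS))
    assert [r.snp_id for r in records] == ["rs1", "rs2", "rs3"]
    assert records[0].effect_allele == "A" and records[0].other_allele == "G"
    assert records[0].pos == 1000 and records[0].n == 10000


def test_invalid_rows_are_rejected_and_counted(tmp_path, caplog):
    bad = [["rs4", "4", 4000, "A", "G", 0.5, 0.1, 0.0, 1e-5, 10000]]  # se = 0
    with caplog.at_level(logging.WARNING, logger="tsmr.summary_io"):
        records = read_summary_stats(_write(tmp_path, ROWS + bad))
    assert len(records) == 3
    assert any("rejected 1 of 4" in m for m in caplog.messages)


def test_csv_with_remapped_headers_matches_tsv(tmp_path):
    tsv = read_summary_stats(_write(tmp_path, ROWS))
    header = "rsid,chrom,bp,A1,A2,freq,effect,stderr,pval,samples"
    csv_path = _write(tmp_path, ROWS, header=header, sep=",", name="stats.csv")
    csv = read_summary_stats(
        csv_path,
        column_map={
            "snp_id": "rsid", "chrom": "chrom", "pos": "bp", "effect_allele": "A1",
            "other_allele": "A2", "eaf": "freq", "beta": "effect", "se": "stderr",
            "pvalue": "pval", "n": "samples",
        },
    )
    assert csv == tsv


def test_missing_mapped_column_names_the_column(tmp_path):
    with pytest.raises(ConfigurationError, match="beta"):
        read_summary_stats(_write(tmp_path, ROWS), column_map={"beta": "nope"})


def test_zero_parseable_rows_is_an_input_error(tmp_path):
    bad = [["rs1", "1", 1, "A", "G", 0.5, 0.1, -1, 0.5, 100]]
    with pytest.raises(InputError):
        read_summary_stats(_write(tmp_path, bad))


def test_duplicate_snp_keeps_lowest_pvalue(tmp_path):
    dup = [["rs1", "1", 1000, "A", "G", 0.25, 0.3, 0.02, 1e-12, 10000]]
    records = read_summary_stats(_write(tmp_path, ROWS + dup))
    assert len(records) == 3
    rs1 = next(r for r in records if r.snp_id == "rs1")
    assert rs1.beta == 0.3  # the lower-p duplicate won


class TestHarmonize:
    def test_aligned_alleles_kept_unchanged(self):
        hset = harmonize([make_record(beta=0.1)], [make_record(beta=0.05)])
        (rec,) = hset.records
        assert rec.action == "kept" and rec.beta_out == 0.05

    def test_swapped_alleles_flip_sign(self):
        hset = harmonize([make_record(ea="A", oa="G")], [make_record(ea="G", oa="A", beta=0.05, eaf=0.3)])
        (rec,) = hset.records
        assert rec.action == "sign_flipped"
        assert rec.beta_out == -0.05 and rec.eaf_out == pytest.approx(0.7)

    def test_strand_complement_resolves_non_palindromic(self):
        # exposure A/G vs outcome T/C is the same variant read off the other strand
        hset = harmonize([make_record(ea="A", oa="G")], [make_record(ea="T", oa="C", beta=0.05)])
        assert hset.records[0].action == "kept"
        assert hset.records[0].beta_out == 0.05

    def test_ambiguous_palindrome_dropped(self):
        hset = harmonize(
            [make_record(ea="A", oa="T", eaf=0.50)],
            [make_record(ea="A", oa="T", eaf=0.50)],
            palindrome_eaf_window=0.08,
        )
        assert hset.records[0].action == "dropped_palindromic"

    def test_informative_palindrome_aligned_by_frequency(self):
        kept = harmonize(
            [make_record(ea="A", oa="T", eaf=0.10)],
            [make_record(ea="A", oa="T", eaf=0.12, beta=0.05)],
        ).records[0]
        assert kept.action == "kept" and kept.beta_out == 0.05
        flipped = harmonize(
            [make_record(ea="A", oa="T", eaf=0.10)],
            [make_record(ea="A", oa="T", eaf=0.88, beta=0.05)],
        ).records[0]
        assert flipped.action == "sign_flipped" and flipped.beta_out == -0.05

    def test_palindrome_without_eaf_dropped(self):
        hset = harmonize(
            [make_record(ea="A", oa="T", eaf=0.2)],
            [make_record(ea="A", oa="T", eaf=None)],
        )
        assert hset.records[0].action == "dropped_palindromic"

    def test_missing_and_incompatible_outcomes(self):
        exposure = [make_record("rs1"), make_record("rs2"), make_record("rs3")]
        outcome = [make_record("rs1"), make_record("rs3", ea="C", oa="G")]
        hset = harmonize(exposure, outcome)
        actions = {r.snp_id: r.action for r in hset.records}
        assert actions == {"rs1": "kept", "rs2": "dropped_missing", "rs3": "dropped_incompatible"}

    def test_empty_intersection_raises(self):
        with pytest.raises(AnalysisError, match="no overlapping"):
            harmonize([make_record("rs1")], [make_record("rs99")])

    @given(
        swap=st.lists(st.booleans(), min_size=2, max_size=8),
        betas=st.lists(st.floats(-1, 1), min_size=8, max_size=8),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sign_flip_involution(self, swap, betas):
        """Swapping outcome alleles and negating beta_out leaves the result unchanged."""
        exposure = [make_record(f"rs{i}", beta=0.1 + 0.01 * i) for i in range(len(swap))]
        outcome, outcome_swapped = [], []
        for i, (do_swap, b) in enumerate(zip(swap, betas)):
            outcome.append(make_record(f"rs{i}", beta=b, eaf=0.3))
            if do_swap:
                outcome_swapped.append(make_record(f"rs{i}", ea="G", oa="A", beta=-b, eaf=0.7))
            else:
                outcome_swapped.append(make_record(f"rs{i}", beta=b, eaf=0.3))
        a = harmonize(exposure, outcome)
        b_ = harmonize(exposure, outcome_swapped)
        for ra, rb in zip(a.kept_records, b_.kept_records):
            assert ra.beta_out == pytest.approx(rb.beta_out)
            assert ra.eaf_out == pytest.approx(rb.eaf_out)

    def test_count_conservation_and_idempotence(self):
        exposure = [
            make_record("rs1"),
            make_record("rs2", ea="A", oa="T", eaf=0.5),
            make_record("rs3"),
            make_record("rs4", ea="C", oa="T"),
        ]
        outcome = [
            make_record("rs1", ea="G", oa="A", beta=-0.2, eaf=0.6),
            make_record("rs2", ea="A", oa="T", eaf=0.5),
            make_record("rs4", ea="C", oa="T", beta=0.3),
        ]
        hset = harmonize(exposure, outcome)
        assert sum(hset.action_counts().values()) == len(exposure)
        assert set(hset.action_counts()) == set(ALL_ACTIONS)

        # idempotence: re-harmonizing the aligned records changes nothing
        exp2 = [
            make_record(r.snp_id, ea=r.effect_allele, oa=r.other_allele,
                        beta=r.beta_exp, se=r.se_exp, eaf=r.eaf_exp)
            for r in hset.kept_records
        ]
        out2 = [
            make_record(r.snp_id, ea=r.effect_allele, oa=r.other_allele,
                        beta=r.beta_out, se=r.se_out, eaf=r.eaf_out)
            for r in hset.kept_records
        ]
        again = harmonize(exp2, out2)
        assert all(r.action in KEPT_ACTIONS for r in again.records)
        for r1, r2 in zip(hset.kept_records, again.kept_records):
            assert r2.beta_out == pytest.approx(r1.beta_out)
            assert r2.action == "kept"
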