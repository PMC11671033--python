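"""Partitioning at the cutoff and the statistics summary/report."""

import re

import numpy as np
import pytest

from seqlensplit import (
    SequenceRecord,
    compute_stats,
    partition_by_length,
    render_stats_text,
)
from seqlensplit.length_split import (
    LengthPartition,
    above_fasta_name,
    below_fasta_name,
    stats_file_name,
)


def _recs(lengths):
    return [SequenceRecord(f"s{i}", "", "A" * n) for i, n in enumerate(lengths)]


def test_boundary_at_default_cutoff():
    """Length 200 is 'above' at cutoff 200; 150 is 'below'."""
    part = partition_by_length(_recs([150, 200, 250]), 200)
    assert sorted(len(r) for r in part.above) == [200, 250]
    assert [len(r) for r in part.below] == [150]


@pytest.mark.parametrize("cutoff", [1, 2, 100, 200])
def test_boundary_rule_across_cutoffs(cutoff):
    """A record of length c is always above; length c-1 always below."""
    part = partition_by_length(_recs([cutoff, cutoff - 1]), cutoff)
    assert [len(r) for r in part.above] == [cutoff]
    assert [len(r) for r in part.below] == [cutoff - 1]


def test_partition_empty_input():
    part = partition_by_length([], 200)
    assert part.above == [] and part.below == []


def test_partition_against_brute_force_oracle():
    rng = np.random.default_rng(42)
    records = _recs(rng.integers(1, 501, size=1000))
    part = partition_by_length(records, 200)
    # independent brute-force filter, record by record
    assert part.above == [r for r in records if len(r.residues) >= 200]
    assert part.below == [r for r in records if len(r.residues) < 200]
    assert len(part.above) + len(part.below) == 1000
    assert min(len(r) for r in part.above) >= 200
    assert max(len(r) for r in part.below) <= 199


def test_partition_preserves_relative_order():
    records = _recs([300, 10, 400, 20, 500])
    part = partition_by_length(records, 200)
    assert [r.identifier for r in part.above] == ["s0", "s2", "s4"]
    assert [r.identifier for r in part.below] == ["s1", "s3"]


def test_compute_stats_two_records():
    part = partition_by_length(_recs([300, 10]), 200)
    s = compute_stats(part, "bp")
    assert (s.total_count, s.above_count, s.below_count) == (2, 1, 1)
    assert (s.above_min, s.above_max) == (300, 300)
    assert (s.below_min, s.below_max) == (10, 10)
    assert (s.input_min, s.input_max) == (10, 300)


def test_compute_stats_empty():
    s = compute_stats(LengthPartition(cutoff=200), "bp")
    assert s.total_count == 0
    assert s.above_min is s.above_max is s.below_min is s.below_max is None
    assert s.input_min is None and s.input_max is None


def test_compute_stats_against_flat_length_list():
    rng = np.random.default_rng(7)
    lengths = rng.integers(0, 1000, size=500).tolist()
    s = compute_stats(partition_by_length(_recs(lengths), 200), "bp")
    above = [n for n in lengths if n >= 200]
    below = [n for n in lengths if n < 200]
    assert s.above_count + s.below_count == s.total_count == 500
    assert (s.above_min, s.above_max) == (min(above), max(above))
    assert (s.below_min, s.below_max) == (min(below), max(below))
    assert (s.input_min, s.input_max) == (min(lengths), max(lengths))


def test_stats_text_tokens():
    s = compute_stats(partition_by_length(_recs([300, 10]), 200), "bp")
    text = render_stats_text(s)
    for token in ["2", "above 199 bp", "below 200 bp", "300", "10"]:
        assert token in text


def test_stats_text_empty_summary():
    text = render_stats_text(compute_stats(LengthPartition(cutoff=200), "bp"))
    assert "Total input sequences: 0" in text
    assert text.count("N/A") == 6


def test_stats_text_parse_back():
    """Every number in the report equals the corresponding summary field."""
    rng = np.random.default_rng(3)
    s = compute_stats(
        partition_by_length(_recs(rng.integers(1, 400, size=80)), 200), "bp"
    )
    values = []
    for line in render_stats_text(s).splitlines()[1:]:
        label, _, value = line.rpartition(": ")
        assert label
        values.append(None if value == "N/A" else int(value))
    assert values == [
        s.total_count, s.input_min, s.input_max,
        s.above_count, s.above_min, s.above_max,
        s.below_count, s.below_min, s.below_max,
    ]


def test_stats_text_protein_unit():
    s = compute_stats(partition_by_length(_recs([50, 150]), 100), "aa")
    text = render_stats_text(s)
    assert "above 99 aa" in text and "below 100 aa" in text
    assert not re.search(r"\bbp\b", text)


def test_output_file_names_default_run():
    assert above_fasta_name(200, "bp") == "seq_above199bp.fasta"
    assert below_fasta_name(200, "bp") == "seqs_below200bp.fasta"
    assert stats_file_name(200) == "seq_length_stats_by_threshold_200.txt"
    assert above_fasta_name(100, "aa") == "seq_above99aa.fasta"
    assert below_fasta_name(100, "aa") == "seqs_below100aa.fasta"
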