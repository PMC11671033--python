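"""Protein-mode split at 100 aa, the common ORF-length threshold.

Generates a synthetic peptide set (log-normal lengths, median ~67 aa),
splits it at 100 amino acids, and prints the summary.  With protein mode
on, every file name, label and stats line uses "aa" instead of "bp":
the sides become "above 99 aa" and "below 100 aa".
"""

from pathlib import Path

from seqlensplit import (
    FixtureSpec,
    LogNormalLengths,
    RunConfig,
    generate_fasta,
    run_pipeline,
)

workdir = Path("scratch/example_peptides")
workdir.mkdir(parents=True, exist_ok=True)
fasta = workdir / "peptides.fasta"

generate_fasta(
    FixtureSpec(
        n_records=800,
        lengths=LogNormalLengths(4.2, 0.8),
        alphabet="protein",
        seed=7,
    ),
    fasta,
)

out = workdir / "peptides_split"
summary = run_pipeline(
    RunConfig(input_path=fasta, output_dir=out, cutoff=100, seq_kind="protein")
)

print(f"total peptides:  {summary.total_count}")
print(f"above 99 aa:     {summary.above_count}  -> seq_above99aa.fasta")
print(f"below 100 aa:    {summary.below_count}  -> seqs_below100aa.fasta")
print((out / "seq_length_stats_by_threshold_100.txt").read_text())
# Peptides under 100 aa are candidates for bioactive-peptide screens;
# sequences at or over 100 aa pass the usual ORF-annotation threshold.
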