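# Methods

## The operation

`seqlensplit` performs one operation: given a FASTA file and a length
cutoff *c* ≥ 1, it partitions the records into an *above* side (length
≥ *c*) and a *below* side (length < *c*), writes each side back as FASTA,
summarises counts and length extremes, and renders a histogram of each
side's length distribution in linear and log scale.  The boundary rule is
closed on the above side: a record of length exactly *c* is above.  This
matches the side labels — at *c* = 200 the sides are "above 199 bp" and
"below 200 bp", which partition the integers with no overlap and no gap.

Length is defined as the number of characters in the residue string.  Gap
(`-`) and stop (`*`) symbols, ambiguity codes and lower-case letters all
count; excluding any class of symbol would silently move records across
the cutoff, so the tool never does.  The `--nt`/`--prot` switch affects
units and labels only (bp vs aa), never parsing or the split itself.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 200 | length threshold, in bp (nucleotide) or aa (protein). 200 bp is the minimum contig length for TSA database submission; 100 aa is the usual ORF-annotation threshold for protein mode. |
| `seq_kind` | nucleotide | selects the unit string used in file names, labels and stats. |
| `output_dir` | `{input-stem}_{nt|prot}_{cutoff}` beside the input | where all seven artifacts go. The auto-name joins the stated components (input name, sequence type, threshold) with underscores, making reruns per (input, type, cutoff) collision-free. |
| `wrap_width` | 60 | FASTA output line width; conventional, and irrelevant to the split (round-trip preserves records for any width ≥ 1). |
| `show_plots` / `plot_backend` | off / `TkAgg` | interactive display only. File rendering always goes through an off-screen Agg canvas, so pipeline runs need no display regardless of the backend setting; the backend name is still validated so typos fail loudly. |

## FASTA handling

Parsing is permissive by design: wrapped sequence lines are concatenated,
CRLF and LF both accepted, blank lines skipped, empty-bodied records kept
(length 0, always below any valid cutoff), duplicate identifiers
preserved.  A zero-byte file is a valid empty input; a non-empty file with
no `>` header is rejected as malformed.  Record identity is
(identifier, description, residues), and reading back a written file
reproduces it exactly — the split is lossless, and the two output files
concatenated contain precisely the input records.  Biopython's FASTA
parser does the low-level record scanning; writing is done directly so
the header layout and wrapping stay under the package's control.

## Histograms

Binning adapts to the data scale: when the length range spans at most 100
distinct values (peptide-scale data), each integer length gets its own
unit-width bin centred on the value; wider ranges get 50 equal-width bins.
Bins cover [min, max] of the side's lengths and the counts always sum to
the side's record count.  "Log scale" means a logarithmic count (y) axis
over a linear length axis — the standard view for heavy-tailed length
distributions, where the sparse long tail is invisible in linear scale.
Zero-count bins are simply not drawn on the log axis.  An empty side is
not renderable: its two plots are skipped with a logged warning rather
than producing a degenerate image, so a two-sided run yields four PNGs,
a one-sided run two, an empty input none.

## Synthetic inputs

The fixture generator produces seeded, byte-reproducible FASTA files from
three length samplers: a deterministic ladder (exact consecutive lengths,
used for boundary checks), uniform integers, and a log-normal model
(default mean_log 6, sigma_log 1, median exp(6) ≈ 403) whose heavy right
tail mimics de novo transcriptome assemblies — the default because that is
the tool's primary input class.  Edge-case flags inject an empty record,
a duplicate identifier or CRLF endings.  The generator emulates only
length distribution, alphabet and FASTA layout; it does not model
realistic base composition, k-mer structure or quality artifacts, so
passing tests demonstrate the I/O and partitioning contracts, not
biological validity of any particular assembly.

Test and acceptance runs use modest sizes — 1000-record fixtures for the
property suites, 5000 records for the distribution-level checks — chosen
so each suite completes in seconds while still exercising both sides of
the cutoff and the empty-side paths.

## Numerical and interface choices

- Empty-side min/max are reported as `N/A`, never 0: zero is a legal
  sequence length and would be misleading.
- The stats file is one labelled `key: value` number per line, so every
  reported figure can be parsed back and checked mechanically.
- Two of the published output names carry a `seqs_` prefix where the other
  five use `seq_` (`seqs_below{c}bp.fasta`,
  `seqs_length_distribution_below{c}bp_log.png`); the asymmetry is
  reproduced verbatim so downstream scripts written against the original
  inventory keep working.
- In protein mode the unit substitution applies inside file names
  (`seq_above99aa.fasta`); the `.fasta` extension is kept, since the files
  remain FASTA regardless of alphabet.
- Usage errors exit 2 (argparse convention) and runtime I/O errors exit 1;
  existing outputs are overwritten without prompting, as expected of a
  pipeline step; per-artifact log lines go to stderr so stdout stays clean.

## Limitations

No FASTQ, no compressed input, no alphabet validation, no N50/median/mean
statistics (other toolkits cover those), no range filtering (simultaneous
min and max), single input file per run, PNG as the only plot format.
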