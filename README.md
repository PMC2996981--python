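# oysterlsu

Comparative analysis of **fragmented mitochondrial LSU rRNA genes** in
cupped oysters (*Crassostrea virginica*, *C. gigas*, *C. hongkongensis*).
In these species the large-subunit (23S-like) rRNA gene is encoded as two
genomic fragments — a 5' half and a 3' half — separated by kilobases of
tRNA and protein-coding genes on the circular mitochondrial genome, and the
two transcripts are never spliced together.  This package re-implements the
computational side of that characterization as a tested, reusable pipeline:

- **Covariation analysis** — mutual information
  `MI(i,j) = Σ_{x,y} f_xy log₂[f_xy/(f_x f_y)]` (bits) and Pearson χ² over
  alignment column pairs, with greedy mutual-best base-pair prediction: the
  comparative method behind rRNA secondary-structure models.
- **Template-based structure mapping** — transfer of a secondary-structure
  model onto a new sequence through a pairwise alignment, with per-domain
  (I–VI) presence calls (e.g. the complete loss of domain III) and overlap
  reports against named regions such as the peptide-exit-tunnel segments.
- **EST-driven boundary inference** — fragment 5' ends from the extreme
  5'-most transcript position (or the first base after an upstream gene),
  3' ends from the modal polyadenylation site, plus circular-genome
  fragment-separation arithmetic.
- **Fragment sequence statistics** — lengths, A+T/G+C content, and an
  asymmetric species-identity matrix (upper triangle 5' fragments, lower
  triangle 3' fragments) from Needleman–Wunsch global alignments.
- **In-silico PCR splicing test** — IUPAC-degenerate primer-site search on
  circular or cDNA templates and the three-primer-set decision rule
  (internal 5', internal 3', spanning) that distinguishes
  `not_spliced` / `spliced_or_contiguous` / `inconclusive`.
- **Synthetic data with ground truth** — a generator for circular genomes
  with a two-fragment gene, polyadenylated error-bearing ESTs, and
  alignments with compensatory substitutions, so every stage is scored
  against known truth without downloads.

## Worked example

The analysis drivers run the whole pipeline on the synthetic system:

```sh
python analysis/01_simulate.py      # genome + ESTs + covarying alignment
python analysis/02_covariation.py   # MI/chi2 stats and pair prediction
python analysis/04_boundaries.py    # EST boundary calls
python analysis/06_splice_test.py   # in-silico RT-PCR splicing test
```

which prints, among other lines:

```
fragments: 5' (8000, 8747), 3' (1500, 2218)
3916 column pairs scored; 30 pairs predicted
PPV 1.000, recall 1.000 against the true structure
call (8000, 8747) vs truth (8000, 8747); modal poly(A) fraction 0.99
exact recovery in 100% of 20 runs
circular gaps between fragments: 8752 nt forward, 5781 nt back
fragmented: not_spliced
contiguous: spliced_or_contiguous
```

Read: the simulated genome carries a 748-nt 5' fragment and a 719-nt 3'
fragment (the *C. virginica* sizes); all 30 true base pairs of the
simulated structure are recovered from covariation alone with no false
positives; the EST pipeline recovers the fragment's boundaries exactly, the
3' end supported by 99 % of polyadenylated transcripts; and the splicing
test returns `not_spliced` for the fragmented system while the
contiguous-gene control amplifies the spanning product from both genomic
DNA and cDNA.  The same stages are available as `oysterlsu` subcommands
(`simulate`, `covary`, `map-structure`, `boundaries`, `stats`, `pcr`,
`splice-test`).

## Published-sequence statistics

The study genomes are not redistributed.  To compute the accession-based
numbers (A+T content per fragment, the species identity matrix, the 233-bp
internal PCR product, the 9958-nt *C. virginica* fragment separation),
fetch each record as FASTA, e.g.

```sh
mkdir -p data/accessions
for acc in AY905542 AF177226 EU672834 EU266073 DQ665851; do
  curl -o data/accessions/$acc.fasta \
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=$acc&rettype=fasta&retmode=text"
done
python analysis/05_seqstats.py
```

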