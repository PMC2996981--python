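# Methods

## The system being modelled

Bilateral-animal mitochondrial genomes are compact circles (~16 kb) whose
large-subunit rRNA gene is normally contiguous.  In the cupped oysters the
gene is split: a 5' half and a 3' half sit in different arcs of the circle,
separated by tRNA and protein-coding genes, each transcribed and
polyadenylated on its own.  The package implements the four kinds of
evidence used to characterize such a system — covariation-based structure
modelling, template-based domain mapping, EST-based boundary inference, and
an in-silico RT-PCR splicing test — plus a generator that produces the whole
system synthetically with known ground truth.

## Coordinate and alphabet conventions

All coordinates are 1-based inclusive (GenBank/GFF3 style).  Origin-spanning
features on circular molecules are encoded as `start > end`, covering
`start..L` then `1..end`; this avoids duplicating sequence.  Genomic
sequences are DNA (T); alignment and structure sequences are RNA (U);
conversion is explicit (`transcribe`/`reverse_transcribe`).  All file
readers reject malformed input with errors that name the offending record,
position or row; nothing is silently repaired.  Dot-bracket supports one
pseudoknot layer (`[]`); CT files use the 6-column Zuker dialect and carry
arbitrary pair sets.

## Covariation statistics

For columns *i*, *j* of an alignment over {A,C,G,U,−}, rows gapped at either
column are dropped (pairwise deletion) and the surviving count reported as
`n_eff`.  Mutual information is the plug-in estimate
`MI = Σ f_xy log₂[f_xy/(f_x f_y)]` in bits (0 ≤ MI ≤ 2 for a 4-letter
alphabet); the association χ² is Pearson's statistic on the observed joint
letter table with `df = (r−1)(c−1)` over observed categories (computed via
`scipy.stats.chi2_contingency`, no continuity correction).  Pairs with
`n_eff` below a minimum (default 5) are reported as *undefined*, never as
zero.  No pseudocounts and no sequence weighting are applied; small-`n` MI
is biased upward by roughly `(|X|−1)(|Y|−1)/(2 n ln 2)` bits, which is why
the minimum-`n_eff` rule exists instead of a correction.

Pair prediction is greedy: candidates sorted by MI descending (ties broken
by higher χ², then smaller *i*), accepted when both columns are unassigned,
MI ≥ threshold (default 0.3 bits), and each column is the other's best
remaining partner.  The tie-break order is fixed so runs are reproducible.
An optional filter restricts candidates to column pairs whose consensus
letters can form a Watson–Crick or GU pair; the end-to-end experiment does
not apply it, because under heavy compensatory substitution the plurality
letter of a column is noisy and the filter only costs recall while the
MI + mutual-best rule already holds precision at 1 on the synthetic
benchmark.

## Structure transfer and domain calls

A template structure is transferred through a two-row alignment as a
monotone position map; pair (i, j) survives iff both positions map and the
target letters form a canonical pair ({AU, UA, GC, CG, GU, UG} — standard
comparative-model practice for rRNA).  Monotone maps cannot introduce
crossings, so nestedness is preserved.  Every template pair is accounted
for: retained, or dropped as `unmapped_i`/`unmapped_j`/`non_canonical`.

Domain presence is called from the fraction of a domain's template pairs
retained (a pair belongs to the domain holding its 5' position): below 0.1
→ absent, above 0.9 → present, otherwise partial.  The thresholds are
package choices — the published calls they mirror are qualitative — and are
exposed as parameters.  Domains containing no template pairs are reported
as `no_pairs` rather than guessed.  Region-overlap reports (e.g. peptide
exit tunnel segments versus absent domains) require both maps to declare
the same coordinate-system label; numbering systems are opaque labels and
are never converted.  The fragmentation-site check treats the missing
material between the fragment images (template positions
`frag5.end+1 .. frag3.start-1`) as the break and requires it to fall
strictly after domain II's last position and strictly before domain IV's
first.

## EST boundary inference

The poly(A) detector takes the longest terminal run of A allowing at most
`max_mismatch` (default 1) non-A bases, beginning on an A and containing at
least `min_run` (default 8) adenines.  There is no published operational
definition of these thresholds; both are exposed.

The synthetic-data matcher trims the tail, locates the templated part on
the + strand with edlib (infix mode; the genome is doubled so matches may
cross the origin), then (a) anchors the reported start on the first run of
at least 8 exact matches — a 5'-terminal sequencing error otherwise lets a
co-optimal alignment start early, and the fragment start is a minimum over
ESTs, so one such EST would corrupt the call — and (b) walks the detected
tail against the genomic continuation to reclaim templated adenines the
trimmer swallowed, mirroring how an aligner consumes templated A's before
the tail begins.

Boundary calls: start = minimum observed genomic start, unless a given
upstream feature ends 5' of every transcript, in which case `end+1` of that
feature is used (transcripts may be 5'-truncated).  End = modal
polyadenylation site among tailed transcripts, requiring a supporting
fraction ≥ `majority_min` (default 0.5, a literal majority); ties break
toward the 3'-most site, conservative against truncation artefacts.  No
tailed transcripts, or no site reaching the majority, are errors that carry
the candidate list — not silent guesses.

Fragment separation on a circle reports both gaps (forward from the 5'
fragment's end to the 3' fragment's start, and the complement); the two
gaps plus the two fragment lengths always sum to the genome length.

## In-silico PCR and the splicing test

Degenerate primers are matched set-wise against IUPAC codes (linear scan,
no combinatorial expansion), with a default budget of 2 mismatches and none
allowed in the last 3 nt of the 3' end, where the polymerase extends.
Annealing temperature and primer thermodynamics are not modelled.  Circular
templates are scanned across the origin and products may wrap it; product
length is measured from the forward footprint's 5' start to the reverse
footprint's 3' end inclusive, modulo the template length.  `max_len`
(default 5000 bp) suppresses spurious giant circular products — on a
fragmented genome the "spanning" primer pair does technically face itself
around the circle, at a distance no PCR would cover.

The splicing verdict is a pure function of the evidence table:
`spliced_or_contiguous` iff the spanning product amplifies from cDNA;
`not_spliced` iff both internal products amplify from cDNA and the spanning
product amplifies from neither cDNA nor genomic DNA; otherwise
`inconclusive` (a failed control).  The shipped primer table carries the
six study primers verbatim; the 3'-portion product length is recorded as
494 bp (the primer-table/figure value) with the conflicting 434 bp prose
value noted in the file header rather than resolved.

## The synthetic generator

`simulate_genome` draws an A+T-rich (65 %) circular sequence — molluscan
mtDNA composition — and places the two rRNA fragment features at configured
intervals, by default 748 nt and 719 nt (the *C. virginica* sizes) on a
16-kb circle with eleven 70-nt tRNAs and nine 450-nt protein genes filling
the inter-fragment arc.  Both default inter-fragment gaps exceed the PCR
`max_len`, as in the real genomes.  The base immediately downstream of each
fragment's 3' end is forced non-A: a gene whose next genomic base is A has
no identifiable polyadenylation site (templated and non-templated adenines
are indistinguishable), so the synthetic truth would otherwise be
unrecoverable by any method.

`simulate_ests` (default 200 ESTs) truncates the transcript 5' end by a
geometric number of bases (continuation probability 0.01), substitutes
bases at 0.005 per site, and appends a non-templated poly(A) tail of
Poisson(30) length after truncation and error — matching cDNA reality.
`simulate_structured_alignment` uses a star phylogeny (independent rows
from a root): each true base pair is jointly resampled from the six
canonical pairs with probability `pair_sub_rate` (a compensatory double
substitution), each unpaired position substitutes independently at
`bg_sub_rate`.  This is deliberately the simplest process that produces
covariation; trees, indels, rate heterogeneity and quality scores are out
of scope.  All emissions are reproducible from (config, seed) with one
explicit RNG stream per operation.

What passing synthetic tests do **not** show: real alignments have indels,
phylogenetic correlation (which inflates MI between co-inherited columns),
and alignment error; real EST collections have chimeras, strand mixtures
and internal priming.  Scores on this generator are upper bounds on real
performance, not estimates of it.

## Sequence statistics

A+T / G+C percentages are rounded half-up to integers and reconciled to sum
to 100 (the G+C value is the complement of the rounded A+T value);
ambiguity codes are excluded from the denominator.  Pairwise identity uses
a Needleman–Wunsch global alignment (match +1, mismatch −1, linear gap −2,
via `Bio.Align.PairwiseAligner`) and divides identical columns by the full
alignment length, so gapped columns count against identity; a switch
divides by aligned (non-gap) columns instead, since published identity
tables rarely state their convention — comparisons against such tables
should allow ±2 percentage points for this.  The species matrix is
asymmetric by design: upper triangle 5'-fragment identities, lower triangle
3'-fragment identities, NA where a fragment is missing (one of the
*C. hongkongensis* records lacks the 5' fragment).

## Problem sizes and determinism

The end-to-end experiments run at desk scale: alignments of 100 rows × 89
columns (30 true pairs), 200 ESTs per boundary run, 20 seeded runs for the
recovery rate, 16-kb genomes.  The full test suite and the acceptance
script each complete in well under a minute.  Every stochastic step takes
an explicit integer seed; `scripts/acceptance.py` threads its `--seed`
through all of them.

## Known limitations

- Accession-based statistics require the user to supply the GenBank FASTA
  files; the package ships coordinates only.
- The EST matcher is a utility for synthetic (substitution-error) data;
  it is not a spliced aligner and does not handle strand inference or
  chimeric reads.
- Covariation has no APC correction, covariance-model or significance
  machinery; it implements the classical MI/χ² comparative statistics.
- For *C. gigas* two published 5'-start candidates exist (5103, first base
  after *trnQ*; 5117, extreme transcript position).  Both are carried in
  the coordinate table; the 5117-based length (587 nt) matches the
  published summary table and is the default.
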