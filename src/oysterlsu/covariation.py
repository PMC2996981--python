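"""Covariation statistics between alignment columns and base-pair prediction.

Comparative structure analysis rests on one observation: columns that form a
conserved base pair accumulate *compensatory* double substitutions (AU -> GC
and so on), so their letter distributions are statistically dependent even
when neither column is conserved.  This module quantifies that dependence
with mutual information (in bits) and the Pearson chi-square statistic on the
joint letter table, and turns a ranked list of column pairs into a predicted
secondary structure with a greedy mutual-best assignment.

Gap handling is pairwise deletion: rows gapped at either column are dropped
for that pair, and the surviving row count is reported as ``n_eff`` so users
can see the loss of power.  MI uses plug-in frequencies with no pseudocounts;
at small ``n_eff`` it is biased upward, which is why a minimum ``n_eff`` is
enforced rather than patched over.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

from .formats import FormatError, SecondaryStructure, read_fasta

__all__ = [
    "RnaAlignment",
    "ColumnPairStat",
    "UninformativeColumn",
    "column_profile",
    "mutual_information",
    "pair_chi_square",
    "covariation_matrix",
    "predict_pairs",
    "canonical_pair_candidates",
    "write_stats_tsv",
]

RNA_LETTERS = ("A", "C", "G", "U")
CANONICAL = frozenset(["AU", "UA", "GC", "CG", "GU", "UG"])


class UninformativeColumn(ValueError):
    """A column carries no usable letters (all gaps)."""


@dataclass(frozen=True)
class RnaAlignment:
    """A gapped multiple alignment over {A,C,G,U,-}."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise FormatError("alignment needs at least 2 rows")
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in count")
        rows = tuple(r.upper().replace("T", "U") for r in self.rows)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "ids", tuple(self.ids))
        length = len(rows[0])
        for name, row in zip(self.ids, rows):
            if len(row) != length:
                raise FormatError(
                    f"row {name!r} has length {len(row)}, expected {length}"
                )
            bad = set(row) - set(RNA_LETTERS) - {"-", "N"}
            if bad:
                raise FormatError(f"row {name!r}: illegal characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, i: int) -> str:
        if not (1 <= i <= self.length):
            raise IndexError(f"column {i} outside 1..{self.length}")
        return "".join(row[i - 1] for row in self.rows)

    @classmethod
    def from_fasta(cls, path) -> "RnaAlignment":
        records = read_fasta(path, alphabet="rna", allow_gaps=True)
        ids, rows = zip(*records)
        return cls(ids=ids, rows=rows)


@dataclass(frozen=True)
class ColumnPairStat:
    """Covariation statistics for one unordered column pair (i < j)."""

    i: int
    j: int
    mi_bits: float | None
    chi2: float | None
    df: int
    n_eff: int


def column_profile(aln: RnaAlignment, i: int):
    """Letter frequencies of column *i* over non-gap rows, plus gap count.

    Returns ``(freqs, gap_count)`` where *freqs* maps A/C/G/U to frequencies
    summing to 1 over the non-gap rows.
    """
    col = aln.column(i)
    letters = [c for c in col if c != "-"]
    if not letters:
        raise UninformativeColumn(f"column {i} is entirely gaps")
    n = len(letters)
    freqs = {x: letters.count(x) / n for x in RNA_LETTERS}
    return freqs, len(col) - n


def _joint_counts(aln: RnaAlignment, i: int, j: int):
    """Joint letter counts over rows ungapped at both columns."""
    ci, cj = aln.column(i), aln.column(j)
    pairs = [(a, b) for a, b in zip(ci, cj) if a != "-" and b != "-"]
    counts: dict[tuple[str, str], int] = {}
    for ab in pairs:
        counts[ab] = counts.get(ab, 0) + 1
    return counts, len(pairs)


def mutual_information(
    aln: RnaAlignment, i: int, j: int, gap_policy: str = "pairwise", min_n_eff: int = 2
) -> float | None:
    """Mutual information between columns *i* and *j*, in bits.

    MI = sum_xy f(x,y) log2[ f(x,y) / (f(x) f(y)) ] over joint letter
    frequencies of the rows ungapped at both columns.  Returns ``None``
    (undefined, not zero) when fewer than *min_n_eff* rows survive.
    """
    if gap_policy != "pairwise":
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    counts, n = _joint_counts(aln, i, j)
    if n < min_n_eff:
        return None
    fx: dict[str, float] = {}
    fy: dict[str, float] = {}
    for (a, b), c in counts.items():
        fx[a] = fx.get(a, 0) + c / n
        fy[b] = fy.get(b, 0) + c / n
    mi = 0.0
    for (a, b), c in counts.items():
        fab = c / n
        mi += fab * math.log2(fab / (fx[a] * fy[b]))
    return max(mi, 0.0)


def pair_chi_square(
    aln: RnaAlignment, i: int, j: int, gap_policy: str = "pairwise", min_n_eff: int = 2
):
    """Pearson chi-square of association between two columns.

    The contingency table is built over the letter categories actually
    observed in each column, so ``df = (r-1)(c-1)`` for *r*, *c* observed
    categories.  A single-category column gives ``(0.0, 0)``.  Returns
    ``(None, 0)`` when fewer than *min_n_eff* rows survive the gap policy.
    """
    if gap_policy != "pairwise":
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    counts, n = _joint_counts(aln, i, j)
    if n < min_n_eff:
        return None, 0
    rows = sorted({a for a, _ in counts})
    cols = sorted({b for _, b in counts})
    if len(rows) < 2 or len(cols) < 2:
        return 0.0, 0
    table = np.array(
        [[counts.get((a, b), 0) for b in cols] for a in rows], dtype=float
    )
    chi2, _, df, _ = chi2_contingency(table, correction=False)
    return float(chi2), int(df)


def covariation_matrix(
    aln: RnaAlignment, gap_policy: str = "pairwise", min_n_eff: int = 5
):
    """All unordered column-pair statistics, ordered by (i, then j).

    Pairs with fewer than *min_n_eff* ungapped rows get ``mi_bits=None`` and
    ``chi2=None`` rather than a silent zero.
    """
    stats = []
    for i, j in itertools.combinations(range(1, aln.length + 1), 2):
        mi = mutual_information(aln, i, j, gap_policy, min_n_eff)
        chi2, df = pair_chi_square(aln, i, j, gap_policy, min_n_eff)
        _, n = _joint_counts(aln, i, j)
        stats.append(
            ColumnPairStat(i=i, j=j, mi_bits=mi, chi2=chi2, df=df, n_eff=n)
        )
    return stats


def consensus_letter(aln: RnaAlignment, i: int) -> str:
    """Plurality letter of a column (ties broken alphabetically)."""
    freqs, _ = column_profile(aln, i)
    return max(sorted(freqs), key=lambda x: freqs[x])


def canonical_pair_candidates(aln: RnaAlignment):
    """Column pairs whose consensus letters can form a WC or GU pair."""
    cons = {}
    for i in range(1, aln.length + 1):
        try:
            cons[i] = consensus_letter(aln, i)
        except UninformativeColumn:
            continue
    return frozenset(
        (i, j)
        for i, j in itertools.combinations(sorted(cons), 2)
        if cons[i] + cons[j] in CANONICAL
    )


def predict_pairs(
    stats,
    mi_threshold: float = 0.3,
    require_mutual_best: bool = True,
    allow_pairs=None,
    sequence: str | None = None,
) -> SecondaryStructure:
    """Greedy base-pair prediction from covariation statistics.

    Candidates are sorted by MI descending (ties: higher chi-square, then
    smaller *i*); a pair (i, j) is accepted when both columns are still
    unassigned, MI >= *mi_threshold*, and — with *require_mutual_best* — each
    column is the other's best remaining partner.  *allow_pairs*, when given,
    restricts candidates (e.g. to consensus-canonical pairs from
    :func:`canonical_pair_candidates`).

    *sequence* supplies the structure's sequence; defaults to N's spanning
    the highest column index seen.
    """
    defined = [s for s in stats if s.mi_bits is not None]
    if allow_pairs is not None:
        allow = {(min(i, j), max(i, j)) for i, j in allow_pairs}
        defined = [s for s in defined if (s.i, s.j) in allow]
    order = sorted(
        defined, key=lambda s: (-s.mi_bits, -(s.chi2 or 0.0), s.i, s.j)
    )
    # Per-column candidate lists, MI-descending, for the mutual-best check;
    # cursors only ever advance, so the whole pass stays near-linear.
    per_col: dict[int, list[tuple[float, int]]] = {}
    for s in defined:
        per_col.setdefault(s.i, []).append((s.mi_bits, s.j))
        per_col.setdefault(s.j, []).append((s.mi_bits, s.i))
    for lst in per_col.values():
        lst.sort(key=lambda t: -t[0])
    cursor = {p: 0 for p in per_col}

    n = max((s.j for s in stats), default=0)
    if sequence is None:
        sequence = "N" * n
    assigned: set[int] = set()
    accepted: set[tuple[int, int]] = set()

    def best_remaining(p: int) -> float:
        lst = per_col[p]
        k = cursor[p]
        while k < len(lst) and lst[k][1] in assigned:
            k += 1
        cursor[p] = k
        return lst[k][0] if k < len(lst) else -1.0

    for s in order:
        if s.mi_bits < mi_threshold:
            break
        if s.i in assigned or s.j in assigned:
            continue
        if require_mutual_best and (
            s.mi_bits < best_remaining(s.i) or s.mi_bits < best_remaining(s.j)
        ):
            continue
        accepted.add((s.i, s.j))
        assigned.update((s.i, s.j))
    from .formats import _has_crossing  # local: avoid public re-export

    return SecondaryStructure(
        sequence=sequence,
        pairs=frozenset(accepted),
        pseudoknot=_has_crossing(accepted),
    )


def write_stats_tsv(stats, path) -> None:
    """TSV rendering of column-pair statistics (i, j, mi_bits, chi2, df, n_eff)."""
    with open(path, "w") as fh:
        fh.write("i\tj\tmi_bits\tchi2\tdf\tn_eff\n")
        for s in stats:
            mi = "NA" if s.mi_bits is None else f"{s.mi_bits:.6f}"
            chi2 = "NA" if s.chi2 is None else f"{s.chi2:.6f}"
            fh.write(f"{s.i}\t{s.j}\t{mi}\t{chi2}\t{s.df}\t{s.n_eff}\n")
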