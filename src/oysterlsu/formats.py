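"""File formats and coordinate conventions shared by every stage.

All genomic coordinates in this package are 1-based and inclusive on both
ends (GenBank/GFF3 style).  Genomic sequences are stored as DNA (with T);
alignment and secondary-structure sequences are RNA (with U); conversion
happens explicitly at module boundaries via :func:`transcribe` /
:func:`reverse_transcribe`.

Circular molecules may carry origin-spanning features, encoded as
``start > end``; the feature then covers ``start..L`` followed by ``1..end``.

Readers here reject malformed input instead of repairing it: the error
message names the offending record, position or row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import SeqIO

__all__ = [
    "FormatError",
    "CoordinateError",
    "GeneFeature",
    "CircularGenome",
    "SecondaryStructure",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_dotbracket",
    "to_dotbracket",
    "read_ct",
    "write_ct",
    "transcribe",
    "reverse_transcribe",
    "reverse_complement",
]

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")
GAP = "-"

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

FEATURE_KINDS = ("tRNA", "rRNA_fragment", "CDS", "other")


class FormatError(ValueError):
    """A file violates its format contract."""


class CoordinateError(ValueError):
    """A coordinate falls outside the molecule or violates circularity rules."""


def transcribe(dna: str) -> str:
    """DNA coding strand -> RNA (T becomes U)."""
    return dna.upper().replace("T", "U")


def reverse_transcribe(rna: str) -> str:
    """RNA -> DNA alphabet (U becomes T)."""
    return rna.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    """Reverse complement; accepts DNA or RNA, returns DNA."""
    return reverse_transcribe(seq)[::-1].translate(_COMPLEMENT)


@dataclass(frozen=True)
class GeneFeature:
    """A gene on a (possibly circular) genome, 1-based inclusive.

    ``start > end`` encodes an origin-spanning feature and is only legal on a
    circular genome.
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"feature {self.name!r}: coordinates are 1-based, got "
                f"({self.start}, {self.end})"
            )

    @property
    def wraps_origin(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass(frozen=True)
class CircularGenome:
    """A nucleotide molecule (DNA, uppercase) with annotated features."""

    accession: str
    sequence: str
    is_circular: bool = True
    features: tuple[GeneFeature, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise FormatError(f"{self.accession}: empty sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(seq, start=1) if c in bad)
            raise FormatError(
                f"{self.accession}: illegal character {seq[pos - 1]!r} at "
                f"position {pos}"
            )
        object.__setattr__(self, "features", tuple(self.features))
        for f in self.features:
            self._check_feature(f)

    def _check_feature(self, f: GeneFeature) -> None:
        n = len(self.sequence)
        if f.start > n or f.end > n:
            raise CoordinateError(
                f"feature {f.name!r} ({f.start}, {f.end}) exceeds genome "
                f"length {n}"
            )
        if f.wraps_origin and not self.is_circular:
            raise CoordinateError(
                f"feature {f.name!r} spans the origin but {self.accession} "
                "is linear"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def extract(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of the 1-based inclusive interval, honouring circularity.

        ``start > end`` wraps the origin (circular genomes only).  For the
        minus strand the reverse complement is returned.
        """
        n = len(self.sequence)
        if not (1 <= start <= n and 1 <= end <= n):
            raise CoordinateError(f"interval ({start}, {end}) outside 1..{n}")
        if start <= end:
            seq = self.sequence[start - 1 : end]
        else:
            if not self.is_circular:
                raise CoordinateError(
                    f"interval ({start}, {end}) wraps the origin of a "
                    "linear genome"
                )
            seq = self.sequence[start - 1 :] + self.sequence[:end]
        if strand == "-":
            seq = reverse_complement(seq)
        return seq

    def with_features(self, features) -> "CircularGenome":
        return replace(self, features=tuple(features))


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA sequence plus a non-redundant set of base pairs.

    Pairs are 1-based ``(i, j)`` with ``i < j`` and each position in at most
    one pair.  ``pseudoknot`` is set when the pair set is non-nested.
    Optional per-position labels assign structural domains (I-VI) and the
    molluscan helix features (a/b/c).
    """

    sequence: str
    pairs: frozenset[tuple[int, int]] = frozenset()
    pseudoknot: bool = False
    domain_labels: dict[int, str] | None = None
    feature_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - RNA_ALPHABET - {GAP}
        if bad:
            raise FormatError(f"illegal structure characters: {sorted(bad)}")
        pairs = frozenset(
            (min(i, j), max(i, j)) for i, j in self.pairs
        )
        object.__setattr__(self, "pairs", pairs)
        n = len(seq)
        seen: set[int] = set()
        for i, j in sorted(pairs):
            if i == j:
                raise FormatError(f"position {i} paired with itself")
            if not (1 <= i <= n and 1 <= j <= n):
                raise FormatError(f"pair ({i}, {j}) outside sequence 1..{n}")
            for p in (i, j):
                if p in seen:
                    raise FormatError(f"position {p} occurs in two pairs")
                seen.add(p)
        if not self.pseudoknot and _has_crossing(pairs):
            raise FormatError("crossing pairs present but pseudoknot flag unset")

    def __len__(self) -> int:
        return len(self.sequence)

    def partner(self, i: int) -> int | None:
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None


def _has_crossing(pairs) -> bool:
    ps = sorted(pairs)
    for a in range(len(ps)):
        i, j = ps[a]
        for k, l in ps[a + 1 :]:
            if i < k < j < l:
                return True
    return False


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: str | None = None, allow_gaps: bool = False):
    """Read a multi-record FASTA file as a list of ``(id, sequence)``.

    Sequences are uppercased; ``alphabet`` may be ``"dna"`` or ``"rna"`` to
    normalize U<->T, or ``None`` to keep letters as found.  Duplicate ids,
    empty files, and characters outside {A,C,G,T,U,N} (plus ``-`` when
    ``allow_gaps``) are errors.
    """
    records = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate FASTA id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            if alphabet == "dna":
                seq = seq.replace("U", "T")
            elif alphabet == "rna":
                seq = seq.replace("T", "U")
            elif alphabet is not None:
                raise ValueError(f"unknown alphabet {alphabet!r}")
            allowed = set("ACGTUN") | ({GAP} if allow_gaps else set())
            for pos, c in enumerate(seq, start=1):
                if c not in allowed:
                    raise FormatError(
                        f"record {rec.id!r}: illegal character {c!r} at "
                        f"position {pos}"
                    )
            records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
#
# Hand-rolled on purpose: the contract here is strict nine-column validation
# with errors that name the offending line, which the DB-building GFF
# libraries do not give us.

_GFF_KIND = {
    "tRNA": "tRNA",
    "rRNA": "rRNA_fragment",
    "rRNA_fragment": "rRNA_fragment",
    "CDS": "CDS",
}


def read_gff3(path, genome: CircularGenome):
    """Parse GFF3 into :class:`GeneFeature` records validated against *genome*.

    Coordinates are 1-based inclusive.  ``start > end`` is accepted only on a
    circular genome (origin-spanning feature).
    """
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            _, _, ftype, start_s, end_s, _, strand, _, attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            n = len(genome)
            if not (1 <= start <= n and 1 <= end <= n):
                raise CoordinateError(
                    f"{path}:{lineno}: coordinates ({start}, {end}) outside "
                    f"genome 1..{n}"
                )
            if start > end and not genome.is_circular:
                raise CoordinateError(
                    f"{path}:{lineno}: start > end on a linear genome"
                )
            name = _attr(attrs, "Name") or _attr(attrs, "ID") or ftype
            features.append(
                GeneFeature(
                    name=name,
                    start=start,
                    end=end,
                    strand=strand,
                    kind=_GFF_KIND.get(ftype, "other"),
                )
            )
    return features


def _attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


_KIND_GFF = {"tRNA": "tRNA", "rRNA_fragment": "rRNA", "CDS": "CDS", "other": "region"}


def write_gff3(genome: CircularGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.accession} 1 {len(genome)}\n")
        for f in genome.features:
            fh.write(
                "\t".join(
                    [
                        genome.accession,
                        "oysterlsu",
                        _KIND_GFF[f.kind],
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.name};Name={f.name}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Dot-bracket

_OPENERS = {"(": ")", "[": "]"}


def read_dotbracket(text: str, sequence: str | None = None) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    ``()`` carries the nested layer; ``[]`` carries one pseudoknot layer.
    The pseudoknot flag is set whenever any two pairs cross.  An unmatched
    bracket is an error naming its position.
    """
    text = text.strip()
    if sequence is None:
        sequence = "N" * len(text)
    if len(sequence) != len(text):
        raise FormatError(
            f"sequence length {len(sequence)} != structure length {len(text)}"
        )
    stacks: dict[str, list[int]] = {"(": [], "[": []}
    pairs: set[tuple[int, int]] = set()
    for pos, c in enumerate(text, start=1):
        if c in _OPENERS:
            stacks[c].append(pos)
        elif c in (")", "]"):
            opener = "(" if c == ")" else "["
            if not stacks[opener]:
                raise FormatError(f"unmatched {c!r} at position {pos}")
            pairs.add((stacks[opener].pop(), pos))
        elif c != ".":
            raise FormatError(f"illegal structure character {c!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise FormatError(f"unmatched {opener!r} at position {stack[-1]}")
    return SecondaryStructure(
        sequence=sequence, pairs=frozenset(pairs), pseudoknot=_has_crossing(pairs)
    )


def to_dotbracket(structure: SecondaryStructure) -> str:
    """Render a structure as dot-bracket; crossing pairs go to the [] layer."""
    out = ["."] * len(structure)
    nested: list[tuple[int, int]] = []
    knotted: list[tuple[int, int]] = []
    for pair in sorted(structure.pairs):
        i, j = pair
        if any(a < i < b < j or i < a < j < b for a, b in nested):
            knotted.append(pair)
        else:
            nested.append(pair)
    for i, j in nested:
        out[i - 1], out[j - 1] = "(", ")"
    for i, j in knotted:
        if any(a < i < b < j or i < a < j < b for a, b in knotted if (a, b) != (i, j)):
            raise FormatError("structure needs more than one pseudoknot layer")
        out[i - 1], out[j - 1] = "[", "]"
    return "".join(out)


# ---------------------------------------------------------------------------
# CT (Zuker dialect: header "N  title", then 6 columns)


def write_ct(structure: SecondaryStructure, path, title: str = "structure") -> None:
    partner = {i: j for i, j in structure.pairs}
    partner.update({j: i for i, j in structure.pairs})
    with open(path, "w") as fh:
        fh.write(f"{len(structure)}\t{title}\n")
        n = len(structure)
        for i, base in enumerate(structure.sequence, start=1):
            fh.write(
                f"{i}\t{base}\t{i - 1}\t{(i + 1) % (n + 1)}\t"
                f"{partner.get(i, 0)}\t{i}\n"
            )


def read_ct(path) -> SecondaryStructure:
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty CT file")
        try:
            n = int(header.split()[0])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: bad CT header {header!r}") from exc
        bases: list[str] = []
        partner: dict[int, int] = {}
        for row, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) < 6:
                raise FormatError(f"{path}:{row}: expected 6 CT columns")
            i, base, j = int(cols[0]), cols[1], int(cols[4])
            bases.append(base)
            if j:
                partner[i] = j
    if len(bases) != n:
        raise FormatError(f"{path}: header says {n} rows, found {len(bases)}")
    pairs: set[tuple[int, int]] = set()
    for i, j in partner.items():
        if partner.get(j) != i:
            raise FormatError(
                f"{path}: inconsistent pairing rows {i} and {j} "
                f"({i}->{j} but {j}->{partner.get(j, 0)})"
            )
        pairs.add((min(i, j), max(i, j)))
    return SecondaryStructure(
        sequence="".join(bases), pairs=frozenset(pairs),
        pseudoknot=_has_crossing(pairs),
    )
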