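"""Synthetic genomes, ESTs, and covarying alignments with known ground truth.

The generator emulates the situation found in cupped-oyster mitochondrial
genomes: a circular, A+T-rich molecule whose LSU rRNA gene is encoded as two
fragments (a 5' half and a 3' half) separated by blocks of tRNA and
protein-coding genes, with transcripts of each fragment polyadenylated at the
fragment's 3' boundary.  Every emission is reproducible from ``(config,
seed)`` and ships a machine-readable truth record so downstream inference can
be scored exactly.

The alignment simulator uses a star phylogeny: each row is drawn
independently from a root sequence.  Positions that are base-paired in the
true structure are jointly resampled from the six canonical pairs
(compensatory substitution); unpaired positions mutate independently.  This
is deliberately the simplest process that produces covariation — tree
correlation, indels and rate heterogeneity are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .formats import (
    CircularGenome,
    GeneFeature,
    SecondaryStructure,
    transcribe,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "EstTruth",
    "simulate_genome",
    "simulate_ests",
    "simulate_structured_alignment",
    "demo_structure",
]

CANONICAL_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")

# Default layout mirrors the oyster arrangement at reduced scale: the 3' half
# sits early in the numbering, the 5' half later, so the transcription-order
# gap (5' half -> forward around the circle -> 3' half) wraps the origin and
# is several kilobases long, and eleven tRNAs plus nine protein genes fill
# the complementary arc.
DEFAULT_GENOME_LENGTH = 16_000
DEFAULT_FRAG5 = (8_000, 8_747)   # 748 nt, like the C. virginica 5' half
DEFAULT_FRAG3 = (1_500, 2_218)   # 719 nt, like the C. virginica 3' half
DEFAULT_SPACERS = tuple(
    [("tRNA", 70)] * 11 + [("CDS", 450)] * 9
)
DEFAULT_AT_FRACTION = 0.65       # molluscan mtDNA is A+T rich


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic fragmented-gene system.

    ``trunc_geometric_p`` is the per-base probability that 5'-truncation of
    an EST continues one base further (geometric tail; p -> 0 means
    full-length transcripts).  ``error_rate`` is the per-base substitution
    probability.  ``polya_mean`` is the Poisson mean of the non-templated
    poly(A) tail length.
    """

    genome_length: int = DEFAULT_GENOME_LENGTH
    frag5: tuple[int, int] = DEFAULT_FRAG5
    frag3: tuple[int, int] = DEFAULT_FRAG3
    spacer_features: tuple[tuple[str, int], ...] = DEFAULT_SPACERS
    est_count: int = 200
    trunc_geometric_p: float = 0.01
    error_rate: float = 0.005
    polya_mean: float = 30.0
    at_fraction: float = DEFAULT_AT_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "frag5", tuple(self.frag5))
        object.__setattr__(self, "frag3", tuple(self.frag3))
        object.__setattr__(
            self, "spacer_features", tuple(map(tuple, self.spacer_features))
        )
        for name, value in (
            ("trunc_geometric_p", self.trunc_geometric_p),
            ("error_rate", self.error_rate),
            ("at_fraction", self.at_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.trunc_geometric_p >= 1.0:
            raise ConfigError("trunc_geometric_p must be < 1")
        if self.polya_mean < 0:
            raise ConfigError("polya_mean must be >= 0")
        for label, (s, e) in (("frag5", self.frag5), ("frag3", self.frag3)):
            if not (1 <= s <= e <= self.genome_length):
                raise ConfigError(
                    f"{label}={s, e} must be an increasing interval within "
                    f"1..{self.genome_length}"
                )
        a, b = sorted([self.frag5, self.frag3])
        if b[0] <= a[1]:
            raise ConfigError(
                f"fragment intervals {self.frag5} and {self.frag3} overlap"
            )


@dataclass(frozen=True)
class EstTruth:
    """Ground truth for one simulated EST."""

    est_id: str
    genomic_start: int
    genomic_end: int
    tail_length: int
    n_errors: int


@dataclass
class SimTruth:
    """Everything the generator knows that inference must recover."""

    frag5: tuple[int, int] | None = None
    frag3: tuple[int, int] | None = None
    structure_pairs: frozenset = frozenset()
    ests: list[EstTruth] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "frag5": self.frag5,
            "frag3": self.frag3,
            "structure_pairs": sorted(map(list, self.structure_pairs)),
            "ests": [asdict(e) for e in self.ests],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _random_seq(rng: np.random.Generator, n: int, at_fraction: float) -> str:
    p = np.array(
        [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2,
         at_fraction / 2]
    )
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def simulate_genome(config: SimConfig) -> tuple[CircularGenome, SimTruth]:
    """Draw a circular genome with the two rRNA fragments and spacer genes.

    Fragment features sit exactly at the configured intervals.  Spacer
    features are laid head-to-tail in the arc between the fragments (in the
    direction that fits them), alternating strand for a little realism; a
    layout that does not fit is a configuration error.
    """
    rng = np.random.default_rng(config.seed)
    seq = _random_seq(rng, config.genome_length, config.at_fraction)
    # A fragment whose next genomic base is A has no identifiable
    # polyadenylation site (templated and non-templated adenines are
    # indistinguishable); keep the synthetic boundaries well-posed by
    # forcing a non-A immediately downstream of each fragment's 3' end.
    chars = list(seq)
    for _, end in (config.frag5, config.frag3):
        nxt = end % config.genome_length  # 0-based index of position end+1
        if chars[nxt] == "A":
            chars[nxt] = rng.choice(list("CGT"))
    seq = "".join(chars)
    features = [
        GeneFeature("rrnL5", *config.frag5, "+", "rRNA_fragment"),
        GeneFeature("rrnL3", *config.frag3, "+", "rRNA_fragment"),
    ]
    # place spacers in the arc running forward from the earlier fragment's
    # end to the later fragment's start
    (a_start, a_end), (b_start, b_end) = sorted([config.frag5, config.frag3])
    arc_start, arc_end = a_end + 1, b_start - 1
    cursor = arc_start
    for k, (kind, length) in enumerate(config.spacer_features):
        if cursor + length - 1 > arc_end:
            raise ConfigError(
                f"spacer features overflow the inter-fragment arc "
                f"({arc_start}..{arc_end}) at feature {k}"
            )
        features.append(
            GeneFeature(
                f"{kind.lower()}_{k:02d}", cursor, cursor + length - 1,
                "+" if k % 2 == 0 else "-", kind,
            )
        )
        cursor += length
    genome = CircularGenome(
        accession="SYN_MITO_1", sequence=seq, is_circular=True,
        features=tuple(features),
    )
    truth = SimTruth(frag5=config.frag5, frag3=config.frag3)
    return genome, truth


def simulate_ests(
    genome: CircularGenome,
    gene_interval: tuple[int, int],
    config: SimConfig,
    strand: str = "+",
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Simulate polyadenylated ESTs of one gene fragment.

    Each EST is the gene sequence (5'->3' on *strand*) truncated at a
    geometric random 5' point, substituted at ``error_rate``, with a
    non-templated poly(A) tail of Poisson(``polya_mean``) length appended.
    Returns FASTA-style ``(id, sequence)`` records (DNA alphabet) and the
    per-EST truth.
    """
    if config.est_count <= 0:
        raise ConfigError("est_count must be positive")
    start, end = gene_interval
    gene = genome.extract(start, end, strand)
    rng = np.random.default_rng(config.seed + 1)
    records: list[tuple[str, str]] = []
    truth = SimTruth(frag5=None, frag3=None)
    bases = np.frombuffer(gene.encode(), dtype="S1")
    alphabet = np.array(list("ACGT"), dtype="S1")
    for k in range(config.est_count):
        p = config.trunc_geometric_p
        trunc = int(rng.geometric(1.0 - p) - 1) if p > 0 else 0
        trunc = min(trunc, len(gene) - 1)
        body = bases[trunc:].copy()
        errs = rng.random(body.size) < config.error_rate
        n_err = int(errs.sum())
        if n_err:
            body[errs] = alphabet[rng.integers(0, 4, size=n_err)]
        tail = int(rng.poisson(config.polya_mean)) if config.polya_mean > 0 else 0
        seq = body.tobytes().decode() + "A" * tail
        if strand == "+":
            g_start, g_end = start + trunc, end
        else:
            g_start, g_end = start, end - trunc
        est_id = f"est_{k:04d}"
        records.append((est_id, seq))
        truth.ests.append(
            EstTruth(
                est_id=est_id, genomic_start=g_start, genomic_end=g_end,
                tail_length=tail, n_errors=n_err,
            )
        )
    return records, truth


def demo_structure(n_helices: int = 6, helix_len: int = 5, loop_len: int = 4,
                   seed: int = 7) -> SecondaryStructure:
    """A nested multi-helix RNA with canonical pairs, for simulations.

    Helices are arranged side by side ( (((( .... )))) )*, giving
    ``n_helices * helix_len`` true pairs over a sequence of
    ``n_helices * (2 * helix_len + loop_len) + (n_helices - 1)`` nt.
    """
    rng = np.random.default_rng(seed)
    seq: list[str] = []
    pairs: set[tuple[int, int]] = set()
    pos = 1
    for h in range(n_helices):
        if h:
            seq.append("A")  # single-stranded linker
            pos += 1
        left = pos
        stems = [rng.choice(CANONICAL_PAIRS) for _ in range(helix_len)]
        for s in stems:
            seq.append(s[0])
        for _ in range(loop_len):
            seq.append(rng.choice(list("ACGU")))
        for s in reversed(stems):
            seq.append(s[1])
        right = left + 2 * helix_len + loop_len - 1
        for k in range(helix_len):
            pairs.add((left + k, right - k))
        pos = right + 1
    return SecondaryStructure(sequence="".join(seq), pairs=frozenset(pairs))


def simulate_structured_alignment(
    structure: SecondaryStructure,
    n_seqs: int,
    pair_sub_rate: float,
    bg_sub_rate: float,
    seed: int,
):
    """Sample an alignment whose paired columns covary.

    Star phylogeny from the structure's sequence as root: for every true
    pair, each row keeps the root pair with probability ``1 - pair_sub_rate``
    and otherwise draws one of the six canonical pairs uniformly (a
    compensatory double substitution); every unpaired position independently
    substitutes to a uniform different base with probability ``bg_sub_rate``.
    Gap-free by construction.  Returns an :class:`RnaAlignment`.
    """
    from .covariation import RnaAlignment  # late import, avoids cycle

    if n_seqs < 2:
        raise ConfigError("n_seqs must be >= 2")
    for name, rate in (("pair_sub_rate", pair_sub_rate), ("bg_sub_rate", bg_sub_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1]")
    if structure.pseudoknot:
        raise ConfigError("simulator requires a nested structure")
    rng = np.random.default_rng(seed)
    root = transcribe(structure.sequence)
    n = len(root)
    paired_pos = {p for ij in structure.pairs for p in ij}
    unpaired = [p for p in range(1, n + 1) if p not in paired_pos]
    others = {b: [x for x in "ACGU" if x != b] for b in "ACGU"}
    rows = []
    for _ in range(n_seqs):
        row = list(root)
        for i, j in sorted(structure.pairs):
            if rng.random() < pair_sub_rate:
                pair = CANONICAL_PAIRS[rng.integers(0, len(CANONICAL_PAIRS))]
                row[i - 1], row[j - 1] = pair[0], pair[1]
        for p in unpaired:
            if rng.random() < bg_sub_rate:
                row[p - 1] = others[root[p - 1]][rng.integers(0, 3)]
        rows.append("".join(row))
    ids = tuple(f"seq_{k:03d}" for k in range(n_seqs))
    return RnaAlignment(ids=ids, rows=tuple(rows))
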