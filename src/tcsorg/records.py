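"""Core record types: genes, domain hits, intervals, clusters and foci.

Coordinates are 1-based and fully inclusive (GFF convention) and always stored
on the forward axis regardless of strand, so ``start <= end`` for every gene.
A gene on the minus strand simply carries ``strand == '-'``.

Foci and clusters hold member *locus tags* (plus the per-member category and
architecture strings needed by the census code) rather than embedded gene
records; members are stored in coordinate (left-to-right) order and the
5'→3' string views reverse minus-strand foci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

REPLICON_TYPES = frozenset({"chromosome", "plasmid"})
TOPOLOGIES = frozenset({"linear", "circular"})
STRANDS = frozenset({"+", "-"})
DOMAIN_CLASSES = frozenset({"h", "P", "R"})
GENE_FLAGS = frozenset({"incomplete_hk", "mispredicted"})

#: gene categories; hybrid kinases are aggregated under HK in censuses
CATEGORIES = ("HK", "hybrid_HK", "RR", "PP", "excluded")


@dataclass(frozen=True)
class GeneRecord:
    """One TCS gene with its replicon context.

    ``start``/``end`` are 1-based inclusive nucleotide positions on the
    forward axis; ``flags`` may contain ``incomplete_hk`` (treated alongside
    HKs downstream) and/or ``mispredicted`` (excluded downstream but retained
    at parse time).
    """

    locus_tag: str
    replicon_id: str
    start: int
    end: int
    strand: str
    replicon_type: str = "chromosome"
    topology: str = "linear"
    flags: frozenset = frozenset()

    def __post_init__(self):
        from .errors import RowError

        if self.start < 1:
            raise RowError(f"{self.locus_tag}: start must be >= 1 (got {self.start})")
        if self.end < self.start:
            raise RowError(
                f"{self.locus_tag}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in STRANDS:
            raise RowError(f"{self.locus_tag}: strand must be '+' or '-' (got {self.strand!r})")
        if self.replicon_type not in REPLICON_TYPES:
            raise RowError(
                f"{self.locus_tag}: replicon_type must be chromosome|plasmid "
                f"(got {self.replicon_type!r})"
            )
        if self.topology not in TOPOLOGIES:
            raise RowError(
                f"{self.locus_tag}: topology must be linear|circular (got {self.topology!r})"
            )
        unknown = set(self.flags) - GENE_FLAGS
        if unknown:
            raise RowError(f"{self.locus_tag}: unknown flags {sorted(unknown)}")
        object.__setattr__(self, "flags", frozenset(self.flags))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def sort_key(self):
        """Coordinate order; ties broken by end then locus tag."""
        return (self.start, self.end, self.locus_tag)


@dataclass(frozen=True)
class DomainHit:
    """One signalling-domain occurrence within a protein.

    ``domain_class`` is one of ``h`` (HATPase), ``P`` (phosphotransfer,
    HisKA/Hpt-type) or ``R`` (receiver); ``aa_start``/``aa_end`` are 1-based
    residue coordinates.
    """

    locus_tag: str
    domain_name: str
    domain_class: str
    aa_start: int
    aa_end: int

    def __post_init__(self):
        from .errors import RowError

        if self.domain_class not in DOMAIN_CLASSES:
            raise RowError(
                f"{self.locus_tag}/{self.domain_name}: domain_class must be one of "
                f"h/P/R (got {self.domain_class!r})"
            )
        if self.aa_start < 1 or self.aa_end < self.aa_start:
            raise RowError(
                f"{self.locus_tag}/{self.domain_name}: bad residue range "
                f"{self.aa_start}..{self.aa_end}"
            )


@dataclass(frozen=True)
class Interval:
    """Gap between two consecutive TCS genes on one replicon.

    ``distance_bp`` counts intervening bases (``right.start - left.end - 1``);
    overlapping genes give a negative distance, abutting genes give 0.
    ``orientation`` is ``cis`` when both genes share a strand, else ``trans``.
    """

    left_locus: str
    right_locus: str
    distance_bp: int
    orientation: str
    replicon_id: str
    wrap: bool = False  # True for the circular-topology terminal interval


@dataclass(frozen=True)
class Cluster:
    """Maximal run of TCS genes, strand-agnostic, gaps <= cutoff."""

    members: tuple
    replicon_id: str

    @property
    def size(self) -> int:
        return len(self.members)


def _render(parts, strand, sep):
    ordered = tuple(reversed(parts)) if strand == "-" else tuple(parts)
    return sep.join(ordered)


@dataclass(frozen=True)
class Focus:
    """Maximal same-strand run of TCS genes with gaps <= cutoff.

    ``members``, ``categories`` and ``architectures`` are aligned, in
    coordinate order.  ``gene_string``/``domain_string`` read 5'→3' (reversed
    for minus-strand foci); hybrid kinases render as ``HK`` in the gene
    string, matching the HK/RR/PP organisation alphabet.
    """

    members: tuple
    replicon_id: str
    strand: str
    categories: tuple = None
    architectures: tuple = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def focus_id(self) -> str:
        """Locus tag of the 5'-most member."""
        return self.members[-1] if self.strand == "-" else self.members[0]

    @property
    def gene_string(self):
        if self.categories is None:
            return None
        tokens = ["HK" if c == "hybrid_HK" else c for c in self.categories]
        return _render(tokens, self.strand, ">")

    @property
    def domain_string(self):
        if self.architectures is None:
            return None
        return _render(self.architectures, self.strand, "-")

    @property
    def n_domains(self):
        if self.architectures is None:
            return None
        return sum(len(a) for a in self.architectures)

    @property
    def domain_combo(self):
        """Order-free multiset of domain letters, canonically T < R < P."""
        if self.architectures is None:
            return None
        return combo_key("".join(self.architectures))


_COMBO_ORDER = {"T": 0, "R": 1, "P": 2}


def combo_key(letters: str) -> str:
    """Canonical key for an order-free multiset of T/R/P letters (T<R<P)."""
    return "".join(sorted(letters, key=_COMBO_ORDER.__getitem__))
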