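"""Published census counts used as validation-fixture inputs.

These are the printed summary tables of a genome-wide survey of TCS gene
organisation across 1,405 prokaryotic replicons (P2CS v1 annotations;
44,008 genes before curation, 43,426 after).  They serve two purposes:

* fixture builders reconstruct datasets realising the printed marginals, so
  the census code's arithmetic can be checked against the survey's printed
  summary statistics;
* the counts themselves are inputs for group-comparison statistics (e.g.
  the plasmid focus-size contingency).

Where a table is under-determined below its printed marginals (e.g. the
per-geometry split of pair foci), any integer decomposition matching the
printed totals is used; the derived statistics depend only on the marginals.
"""

from __future__ import annotations

from .architecture import Architecture
from .records import Focus

# Distribution of TCS genes between gene organisations (gene counts).
CLUSTER_GENE_COUNTS = {1: 16596, 2: 24380, 3: 2268, 4: 764}
FOCUS_GENE_COUNTS = {1: 17590, 2: 24042, 3: 1788, 4: 588}

# Gene-category totals by focus size (HK incl. hybrids / RR / PP, n_foci).
GENE_TYPE_BY_FOCUS_SIZE = {
    1: {"HK": 7854, "RR": 8858, "PP": 666, "n_foci": 17378},
    2: {"HK": 11395, "RR": 11999, "PP": 306, "n_foci": 11850},
    3: {"HK": 791, "RR": 936, "PP": 37, "n_foci": 588},
    4: {"HK": 314, "RR": 265, "PP": 5, "n_foci": 146},
}

# Histogram of TCS domains per protein; the 7+ bin comprises two 8-domain
# proteins (PPPPPPTR) and one 9-domain protein (RRTRRPRTR).
DOMAINS_PER_PROTEIN = {1: 38317, 2: 3605, 3: 1136, 4: 343, 5: 20, 6: 2}
SEVEN_PLUS_ARCHITECTURES = ["PPPPPPTR", "PPPPPPTR", "RRTRRPRTR"]

# Transmitter × receiver cross-table: (n_T, n_R) -> protein count.
T_BY_R_COUNTS = {
    (0, 0): 1014, (0, 1): 21743, (0, 2): 301, (0, 3): 14,
    (1, 0): 15702, (1, 1): 3919, (1, 2): 588, (1, 3): 88, (1, 4): 4,
    (2, 0): 2, (2, 1): 33, (2, 2): 13, (2, 3): 4, (2, 6): 1,
}

# Domain-combination counts among 3- and 4-domain proteins.
THREE_DOMAIN_COMBOS = {"TRP": 679, "TRR": 392, "other": 65}  # of 1136
FOUR_DOMAIN_COMBOS = {"TRRP": 196, "TRRR": 86, "TRPP": 36, "other": 25}  # of 343

# Gene-partition geometries of four-domain T,R,P,R ("TRPR") foci: 307 foci,
# 85 single-gene, 210 two-gene (209 of them TRP-R), 11 three-gene (9 of them
# TR-P-R), 1 four-gene.
TRPR_GEOMETRIES = {
    "TRPR": 85,
    "TRP-R": 209,
    "TR-PR": 1,
    "TR-P-R": 9,
    "T-RP-R": 2,
    "T-R-P-R": 1,
}

# Five-domain T,R,R,R,P foci: 105 foci, 81 of them two-gene TRRP-R.
TRRRP_GEOMETRIES = {"TRRP-R": 81, "TRRRP": 10, "TRR-P-R": 14}

# Plasmid-encoded focus-size contingency: observed plasmid gene counts for
# orphans/pairs/triads/tetrads vs counts expected from the whole dataset.
PLASMID_OBSERVED = [367, 366, 48, 16]
PLASMID_EXPECTED = [319, 435, 32, 19]


def _focus(categories=None, architectures=None, replicon="ref", strand="+"):
    members = tuple(
        f"x{i}" for i in range(len(categories or architectures or (None,)))
    )
    return Focus(
        members=members,
        replicon_id=replicon,
        strand=strand,
        categories=categories,
        architectures=architectures,
    )


def focus_size_fixture(counts=None):
    """Focus sizes realising the printed gene-count-by-organisation row."""
    counts = FOCUS_GENE_COUNTS if counts is None else counts
    sizes = []
    for size, n_genes in counts.items():
        n_foci, rem = divmod(n_genes, size)
        if rem:
            raise ValueError(f"gene count {n_genes} not divisible by size {size}")
        sizes.extend([size] * n_foci)
    return sizes


# Integer decomposition of the gene-type-by-focus-size marginals into
# per-focus category tuples (any decomposition matching the totals works).
_PAIR_DECOMP = [
    (("HK", "RR"), 10879),
    (("HK", "HK"), 235),
    (("RR", "RR"), 430),
    (("RR", "PP"), 260),
    (("HK", "PP"), 46),
]
_TRIAD_DECOMP = [
    (("HK", "RR", "RR"), 341),
    (("HK", "HK", "RR"), 210),
    (("HK", "RR", "PP"), 30),
    (("RR", "RR", "PP"), 7),
]
_TETRAD_DECOMP = [
    (("HK", "RR", "HK", "RR"), 104),
    (("HK", "RR", "RR", "PP"), 1),
    (("HK", "RR", "PP", "HK"), 4),
    (("HK", "HK", "HK", "RR"), 23),
    (("HK", "HK", "RR", "RR"), 14),
]


def gene_type_fixture():
    """Per-focus category tuples realising the printed category marginals."""
    foci = []
    row1 = GENE_TYPE_BY_FOCUS_SIZE[1]
    for cat in ("HK", "RR", "PP"):
        foci.extend([(cat,)] * row1[cat])
    for decomp in (_PAIR_DECOMP, _TRIAD_DECOMP, _TETRAD_DECOMP):
        for cats, n in decomp:
            foci.extend([cats] * n)
    return foci


def domains_per_protein_fixture():
    """Architectures realising the printed domains-per-protein histogram."""
    archs = []
    for n, count in DOMAINS_PER_PROTEIN.items():
        archs.extend([Architecture.from_string("R" * n)] * count)
    archs.extend(Architecture.from_string(s) for s in SEVEN_PLUS_ARCHITECTURES)
    return archs


def t_by_r_fixture():
    """Architectures realising the printed transmitter × receiver table."""
    archs = []
    for (t, r), count in T_BY_R_COUNTS.items():
        string = "T" * t + "R" * r or "P"  # the (0,0) cell is the PP class
        archs.extend([Architecture.from_string(string)] * count)
    return archs


def combo_fixture(combos, n_domains):
    """Architectures realising printed domain-combination counts."""
    fallback = {3: "RRR", 4: "RRRR"}[n_domains]
    archs = []
    for combo, count in combos.items():
        string = fallback if combo == "other" else combo
        archs.extend([Architecture.from_string(string)] * count)
    return archs


def geometry_fixture(geometries):
    """Foci realising printed gene-partition geometry counts."""
    foci = []
    for geometry, count in geometries.items():
        arch = tuple(geometry.split("-"))
        foci.extend([_focus(architectures=arch)] * count)
    return foci
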