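"""Synthetic multi-replicon TCS datasets with known ground truth.

The generator emulates the structure of genome-database extracts of TCS
genes: each replicon carries a sequence of planted foci (orphans, tandem
pairs, triads, tetrads) separated by background spacings far larger than any
credible linkage cut-off, with intra-focus gaps drawn from a distribution
centred near 0 bp whose left tail produces overlapping gene pairs (about
20% of tandem intervals, matching the well-documented overlap frequency of
TCS gene pairs).  Focus templates cover the standard organisations: HK-RR
pairs, hybrid-kinase orphans, phosphorelay foci (TRP-R, TRRP-R, T-R-T-R),
response-regulator and phosphotransfer orphans.  Strands are assigned per
focus; replicons are chromosomes or plasmids.

Because intra-focus gaps are truncated at ``gap_max`` and inter-focus
spacings start at ``spacing_min``, the planted partition is recoverable
exactly by focus building at any cutoff in ``[gap_max, spacing_min)``.
Non-TCS genes are not simulated: the classification pipeline never sees
them.  No nucleotide sequence is generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import Architecture, classify_gene, expand_architecture
from .errors import TCSDataError
from .records import DomainHit, GeneRecord

#: focus-size frequencies of the genome-wide survey (share of foci that are
#: orphans / pairs / triads / tetrads)
DEFAULT_SIZE_DISTRIBUTION = {1: 0.580, 2: 0.395, 3: 0.020, 4: 0.005}

#: per-size focus templates (tuples of per-gene architecture strings, 5'→3')
#: with weights; drawn after the focus size is chosen
DEFAULT_TEMPLATES = {
    1: [
        (("T",), 0.33),  # orphan HK
        (("TR",), 0.10),  # hybrid kinase: an entire TCS in one gene
        (("R",), 0.47),  # orphan RR
        (("RR",), 0.02),  # multi-receiver RR
        (("P",), 0.04),  # phosphotransfer protein
        (("TRP",), 0.04),  # orphan phosphorelay kinase
    ],
    2: [
        (("T", "R"), 0.80),  # classic HK-RR pair
        (("R", "T"), 0.10),
        (("TRP", "R"), 0.04),  # two-gene phosphorelay
        (("TRRP", "R"), 0.02),
        (("R", "R"), 0.02),
        (("R", "P"), 0.02),  # RR-PP unit
    ],
    3: [
        (("T", "R", "R"), 0.50),
        (("T", "R", "T"), 0.15),
        (("TR", "P", "R"), 0.20),  # three-gene phosphorelay
        (("T", "R", "P"), 0.15),
    ],
    4: [
        (("T", "R", "T", "R"), 0.40),
        (("R", "T", "R", "T"), 0.30),
        (("T", "R", "R", "P"), 0.15),
        (("TR", "R", "P", "R"), 0.15),
    ],
}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate the survey-scale conditions.

    ``pair_gap_loc``/``pair_gap_scale`` parameterise the normal intra-focus
    gap distribution in bp (loc 20, scale 24 gives ~20% negative gaps =
    overlapping genes), truncated to ``[overlap_min, gap_max]``;
    ``spacing_range`` is the uniform inter-focus spacing (min must exceed
    any credible cutoff).
    """

    seed: int = 0
    n_replicons: int = 5
    replicon_length_bp: int = 2_000_000
    topology: str = "linear"
    plasmid_fraction: float = 0.2
    foci_per_replicon: int = 30
    focus_size_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_SIZE_DISTRIBUTION)
    )
    pair_gap_loc: float = 20.0
    pair_gap_scale: float = 24.0
    overlap_min: int = -60
    gap_max: int = 150
    spacing_range: tuple = (1000, 20000)
    templates: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_TEMPLATES.items()})

    def validate(self):
        probs = np.array(list(self.focus_size_distribution.values()), dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise TCSDataError("focus_size_distribution probabilities must sum to 1")
        if self.spacing_range[0] <= self.gap_max:
            raise TCSDataError("spacing_range min must exceed gap_max")
        for size in self.focus_size_distribution:
            if size not in self.templates:
                raise TCSDataError(f"no templates for focus size {size}")


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the synthetic tables."""

    focus_partition: list  # list of tuples of locus tags, coordinate order
    focus_strands: list
    categories: dict  # locus_tag -> category
    architectures: dict  # locus_tag -> architecture string
    pairing_scale_bp: int  # upper end of the intra-focus gap support
    min_spacing_bp: int

    def to_dict(self):
        return {
            "focus_partition": [list(f) for f in self.focus_partition],
            "focus_strands": list(self.focus_strands),
            "categories": dict(self.categories),
            "architectures": dict(self.architectures),
            "pairing_scale_bp": self.pairing_scale_bp,
            "min_spacing_bp": self.min_spacing_bp,
        }


def _gene_length(arch_string: str) -> int:
    # ~200 aa core + ~130 aa per signalling unit, in nucleotides
    return 600 + 400 * len(arch_string)


def simulate(config: SimulationConfig):
    """Generate (genes, hits, ground_truth); deterministic given the seed.

    Raises on infeasible packing (too many foci for the replicon length).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = sorted(config.focus_size_distribution)
    size_p = np.array([config.focus_size_distribution[s] for s in sizes], float)
    size_p = size_p / size_p.sum()

    genes, hits = [], []
    partition, strands = [], []
    categories, architectures = {}, {}
    counter = 0
    for rep_i in range(config.n_replicons):
        is_plasmid = rng.random() < config.plasmid_fraction
        rep_id = f"{'pls' if is_plasmid else 'chr'}{rep_i:03d}"
        rep_type = "plasmid" if is_plasmid else "chromosome"
        cursor = int(rng.integers(config.spacing_range[0], config.spacing_range[1]))
        for _ in range(config.foci_per_replicon):
            size = int(rng.choice(sizes, p=size_p))
            menu = config.templates[size]
            weights = np.array([w for _, w in menu], float)
            template = menu[rng.choice(len(menu), p=weights / weights.sum())][0]
            strand = "+" if rng.random() < 0.5 else "-"
            arch_order = tuple(reversed(template)) if strand == "-" else template

            members = []
            for j, arch in enumerate(arch_order):
                if j > 0:
                    gap = int(
                        np.clip(
                            round(rng.normal(config.pair_gap_loc, config.pair_gap_scale)),
                            config.overlap_min,
                            config.gap_max,
                        )
                    )
                    cursor = cursor + gap  # next start = prev_end + gap + 1
                start = max(1, cursor + 1)
                end = start + _gene_length(arch) - 1
                tag = f"g{counter:06d}"
                counter += 1
                gene = GeneRecord(
                    locus_tag=tag,
                    replicon_id=rep_id,
                    start=start,
                    end=end,
                    strand=strand,
                    replicon_type=rep_type,
                    topology=config.topology,
                )
                genes.append(gene)
                members.append(tag)
                hits.extend(expand_architecture(arch, locus_tag=tag))
                architectures[tag] = arch
                categories[tag] = classify_gene(
                    Architecture.from_string(arch, tag), frozenset()
                )
                cursor = end
            partition.append(tuple(members))
            strands.append(strand)
            cursor += int(rng.integers(config.spacing_range[0], config.spacing_range[1]))
            if cursor > config.replicon_length_bp:
                raise TCSDataError(
                    f"{rep_id}: foci do not fit in replicon_length_bp={config.replicon_length_bp}"
                )
    truth = GroundTruth(
        focus_partition=partition,
        focus_strands=strands,
        categories=categories,
        architectures=architectures,
        pairing_scale_bp=config.gap_max,
        min_spacing_bp=config.spacing_range[0],
    )
    return genes, hits, truth


def mixture_intervals_config(
    seed: int = 0,
    n_replicons: int = 10,
    pairing_scale_bp: int = 150,
    foci_per_replicon: int = 40,
) -> SimulationConfig:
    """Config for cut-off recovery studies: a pairs-plus-background mixture.

    All foci are HK-RR pairs with intra-focus gaps roughly uniform over the
    pairing scale (a wide, flat-ish normal truncated at the scale), against a
    uniform background of inter-focus spacings.
    """
    return SimulationConfig(
        seed=seed,
        n_replicons=n_replicons,
        replicon_length_bp=5_000_000,
        foci_per_replicon=foci_per_replicon,
        focus_size_distribution={2: 1.0},
        pair_gap_loc=pairing_scale_bp / 2,
        pair_gap_scale=pairing_scale_bp,  # wide: near-flat over the support
        overlap_min=-30,
        gap_max=pairing_scale_bp,
        spacing_range=(1000, 20000),
        templates={2: [(("T", "R"), 1.0)]},
    )
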