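"""End-to-end composition: tables in, classified foci and metrics out."""

from __future__ import annotations

from dataclasses import dataclass, field

from .architecture import build_dataset_architectures
from .linkage import DEFAULT_CUTOFF_BP, partition_dataset


@dataclass
class ClassifiedDataset:
    """Classified genes plus their focus/cluster partition."""

    genes: list  # non-excluded GeneRecords, sorted
    foci: list
    architectures: dict  # locus_tag -> Architecture (all genes, incl. excluded)
    categories: dict  # locus_tag -> category
    n_excluded_mispredicted: int = 0
    n_excluded_isolated_h: int = 0
    mode: str = "foci"
    cutoff_bp: int = DEFAULT_CUTOFF_BP


def classify_dataset(
    genes, hits, cutoff_bp: int = DEFAULT_CUTOFF_BP, mode: str = "foci",
    replicon_lengths: dict = None,
) -> ClassifiedDataset:
    """Architecture-encode, categorise and partition a whole dataset.

    Mispredicted genes and isolated-h genes (empty architecture, not flagged
    incomplete) are excluded before distances are computed, so they neither
    join nor break foci.
    """
    archs, cats = build_dataset_architectures(genes, hits)
    kept = [g for g in genes if cats[g.locus_tag] != "excluded"]
    n_mis = sum(1 for g in genes if "mispredicted" in g.flags)
    n_iso = sum(
        1
        for g in genes
        if cats[g.locus_tag] == "excluded" and "mispredicted" not in g.flags
    )
    foci = partition_dataset(
        kept,
        cutoff_bp=cutoff_bp,
        mode=mode,
        architectures={t: a.string for t, a in archs.items()},
        categories=cats,
        replicon_lengths=replicon_lengths,
    )
    return ClassifiedDataset(
        genes=kept,
        foci=foci,
        architectures=archs,
        categories=cats,
        n_excluded_mispredicted=n_mis,
        n_excluded_isolated_h=n_iso,
        mode=mode,
        cutoff_bp=cutoff_bp,
    )
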