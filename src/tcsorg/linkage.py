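"""Inter-gene intervals and distance-based grouping into clusters and foci.

Distances count intervening bases between consecutive TCS genes on one
replicon: ``right.start - left.end - 1``, so abutting genes are 0 bp apart
and overlapping genes have negative distance.  Two consecutive genes are
linked when their distance is <= the cutoff (default 200 bp, the empirical
boundary between the tandem-pair and random regimes); a *cluster* links
regardless of strand, a *focus* additionally requires both genes on the same
strand.  Orphans are size-1 foci.  Only TCS genes participate: intervening
non-TCS genes are invisible to the distance calculation.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .errors import TCSDataError
from .records import Cluster, Focus, Interval

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    BaseEstimator = object

DEFAULT_CUTOFF_BP = 200


def _sorted_one_replicon(genes):
    if not genes:
        return []
    rep = {g.replicon_id for g in genes}
    if len(rep) > 1:
        raise TCSDataError(f"genes span multiple replicons: {sorted(rep)}")
    return sorted(genes, key=lambda g: g.sort_key)


def gene_distance(left: GeneRecord, right: GeneRecord) -> int:
    """Intervening bases between two genes in coordinate order."""
    return right.start - left.end - 1


def compute_intervals(genes, topology: str = None, replicon_length: int = None):
    """Intervals between consecutive TCS genes of one replicon.

    With circular topology the wrap interval between the last and first gene
    is appended (requires ``replicon_length``).  Fewer than two genes give an
    empty list.
    """
    genes = _sorted_one_replicon(genes)
    if len(genes) < 2:
        return []
    if topology is None:
        topology = genes[0].topology
    intervals = []
    for left, right in zip(genes, genes[1:]):
        intervals.append(
            Interval(
                left_locus=left.locus_tag,
                right_locus=right.locus_tag,
                distance_bp=gene_distance(left, right),
                orientation="cis" if left.strand == right.strand else "trans",
                replicon_id=left.replicon_id,
            )
        )
    if topology == "circular":
        if replicon_length is None:
            raise TCSDataError(
                f"{genes[0].replicon_id}: circular topology requires replicon_length"
            )
        last, first = genes[-1], genes[0]
        wrap_distance = replicon_length - last.end + first.start - 1
        intervals.append(
            Interval(
                left_locus=last.locus_tag,
                right_locus=first.locus_tag,
                distance_bp=wrap_distance,
                orientation="cis" if last.strand == first.strand else "trans",
                replicon_id=last.replicon_id,
                wrap=True,
            )
        )
    return intervals


def _runs(genes, linked):
    """Split sorted genes into maximal runs given per-adjacent-pair links.

    ``linked`` has one bool per consecutive pair plus, for circular
    replicons, a final wrap entry; a True wrap joins the last run to the
    first.  Returns a list of lists of genes, each ordered along the
    (possibly origin-crossing) run.
    """
    n = len(genes)
    runs = [[genes[0]]]
    for i in range(1, n):
        if linked[i - 1]:
            runs[-1].append(genes[i])
        else:
            runs.append([genes[i]])
    if len(linked) == n and linked[-1] and len(runs) > 1:
        runs[0] = runs.pop() + runs[0]  # wrap joins last run onto the first
    elif len(linked) == n and linked[-1] and len(runs) == 1 and n > 1:
        pass  # whole replicon is one ring; keep coordinate order
    return runs


def _link_flags(genes, intervals, cutoff_bp, same_strand):
    flags = []
    for iv, (left, right) in zip(
        intervals, list(zip(genes, genes[1:])) + [(genes[-1], genes[0])]
    ):
        ok = iv.distance_bp <= cutoff_bp
        if same_strand:
            ok = ok and left.strand == right.strand
        flags.append(ok)
    return flags


def build_clusters(
    genes, cutoff_bp: int = DEFAULT_CUTOFF_BP, topology: str = None,
    replicon_length: int = None,
):
    """Partition one replicon's genes into strand-agnostic clusters."""
    genes = _sorted_one_replicon(genes)
    if not genes:
        return []
    if len(genes) == 1:
        return [Cluster(members=(genes[0].locus_tag,), replicon_id=genes[0].replicon_id)]
    intervals = compute_intervals(genes, topology, replicon_length)
    linked = _link_flags(genes, intervals, cutoff_bp, same_strand=False)
    return [
        Cluster(members=tuple(g.locus_tag for g in run), replicon_id=genes[0].replicon_id)
        for run in _runs(genes, linked)
    ]


def build_foci(
    genes, cutoff_bp: int = DEFAULT_CUTOFF_BP, architectures: dict = None,
    categories: dict = None, topology: str = None, replicon_length: int = None,
):
    """Partition one replicon's genes into same-strand foci.

    ``architectures``/``categories`` map locus tags to architecture strings
    (or Architecture objects) and gene categories; when given, each focus
    carries 5'→3' gene and domain strings.
    """
    genes = _sorted_one_replicon(genes)
    if not genes:
        return []
    if len(genes) == 1:
        runs = [genes]
    else:
        intervals = compute_intervals(genes, topology, replicon_length)
        linked = _link_flags(genes, intervals, cutoff_bp, same_strand=True)
        runs = _runs(genes, linked)

    foci = []
    for run in runs:
        arch = None
        if architectures is not None:
            arch = tuple(
                getattr(architectures[g.locus_tag], "string", architectures[g.locus_tag])
                for g in run
            )
        cats = None
        if categories is not None:
            cats = tuple(categories[g.locus_tag] for g in run)
        foci.append(
            Focus(
                members=tuple(g.locus_tag for g in run),
                replicon_id=run[0].replicon_id,
                strand=run[0].strand,
                categories=cats,
                architectures=arch,
            )
        )
    return foci


def partition_dataset(
    genes, cutoff_bp: int = DEFAULT_CUTOFF_BP, mode: str = "foci",
    architectures: dict = None, categories: dict = None,
    replicon_lengths: dict = None,
):
    """Group a multi-replicon gene list into foci or clusters.

    Topology is taken from each replicon's gene records; ``replicon_lengths``
    supplies lengths for circular replicons.  Returns a flat list ordered by
    replicon then coordinate.
    """
    by_rep = {}
    for g in genes:
        by_rep.setdefault(g.replicon_id, []).append(g)
    out = []
    for rep_id in sorted(by_rep):
        rep_genes = by_rep[rep_id]
        length = (replicon_lengths or {}).get(rep_id)
        if mode == "clusters":
            out.extend(build_clusters(rep_genes, cutoff_bp, replicon_length=length))
        elif mode == "foci":
            out.extend(
                build_foci(
                    rep_genes, cutoff_bp, architectures=architectures,
                    categories=categories, replicon_length=length,
                )
            )
        else:
            raise ValueError(f"mode must be 'foci' or 'clusters', got {mode!r}")
    return out


SIZE_LABELS = ["1", "2", "3", "4", "5+"]


def focus_size_census(foci) -> pd.DataFrame:
    """Gene counts by focus (or cluster) size: orphans, pairs, triads, ...

    Accepts Focus/Cluster objects or bare integer sizes.  Returns one row per
    size class with the number of foci, genes, the percentage of genes and
    the ratio of genes relative to the paired-gene class.
    """
    n_foci = Counter()
    n_genes = Counter()
    for f in foci:
        size = f if isinstance(f, int) else f.size
        lab = SIZE_LABELS[-1] if size >= 5 else str(size)
        n_foci[lab] += 1
        n_genes[lab] += size
    total = sum(n_genes.values())
    paired = n_genes["2"]
    rows = []
    for lab in SIZE_LABELS:
        rows.append(
            {
                "size": lab,
                "n_foci": n_foci[lab],
                "n_genes": n_genes[lab],
                "pct_genes": 100.0 * n_genes[lab] / total if total else float("nan"),
                "ratio_vs_paired": n_genes[lab] / paired if paired else float("nan"),
            }
        )
    return pd.DataFrame(rows)


class FocusClusterer(BaseEstimator):
    """Sklearn-style clusterer over gene coordinate records.

    Parameters mirror the grouping rule: ``cutoff_bp`` is the maximum
    intervening distance for two consecutive TCS genes to be linked and
    ``mode`` selects strand-aware foci (default) or strand-agnostic clusters.

    ``fit(genes)`` accepts a list of GeneRecord (multi-replicon is fine) and
    exposes ``labels_`` (one integer partition label per input gene, aligned
    with the input order), ``partitions_`` (Focus/Cluster objects) and
    ``n_partitions_``.
    """

    def __init__(self, cutoff_bp: int = DEFAULT_CUTOFF_BP, mode: str = "foci"):
        self.cutoff_bp = cutoff_bp
        self.mode = mode

    def fit(self, X, y=None):
        genes = list(X)
        parts = partition_dataset(genes, cutoff_bp=self.cutoff_bp, mode=self.mode)
        label_of = {}
        for i, p in enumerate(parts):
            for tag in p.members:
                label_of[tag] = i
        self.partitions_ = parts
        self.labels_ = np.array([label_of[g.locus_tag] for g in genes])
        self.n_partitions_ = len(parts)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
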