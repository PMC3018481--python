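"""Domain-architecture strings and gene categorisation.

Each TCS protein is summarised as an ordered string over the alphabet
{T, R, P}, read N→C.  A transmitter (T) is an HATPase (h) domain immediately
preceded by a phosphotransfer (P) domain — the classic Ph unit of a histidine
kinase.  The scan is greedy left-to-right: every h whose immediately
preceding, still-unconsumed signalling domain is a P merges with it into one
T; an h with no such partner is dropped (isolated HATPase domains carry no
phospho-accepting histidine and are excluded from analysis).  Receiver (R)
and unpaired phosphotransfer (P) domains pass through in order.

Genes are then categorised from their string: HK (≥1 T, no R), hybrid HK
(≥1 T and ≥1 R), RR (no T, ≥1 R), PP (P only), or excluded (empty string or
a mispredicted annotation).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .records import DomainHit, combo_key

try:  # sklearn is used only for the estimator facade
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    BaseEstimator = object

    class TransformerMixin:  # noqa: D401 - minimal stand-in
        pass


@dataclass(frozen=True)
class Architecture:
    """Per-gene ordered domain string over {T, R, P} with letter counts."""

    locus_tag: str
    string: str
    dropped_h: int = 0

    @property
    def n_T(self) -> int:
        return self.string.count("T")

    @property
    def n_R(self) -> int:
        return self.string.count("R")

    @property
    def n_P(self) -> int:
        return self.string.count("P")

    @property
    def n_domains(self) -> int:
        return len(self.string)

    @property
    def combo(self) -> str:
        """Order-free multiset key (canonical T<R<P ordering)."""
        return combo_key(self.string)

    @classmethod
    def from_string(cls, string: str, locus_tag: str = "", dropped_h: int = 0):
        if set(string) - {"T", "R", "P"}:
            raise ValueError(f"architecture string may only contain T/R/P: {string!r}")
        return cls(locus_tag=locus_tag, string=string, dropped_h=dropped_h)


def build_architecture(hits, locus_tag: str = None) -> Architecture:
    """Collapse ordered h/P/R domain hits into an architecture string.

    ``hits`` may be DomainHit objects (sorted by aa_start) or bare class
    letters.  Empty input yields the empty string.
    """
    letters = []
    dropped_h = 0
    tag = locus_tag or ""
    for hit in hits:
        if isinstance(hit, DomainHit):
            cls = hit.domain_class
            tag = tag or hit.locus_tag
        else:
            cls = hit
        if cls == "h":
            if letters and letters[-1] == "P":
                letters[-1] = "T"  # Ph pair -> transmitter
            else:
                dropped_h += 1
        elif cls in ("P", "R"):
            letters.append(cls)
        else:
            raise ValueError(f"unknown domain class {cls!r}")
    return Architecture(locus_tag=tag, string="".join(letters), dropped_h=dropped_h)


def expand_architecture(arch, locus_tag: str = None):
    """Inverse of :func:`build_architecture`: emit a canonical hit list.

    Each T expands to a HisKA(P) + HATPase_c(h) pair, R to Response_reg and
    free P to Hpt, with sequential residue coordinates.  Feeding the result
    back through build_architecture reproduces the string (idempotence).
    """
    string = arch.string if isinstance(arch, Architecture) else arch
    tag = locus_tag or (arch.locus_tag if isinstance(arch, Architecture) else "")
    hits = []
    pos = 1
    for letter in string:
        if letter == "T":
            hits.append(DomainHit(tag, "HisKA", "P", pos, pos + 59))
            pos += 60
            hits.append(DomainHit(tag, "HATPase_c", "h", pos, pos + 109))
            pos += 110
        elif letter == "R":
            hits.append(DomainHit(tag, "Response_reg", "R", pos, pos + 114))
            pos += 115
        elif letter == "P":
            hits.append(DomainHit(tag, "Hpt", "P", pos, pos + 79))
            pos += 80
        else:
            raise ValueError(f"bad architecture letter {letter!r}")
        pos += 20  # linker
    return hits


def classify_gene(arch: Architecture, flags=frozenset()) -> str:
    """Categorise a gene as HK / hybrid_HK / RR / PP / excluded.

    A ``mispredicted`` flag excludes the gene outright; an empty string
    (isolated-h gene) is excluded unless the gene is flagged
    ``incomplete_hk``, which forces the HK side of the partition.
    """
    flags = frozenset(flags)
    if "mispredicted" in flags:
        return "excluded"
    s = arch.string
    if "incomplete_hk" in flags:
        return "hybrid_HK" if arch.n_R >= 1 else "HK"
    if not s:
        return "excluded"
    if arch.n_T >= 1 and arch.n_R >= 1:
        return "hybrid_HK"
    if arch.n_T >= 1:
        return "HK"
    if arch.n_R >= 1:
        return "RR"
    return "PP"


def build_dataset_architectures(genes, hits):
    """Architectures + categories for a whole dataset.

    Returns ``(architectures, categories)``: dicts keyed by locus tag, one
    entry per gene (genes with no hits get the empty architecture and are
    excluded unless flagged incomplete_hk).
    """
    per_gene = {}
    for h in hits:
        per_gene.setdefault(h.locus_tag, []).append(h)
    archs, cats = {}, {}
    for g in genes:
        gene_hits = sorted(per_gene.get(g.locus_tag, []), key=lambda h: h.aa_start)
        arch = build_architecture(gene_hits, locus_tag=g.locus_tag)
        archs[g.locus_tag] = arch
        cats[g.locus_tag] = classify_gene(arch, g.flags)
    return archs, cats


# ---------------------------------------------------------------------------
# censuses

_BIN_LABELS = ["1", "2", "3", "4", "5+"]
_HIST_LABELS = ["1", "2", "3", "4", "5", "6", "7+"]


def _bin_label(n, labels):
    top = int(labels[-1].rstrip("+"))
    return labels[-1] if n >= top else str(n)


@dataclass
class DomainCensus:
    """Per-protein domain censuses.

    ``by_domain_bin``: genes with ≥1 T/R/P by total-domain bin;
    ``domains_per_protein``: histogram of total domains per protein;
    ``t_by_r``: n_T × n_R cross-table; ``p_cross``: phosphotransfer-domain
    count cross-classified with T/R content; ``mean_domains``: mean TCS
    domains per protein (NaN for empty input).
    """

    by_domain_bin: pd.DataFrame
    domains_per_protein: pd.DataFrame
    t_by_r: pd.DataFrame
    p_cross: pd.DataFrame
    mean_domains: float


def domain_census(archs) -> DomainCensus:
    """Census of domain content across proteins (excluded genes removed)."""
    archs = [a for a in archs if a.n_domains > 0]
    if not archs:
        empty = pd.DataFrame()
        return DomainCensus(empty, empty, empty, empty, float("nan"))

    rows = {lab: Counter() for lab in _BIN_LABELS}
    hist = Counter()
    t_by_r = Counter()
    p_cross = {
        ">=1 T": Counter(),
        ">=1 R": Counter(),
        ">=1 T AND >=1 R": Counter(),
        ">=1 T OR >=1 R": Counter(),
        "P only": Counter(),
    }
    total_domains = 0
    for a in archs:
        n = a.n_domains
        total_domains += n
        lab = _bin_label(n, _BIN_LABELS)
        rows[lab]["n_genes"] += 1
        for letter, col in (("T", "T"), ("R", "R"), ("P", "P")):
            if a.string.count(letter) >= 1:
                rows[lab][col] += 1
        hist[_bin_label(n, _HIST_LABELS)] += 1
        t_by_r[(a.n_T, a.n_R)] += 1
        has_t, has_r = a.n_T >= 1, a.n_R >= 1
        if has_t:
            p_cross[">=1 T"][a.n_P] += 1
        if has_r:
            p_cross[">=1 R"][a.n_P] += 1
        if has_t and has_r:
            p_cross[">=1 T AND >=1 R"][a.n_P] += 1
        if has_t or has_r:
            p_cross[">=1 T OR >=1 R"][a.n_P] += 1
        if not has_t and not has_r:
            p_cross["P only"][a.n_P] += 1

    by_bin = pd.DataFrame(
        [[rows[lab][c] for c in ("T", "R", "P", "n_genes")] for lab in _BIN_LABELS],
        index=pd.Index(_BIN_LABELS, name="n_domains"),
        columns=["T", "R", "P", "n_genes"],
    )
    dpp = pd.DataFrame(
        [[hist[lab] for lab in _HIST_LABELS]],
        index=["n_proteins"],
        columns=pd.Index(_HIST_LABELS, name="n_domains"),
    )
    max_t = max(t for t, _ in t_by_r)
    max_r = max(r for _, r in t_by_r)
    tbr = pd.DataFrame(
        [[t_by_r[(t, r)] for r in range(max_r + 1)] for t in range(max_t + 1)],
        index=pd.Index(range(max_t + 1), name="n_T"),
        columns=pd.Index(range(max_r + 1), name="n_R"),
    )
    max_p = max(max(c) if c else 0 for c in p_cross.values())
    pc = pd.DataFrame(
        [[c[p] for p in range(max_p + 1)] for c in p_cross.values()],
        index=pd.Index(list(p_cross), name="content"),
        columns=pd.Index(range(max_p + 1), name="n_P"),
    )
    return DomainCensus(by_bin, dpp, tbr, pc, total_domains / len(archs))


def domain_combo_census(archs) -> pd.DataFrame:
    """Counts of order-free domain combinations, by total domain count.

    Returns a DataFrame with columns ``n_domains, combo, count`` sorted by
    (n_domains, -count, combo); combos use the canonical T<R<P letter order.
    """
    counts = Counter((a.n_domains, a.combo) for a in archs if a.n_domains > 0)
    rows = [
        {"n_domains": n, "combo": combo, "count": c}
        for (n, combo), c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["n_domains", "combo", "count"])
    if len(df):
        df = df.sort_values(
            ["n_domains", "count", "combo"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return df


class ArchitectureEncoder(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: per-gene domain hits → Architecture.

    ``transform`` takes an iterable of hit sequences (one per gene, each a
    list of DomainHit or class letters sorted N→C) and returns a list of
    :class:`Architecture`.  Stateless; ``fit`` records only bookkeeping
    counts (``n_genes_``, ``n_dropped_h_``).
    """

    def fit(self, X, y=None):
        archs = [build_architecture(hits) for hits in X]
        self.n_genes_ = len(archs)
        self.n_dropped_h_ = sum(a.dropped_h for a in archs)
        return self

    def transform(self, X):
        return [build_architecture(hits) for hits in X]
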