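"""Census tables, phosphorelay geometry analysis and comparative metrics.

Dataset-wide censuses mirror the standard organisation tables: gene counts by
focus size, gene category by focus size, per-focus domain content, and
geometry censuses that ask how one domain combination (e.g. the T,R,P,R of a
classical phosphorelay) is partitioned between genes.  Per-replicon metrics
summarise each replicon's organisation:

* **Dissemination** — percentage of a replicon's TCS genes that are orphans
  (size-1 foci); high values mean the TCS complement is scattered.
* **Sophistication** — percentage of TCS genes located in foci of more than
  two genes ("complex loci"); a foci-basis variant (% of foci with > 2
  genes) is available via ``basis='foci'``.
* **diversity / diversity_gt2 / n_gt2** — counts of distinct focus
  organisation strings, overall and among complex loci.

Group comparisons (e.g. plasmid vs whole-dataset focus-size distributions)
use the Pearson chi-square statistic with df = k - 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import TCSDataError
from .linkage import SIZE_LABELS, focus_size_census
from .records import combo_key

SUMMARY_COLUMNS = [
    "replicon_id",
    "replicon_type",
    "n_genes",
    "n_HK",
    "n_RR",
    "n_PP",
    "n_hybrid",
    "n_foci",
    "n_orphans",
    "n_paired_genes",
    "n_triad_genes",
    "n_tetrad_genes",
    "dissemination",
    "sophistication",
    "diversity",
    "diversity_gt2",
    "n_gt2",
    "pct_gt2",
    "avg_genes_per_focus",
    "avg_domains_per_gene",
]


def _sizes(foci):
    return [f if isinstance(f, int) else f.size for f in foci]


def dissemination(foci) -> float:
    """Percentage of genes found as orphans (size-1 foci). NaN if empty."""
    sizes = _sizes(foci)
    total = sum(sizes)
    if total == 0:
        return float("nan")
    return 100.0 * sum(1 for s in sizes if s == 1) / total


def sophistication(foci, basis: str = "genes") -> float:
    """Percentage of genes (or foci) in/among foci of more than two genes."""
    sizes = _sizes(foci)
    if basis == "genes":
        total = sum(sizes)
        num = sum(s for s in sizes if s >= 3)
    elif basis == "foci":
        total = len(sizes)
        num = sum(1 for s in sizes if s >= 3)
    else:
        raise ValueError(f"basis must be 'genes' or 'foci', got {basis!r}")
    if total == 0:
        return float("nan")
    return 100.0 * num / total


def complexity_suite(foci, basis: str = "genes") -> dict:
    """Diversity-family complexity measures over a set of foci.

    ``diversity`` counts distinct focus gene-organisation strings;
    ``diversity_gt2`` restricts to foci of more than two genes; ``n_gt2``
    counts such foci; ``pct_gt2`` is the sophistication under ``basis``.
    """
    strings = [f.gene_string for f in foci]
    if any(s is None for s in strings):
        raise TCSDataError("complexity_suite requires foci with gene strings")
    big = [f for f in foci if f.size >= 3]
    return {
        "diversity": len(set(strings)),
        "diversity_gt2": len({f.gene_string for f in big}),
        "n_gt2": len(big),
        "pct_gt2": sophistication(foci, basis=basis),
    }


def gene_type_by_focus_size(foci) -> pd.DataFrame:
    """Gene-category totals (HK incl. hybrids, RR, PP) by focus size.

    Accepts Focus objects with categories, or bare category tuples like
    ``("HK", "RR")``.  Rows are focus sizes 1..4 and 5+, with a Total row.
    """
    counts = {lab: Counter() for lab in SIZE_LABELS}
    n_foci = Counter()
    for f in foci:
        cats = f if isinstance(f, tuple) else f.categories
        if cats is None:
            raise TCSDataError("gene_type_by_focus_size requires gene categories")
        lab = SIZE_LABELS[-1] if len(cats) >= 5 else str(len(cats))
        n_foci[lab] += 1
        for c in cats:
            agg = "HK" if c in ("HK", "hybrid_HK") else c
            counts[lab][agg] += 1
    rows = []
    for lab in SIZE_LABELS:
        rows.append(
            [counts[lab]["HK"], counts[lab]["RR"], counts[lab]["PP"], n_foci[lab]]
        )
    rows.append([sum(r[i] for r in rows) for i in range(4)])
    return pd.DataFrame(
        rows,
        index=pd.Index(SIZE_LABELS + ["Total"], name="focus_size"),
        columns=["HK", "RR", "PP", "n_foci"],
    )


_FOCUS_BIN_LABELS = ["1", "2", "3", "4", "5+"]
_FOCUS_HIST_LABELS = ["1", "2", "3", "4", "5", "6", "7", "8+"]


def _bin(n, labels):
    top = int(labels[-1].rstrip("+"))
    return labels[-1] if n >= top else str(n)


@dataclass
class FociDomainCensus:
    """Per-focus domain censuses.

    ``by_domain_bin``: foci with >= 1 T/R/P by total-domain bin;
    ``domains_per_focus``: histogram of domains per focus;
    ``genes_by_domains``: domains-per-focus × genes-per-focus cross-table;
    cells count foci, and the ``total_genes`` column sums member genes so
    the marginals reconcile with the focus-size census.
    """

    by_domain_bin: pd.DataFrame
    domains_per_focus: pd.DataFrame
    genes_by_domains: pd.DataFrame


def foci_domain_census(foci) -> FociDomainCensus:
    """Census of domain content across foci (requires architectures)."""
    rows = {lab: Counter() for lab in _FOCUS_BIN_LABELS}
    hist = Counter()
    cross = Counter()  # (domain-bin, genes-per-focus) -> n_foci
    max_genes = 1
    for f in foci:
        if f.domain_string is None:
            raise TCSDataError("foci_domain_census requires foci with architectures")
        letters = "".join(f.architectures)
        n_dom = len(letters)
        if n_dom == 0:
            continue
        lab = _bin(n_dom, _FOCUS_BIN_LABELS)
        rows[lab]["n_foci"] += 1
        for letter in "TRP":
            if letter in letters:
                rows[lab][letter] += 1
        hist[_bin(n_dom, _FOCUS_HIST_LABELS)] += 1
        cross[(lab, f.size)] += 1
        max_genes = max(max_genes, f.size)

    by_bin = pd.DataFrame(
        [
            [rows[lab][c] for c in ("T", "R", "P", "n_foci")]
            for lab in _FOCUS_BIN_LABELS
        ],
        index=pd.Index(_FOCUS_BIN_LABELS, name="n_domains"),
        columns=["T", "R", "P", "n_foci"],
    )
    dpf = pd.DataFrame(
        [[hist[lab] for lab in _FOCUS_HIST_LABELS]],
        index=["n_foci"],
        columns=pd.Index(_FOCUS_HIST_LABELS, name="n_domains"),
    )
    gene_cols = list(range(1, max_genes + 1))
    data = []
    for lab in _FOCUS_BIN_LABELS:
        row = [cross[(lab, g)] for g in gene_cols]
        row.append(sum(cross[(lab, g)] * g for g in gene_cols))  # genes total
        data.append(row)
    gbd = pd.DataFrame(
        data,
        index=pd.Index(_FOCUS_BIN_LABELS, name="domains_per_focus"),
        columns=[str(g) for g in gene_cols] + ["total_genes"],
    )
    return FociDomainCensus(by_bin, dpf, gbd)


def geometry_census(foci, combo: str) -> pd.DataFrame:
    """Gene-partition geometries of foci with a given domain combination.

    ``combo`` is an order-free multiset of domain letters (e.g. ``"TRPR"``);
    foci whose pooled domain letters equal the multiset are grouped by their
    5'→3' domain string (``-`` marks gene junctions).  Returns a DataFrame
    with columns ``geometry, count`` sorted by descending count.
    """
    key = combo_key(combo)
    counts = Counter()
    for f in foci:
        if f.domain_string is None:
            raise TCSDataError("geometry_census requires foci with architectures")
        if combo_key("".join(f.architectures)) == key:
            counts[f.domain_string] += 1
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["geometry", "count"],
    )
    df.insert(0, "combo", key)
    return df


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float
    low_expected: bool  # any expected cell < 5


def compare_groups(observed, expected=None, reference=None) -> Chi2Result:
    """Pearson chi-square of observed counts against expected counts.

    ``expected`` gives expected counts directly; alternatively ``reference``
    gives counts (or proportions) from a reference group, rescaled to the
    observed total.  Degrees of freedom are k - 1.  Expected cells below 5
    set a warning flag rather than erroring.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise TCSDataError("chi-square needs at least two categories")
    if obs.sum() <= 0:
        raise TCSDataError("chi-square: observed total is zero")
    if expected is not None:
        exp = np.asarray(expected, dtype=float)
    elif reference is not None:
        ref = np.asarray(reference, dtype=float)
        if ref.sum() <= 0:
            raise TCSDataError("chi-square: reference total is zero")
        exp = ref / ref.sum() * obs.sum()
    else:
        raise TCSDataError("compare_groups needs expected or reference counts")
    if exp.shape != obs.shape:
        raise TCSDataError("observed and expected shapes differ")
    if np.any(exp <= 0):
        raise TCSDataError("chi-square: expected cell <= 0")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return Chi2Result(chi2=chi2, df=df, p=p, low_expected=bool(np.any(exp < 5)))


def correlate_metrics(summaries: pd.DataFrame, metric_x: str, metric_y: str):
    """Squared Pearson correlation between two per-replicon metrics.

    Returns ``(r_squared, sign)``; NaN/0 when fewer than 3 complete pairs or
    a metric has zero variance.
    """
    df = summaries[[metric_x, metric_y]].dropna()
    if len(df) < 3:
        raise TCSDataError("correlate_metrics needs >= 3 replicons with both metrics")
    x, y = df[metric_x].to_numpy(float), df[metric_y].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), 0
    r = float(stats.pearsonr(x, y).statistic)
    return r * r, int(np.sign(r))


def summarize_replicons(genes, foci, categories, architectures, soph_basis="genes"):
    """One summary row per replicon: counts, Dissemination, Sophistication,
    diversity measures and per-focus/gene averages.

    ``genes`` are classified GeneRecords (excluded genes already removed);
    ``foci`` the matching partition; ``categories``/``architectures`` the
    per-gene maps used to build it.  Replicons with zero TCS genes simply do
    not appear.
    """
    by_rep = {}
    for f in foci:
        by_rep.setdefault(f.replicon_id, []).append(f)
    rep_type = {g.replicon_id: g.replicon_type for g in genes}
    rows = []
    for rep_id in sorted(by_rep):
        rep_foci = by_rep[rep_id]
        tags = [t for f in rep_foci for t in f.members]
        cats = [categories[t] for t in tags]
        sizes = [f.size for f in rep_foci]
        n_genes = len(tags)
        comp = complexity_suite(rep_foci, basis=soph_basis)
        n_dom = sum(
            len(getattr(architectures[t], "string", architectures[t])) for t in tags
        )
        rows.append(
            {
                "replicon_id": rep_id,
                "replicon_type": rep_type.get(rep_id, "chromosome"),
                "n_genes": n_genes,
                "n_HK": sum(c in ("HK", "hybrid_HK") for c in cats),
                "n_RR": sum(c == "RR" for c in cats),
                "n_PP": sum(c == "PP" for c in cats),
                "n_hybrid": sum(c == "hybrid_HK" for c in cats),
                "n_foci": len(rep_foci),
                "n_orphans": sum(s == 1 for s in sizes),
                "n_paired_genes": sum(s for s in sizes if s == 2),
                "n_triad_genes": sum(s for s in sizes if s == 3),
                "n_tetrad_genes": sum(s for s in sizes if s == 4),
                "dissemination": dissemination(rep_foci),
                "sophistication": sophistication(rep_foci, basis=soph_basis),
                "diversity": comp["diversity"],
                "diversity_gt2": comp["diversity_gt2"],
                "n_gt2": comp["n_gt2"],
                "pct_gt2": comp["pct_gt2"],
                "avg_genes_per_focus": n_genes / len(rep_foci),
                "avg_domains_per_gene": n_dom / n_genes if n_genes else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def domain_census_tables(ds) -> dict:
    """All nine dataset-level census tables for a classified dataset.

    Keys ``table1`` … ``table9``: focus-size distribution; gene type by
    focus size; genes / foci with each domain class by total-domain bin;
    domains-per-protein and per-focus histograms; the T×R cross-table; the
    phosphotransfer cross-classification; and genes-per-focus by
    domains-per-focus.
    """
    from .architecture import domain_census

    archs = [ds.architectures[t] for f in ds.foci for t in f.members]
    dc = domain_census(archs)
    fc = foci_domain_census(ds.foci)
    return {
        "table1": focus_size_census(ds.foci),
        "table2": gene_type_by_focus_size(ds.foci),
        "table3": dc.by_domain_bin,
        "table4": fc.by_domain_bin,
        "table5": dc.domains_per_protein,
        "table6": dc.t_by_r,
        "table7": dc.p_cross,
        "table8": fc.domains_per_focus,
        "table9": fc.genes_by_domains,
    }


def dataset_summary(genes, foci) -> dict:
    """Genome-level headline numbers: gene totals and plasmid share."""
    n_genes = len(genes)
    n_plasmid = sum(g.replicon_type == "plasmid" for g in genes)
    census = focus_size_census(foci)
    return {
        "n_genes": n_genes,
        "n_foci": len(foci),
        "pct_plasmid_tcs": 100.0 * n_plasmid / n_genes if n_genes else float("nan"),
        "dissemination": dissemination(foci),
        "sophistication": sophistication(foci),
        "focus_size_census": census,
    }
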