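"""Readers and writers for gene tables, domain-hit tables and result tables.

Gene coordinate tables are TSV with columns
``replicon_id, replicon_type, topology, locus_tag, start, stop, strand, flags``
(``flags`` semicolon-separated, may be empty); GFF3 is accepted as an
alternative coordinate source.  Domain-hit tables are TSV with columns
``locus_tag, domain_name, aa_start, aa_end`` and are classed through a
domain-name → class map (class one of ``h``/``P``/``R``, or ``ignore`` to
drop a known non-signalling domain).

All writers emit a deterministic column order so write→read→write
round-trips byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from pathlib import Path

import pandas as pd

from .errors import DatasetError, RowError, SchemaError
from .records import DomainHit, Focus, GeneRecord

GENE_COLUMNS = [
    "replicon_id",
    "replicon_type",
    "topology",
    "locus_tag",
    "start",
    "stop",
    "strand",
    "flags",
]
DOMAIN_COLUMNS = ["locus_tag", "domain_name", "aa_start", "aa_end"]
FOCUS_COLUMNS = [
    "focus_id",
    "replicon_id",
    "size",
    "strand",
    "gene_string",
    "domain_string",
    "n_domains",
    "members",
]

#: Minimal built-in domain-name → class map.  The full catalogue of
#: phosphotransfer signalling domains is curation-dependent; users extend or
#: replace this via a class-map TSV (columns: domain_name, class).
DEFAULT_CLASS_MAP = {
    "HisKA": "P",
    "HisKA_2": "P",
    "HisKA_3": "P",
    "Hpt": "P",
    "HATPase_c": "h",
    "Response_reg": "R",
}


def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _parse_flags(raw: str) -> frozenset:
    raw = (raw or "").strip()
    if not raw:
        return frozenset()
    return frozenset(p for p in raw.split(";") if p)


def read_gene_table(path, fmt: str = None) -> list:
    """Read a gene coordinate table (TSV or GFF3) into sorted GeneRecords.

    Records come back sorted by (replicon_id, start, end, locus_tag).  Rows
    flagged ``mispredicted`` are retained but marked; exclusion happens in the
    classification step.  Format is inferred from the suffix when ``fmt`` is
    None (``.gff``/``.gff3`` → GFF3, else TSV).
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "tsv"
    if fmt == "gff3":
        records = _read_gff3(path)
    elif fmt == "tsv":
        records = _read_gene_tsv(path)
    else:
        raise SchemaError(f"unknown gene-table format {fmt!r}")

    tags = [g.locus_tag for g in records]
    dupes = sorted(t for t, n in Counter(tags).items() if n > 1)
    if dupes:
        raise DatasetError(f"duplicate locus_tag(s): {dupes}")
    records.sort(key=lambda g: (g.replicon_id,) + g.sort_key)
    return records


def _read_gene_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, GENE_COLUMNS[:-1], f"gene table {path}")  # flags optional
    records = []
    for row in df.itertuples(index=False):
        try:
            start, stop = int(row.start), int(row.stop)
        except ValueError as exc:
            raise RowError(f"{row.locus_tag}: non-integer coordinate") from exc
        records.append(
            GeneRecord(
                locus_tag=row.locus_tag,
                replicon_id=row.replicon_id,
                start=start,
                end=stop,
                strand=row.strand,
                replicon_type=row.replicon_type,
                topology=row.topology,
                flags=_parse_flags(getattr(row, "flags", "")),
            )
        )
    return records


def _read_gff3(path) -> list:
    """Coordinates from GFF3 CDS/gene features (locus_tag attr, else ID)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    records = []
    for ftype in ("CDS", "gene"):
        for feat in db.features_of_type(ftype):
            tag = feat.attributes.get("locus_tag", feat.attributes.get("ID", [None]))[0]
            if tag is None:
                raise RowError(
                    f"GFF3 feature at {feat.seqid}:{feat.start} has no locus_tag/ID"
                )
            records.append(
                GeneRecord(
                    locus_tag=tag,
                    replicon_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                )
            )
        if records:
            break
    return records


def write_gene_table(records, path):
    df = pd.DataFrame(
        {
            "replicon_id": [g.replicon_id for g in records],
            "replicon_type": [g.replicon_type for g in records],
            "topology": [g.topology for g in records],
            "locus_tag": [g.locus_tag for g in records],
            "start": [g.start for g in records],
            "stop": [g.end for g in records],
            "strand": [g.strand for g in records],
            "flags": [";".join(sorted(g.flags)) for g in records],
        },
        columns=GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_class_map(path) -> dict:
    """Read a domain-name → class TSV (columns: domain_name, class)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["domain_name", "class"], f"class map {path}")
    mapping = {}
    for name, cls in zip(df["domain_name"], df["class"]):
        if cls not in {"h", "P", "R", "ignore"}:
            raise SchemaError(
                f"class map {path}: {name} has class {cls!r} (expected h/P/R/ignore)"
            )
        mapping[name] = cls
    return mapping


def _resolve_overlaps(hits):
    """Drop overlapping hits within one protein deterministically.

    Keeps the hit with the smaller aa_start; on ties the longer one.  Result
    is non-nesting and sorted by aa_start.
    """
    kept = []
    for hit in sorted(hits, key=lambda h: (h.aa_start, -h.aa_end)):
        if kept and hit.aa_start <= kept[-1].aa_end:
            continue
        kept.append(hit)
    return kept


def read_domain_table(path, class_map: dict = None, strict: bool = True):
    """Read and class a domain-hit table.

    Returns ``(hits, n_dropped)``: hits sorted per protein by aa_start with
    overlaps resolved, and the count of rows dropped because their domain name
    mapped to no signalling class.  With ``strict=True`` a name absent from
    the map is an error; with ``strict=False`` it is dropped and counted.
    """
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, DOMAIN_COLUMNS, f"domain table {path}")

    per_protein = {}
    n_dropped = 0
    order = []
    for row in df.itertuples(index=False):
        name = row.domain_name
        if name not in class_map:
            if strict:
                raise SchemaError(
                    f"domain table {path}: unknown domain name {name!r} "
                    "(pass strict=False to drop, or extend the class map)"
                )
            n_dropped += 1
            continue
        cls = class_map[name]
        if cls == "ignore":
            n_dropped += 1
            continue
        hit = DomainHit(
            locus_tag=row.locus_tag,
            domain_name=name,
            domain_class=cls,
            aa_start=int(row.aa_start),
            aa_end=int(row.aa_end),
        )
        if row.locus_tag not in per_protein:
            order.append(row.locus_tag)
        per_protein.setdefault(row.locus_tag, []).append(hit)

    hits = []
    for tag in order:
        hits.extend(_resolve_overlaps(per_protein[tag]))
    return hits, n_dropped


def write_domain_table(hits, path):
    df = pd.DataFrame(
        {
            "locus_tag": [h.locus_tag for h in hits],
            "domain_name": [h.domain_name for h in hits],
            "aa_start": [h.aa_start for h in hits],
            "aa_end": [h.aa_end for h in hits],
        },
        columns=DOMAIN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_focus_table(foci, path):
    """Write foci as TSV, one row per focus, members comma-separated.

    ``focus_id`` is the locus tag of the 5'-most member; members are listed
    in coordinate order.
    """
    rows = []
    for f in foci:
        rows.append(
            {
                "focus_id": f.focus_id,
                "replicon_id": f.replicon_id,
                "size": f.size,
                "strand": f.strand,
                "gene_string": f.gene_string or "",
                "domain_string": f.domain_string or "",
                "n_domains": "" if f.n_domains is None else f.n_domains,
                "members": ",".join(f.members),
            }
        )
    df = pd.DataFrame(rows, columns=FOCUS_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_focus_table(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, FOCUS_COLUMNS, f"focus table {path}")
    foci = []
    for row in df.itertuples(index=False):
        members = tuple(row.members.split(","))
        arch = None
        if row.domain_string:
            parts = row.domain_string.split("-")
            arch = tuple(reversed(parts)) if row.strand == "-" else tuple(parts)
        cats = None
        if row.gene_string:
            parts = row.gene_string.split(">")
            cats = tuple(reversed(parts)) if row.strand == "-" else tuple(parts)
        foci.append(
            Focus(
                members=members,
                replicon_id=row.replicon_id,
                strand=row.strand,
                categories=cats,
                architectures=arch,
            )
        )
    return foci


def write_metrics_table(df: pd.DataFrame, path):
    """Write a metrics DataFrame as TSV with a stable column order."""
    df.to_csv(path, sep="\t", index=False)


def write_report(report, path):
    """Write a report (dataclass or mapping) as stable, sorted JSON."""
    if dataclasses.is_dataclass(report):
        report = dataclasses.asdict(report)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")
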