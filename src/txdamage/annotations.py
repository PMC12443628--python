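"""Readers and writers for gene annotations, gene sets, counts and sample metadata.

Coordinate conventions
----------------------
Gene coordinates are stored 1-based inclusive internally (the GTF
convention), and gene length is the plain genomic span ``end - start``
— the same quantity BioMart returns as ``gene_end - gene_start``, exons
and introns included.  BED input (0-based, half-open) is shifted on
read so the subtraction yields the same span length for the same
genomic interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = ["gene_id", "symbol", "chromosome", "start", "end", "length", "cfs_label"]

#: Medication regimen class meaning "not taking any medication"; blank
#: medication fields map here.
NO_MEDICATION_CLASS = 7


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (e.g. one GMT file).

    ``sets`` maps set name to the gene list; genes may repeat across
    sets but not within one.
    """

    name: str
    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {set_name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {set_name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with *universe*, dropping sets that become empty."""
        kept = {}
        for name, genes in self.sets.items():
            inter = [g for g in genes if g in universe]
            if inter:
                kept[name] = inter
        return GeneSetCollection(name=self.name, sets=kept)


# ---------------------------------------------------------------------------
# gene annotation

def derive_gene_length(raw: pd.DataFrame, *, zero_based_half_open: bool = False) -> pd.DataFrame:
    """Derive the genomic-span gene length from raw coordinate rows.

    Parameters
    ----------
    raw
        Table with at least ``gene_id``, ``chromosome``, ``start``, ``end``.
    zero_based_half_open
        If True the coordinates follow the BED convention and are
        converted to 1-based inclusive before the subtraction, so the
        stored length equals the GTF-encoded length of the same span.

    Rows with ``end <= start`` (after conversion) are rejected with a
    logged warning rather than raising.  Genes with several records keep
    the record with the widest span.
    """
    df = raw.copy()
    df["start"] = pd.to_numeric(df["start"], errors="raise").astype(np.int64)
    df["end"] = pd.to_numeric(df["end"], errors="raise").astype(np.int64)
    if zero_based_half_open:
        # BED chromStart is 0-based: GTF start = chromStart + 1; chromEnd
        # is already the 1-based inclusive end.
        df["start"] = df["start"] + 1
    df["length"] = df["end"] - df["start"]
    bad = df["length"] <= 0
    if bad.any():
        logger.warning("rejected %d annotation record(s) with end <= start", int(bad.sum()))
        df = df.loc[~bad]
    # duplicate gene ids: keep the widest span (gene-level behaviour)
    n_dup = df["gene_id"].duplicated().sum()
    if n_dup:
        logger.info("collapsing %d duplicate annotation record(s) to widest span", int(n_dup))
        df = df.sort_values("length", ascending=False).drop_duplicates("gene_id", keep="first")
    for col in ("symbol", "cfs_label"):
        if col not in df.columns:
            df[col] = pd.NA
    df = df[GENE_TABLE_COLUMNS].reset_index(drop=True)
    return df


def read_gtf(path: str | Path, *, feature: str = "gene") -> pd.DataFrame:
    """Read gene records from a GTF/GFF file into an annotation table.

    Only rows whose feature column equals *feature* are used; gene_id
    and (if present) gene_name are pulled from the attribute column.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"ragged GTF row ({len(parts)} fields): {line[:80]!r}")
            chrom, _source, feat, start, end, _score, _strand, _frame, attrs = parts[:9]
            if feat != feature:
                continue
            gene_id = _gtf_attr(attrs, "gene_id") or _gtf_attr(attrs, "ID")
            if gene_id is None:
                raise ValueError(f"GTF row lacks gene_id attribute: {line[:80]!r}")
            symbol = _gtf_attr(attrs, "gene_name") or _gtf_attr(attrs, "Name")
            rows.append(
                {"gene_id": gene_id, "symbol": symbol, "chromosome": chrom,
                 "start": int(start), "end": int(end)}
            )
    return derive_gene_length(pd.DataFrame(rows))


def _gtf_attr(attrs: str, key: str) -> str | None:
    for chunk in attrs.replace(";", " ; ").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk and " " not in chunk.split("=")[0]:
            k, _, v = chunk.partition("=")
        else:
            k, _, v = chunk.partition(" ")
        if k.strip() == key:
            return v.strip().strip('"')
    return None


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 annotation (0-based half-open) into the internal table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"ragged BED row: {line[:80]!r}")
            rows.append(
                {"gene_id": parts[3], "chromosome": parts[0],
                 "start": int(parts[1]), "end": int(parts[2])}
            )
    return derive_gene_length(pd.DataFrame(rows), zero_based_half_open=True)


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write the annotation as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.start - 1}\t{row.end}\t{row.gene_id}\t0\t+\n"
            )


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited gene table (gene_id, chromosome, start, end, ...)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = {"gene_id", "chromosome", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return derive_gene_length(df)


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    genes[GENE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets and fragile-site membership

def read_gmt(path: str | Path, *, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: ``set_name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line needs >= 3 fields: {line[:80]!r}")
            set_name, _desc, *genes = parts
            genes = [g for g in genes if g]
            # deduplicate within a set, order-preserving
            sets[set_name] = list(dict.fromkeys(genes))
    return GeneSetCollection(name=name or Path(path).stem, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_name, genes in collection.sets.items():
            fh.write("\t".join([set_name, "na", *genes]) + "\n")


def read_cfs_table(path: str | Path) -> dict[str, str]:
    """Read a tab-delimited fragile-site membership table (HumCFS-style).

    Expects columns for the gene identifier and the fragile-site label
    (``gene``/``gene_symbol`` and ``fragile_site``/``cfs``), or a
    headerless two-plus-column file in that order.  A gene annotated in
    multiple fragile sites keeps the first label (membership counts
    once downstream).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    gene_col = next((cols[k] for k in ("gene", "gene_symbol", "gene_id", "symbol") if k in cols), None)
    site_col = next((cols[k] for k in ("fragile_site", "cfs", "site", "cfs_label") if k in cols), None)
    if gene_col is None or site_col is None:
        # headerless: first row was data
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
        if df.shape[1] < 2:
            raise ValueError("CFS table needs >= 2 columns (gene, fragile_site)")
        gene_col, site_col = df.columns[0], df.columns[1]
    mapping: dict[str, str] = {}
    for gene, site in zip(df[gene_col], df[site_col]):
        if pd.isna(gene) or pd.isna(site):
            continue
        mapping.setdefault(str(gene), str(site))
    return mapping


def write_cfs_table(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_symbol\tfragile_site\n")
        for gene, site in mapping.items():
            fh.write(f"{gene}\t{site}\n")


# ---------------------------------------------------------------------------
# counts and metadata

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count matrix.

    Accepts either a tab-delimited table (first column gene IDs, header
    row sample IDs) or an MTX triplet: ``x.mtx`` with sidecar
    ``x.genes.txt`` and ``x.samples.txt`` name files.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(path).toarray()
        genes = Path(str(path)[: -len(".mtx")] + ".genes.txt").read_text().split()
        samples = Path(str(path)[: -len(".mtx")] + ".samples.txt").read_text().split()
        counts = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene IDs in counts: {dups[:10]}")
    if (counts.values < 0).any():
        raise ValueError("counts contain negative values")
    counts.index.name = "gene_id"
    return counts.astype(np.int64, errors="ignore")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write counts as TSV, or as an MTX triplet if *path* ends in .mtx."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(counts.values))
        stem = str(path)[: -len(".mtx")]
        Path(stem + ".genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
        Path(stem + ".samples.txt").write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        counts.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata CSV and normalize the medication field.

    Blank ``medication_class`` entries mean "not taking any medication"
    and map to class 7; visits must be 1 or 8.
    """
    meta = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    required = {"sample_id", "subject_id", "group", "visit"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicated sample IDs in metadata")
    meta["visit"] = meta["visit"].astype(int)
    bad_visits = set(meta["visit"]) - {1, 8}
    if bad_visits:
        raise ValueError(f"visit values outside {{1, 8}}: {sorted(bad_visits)}")
    if "medication_class" not in meta.columns:
        meta["medication_class"] = NO_MEDICATION_CLASS
    meta["medication_class"] = (
        meta["medication_class"].fillna(NO_MEDICATION_CLASS).astype(int)
    )
    if not meta["medication_class"].between(1, 7).all():
        raise ValueError("medication_class outside 1..7")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def validate_cohort(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Check that every counts column has a metadata record."""
    missing = [s for s in counts.columns if s not in set(meta["sample_id"])]
    if missing:
        raise ValueError(f"samples in counts missing from metadata: {missing}")
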