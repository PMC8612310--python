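"""Readers and writers for the external file formats and internal result tables.

All tabular data is carried as :class:`pandas.DataFrame` objects with fixed
column schemas (the ``*_COLUMNS`` constants below).  Conventions enforced
here, and relied on everywhere else in the package:

* genomic coordinates are **1-based inclusive**, so a CDS spanning
  ``start..end`` has length ``end - start + 1`` bp;
* TSV files are tab-separated with ``.`` as the decimal mark; lines starting
  with ``#`` are comments;
* alignment hit tables are BLAST/DIAMOND ``outfmt 6`` (12 columns) with two
  appended taxonomy columns (domain, free-form label);
* every table written by :func:`write_long_table` is canonically sorted so
  that runs are byte-comparable.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line


class FormatError(ValueError):
    """A file did not conform to the expected dialect."""


GENE_CALL_COLUMNS = [
    "gene_id",
    "contig_id",
    "site_id",
    "start",
    "end",
    "strand",
    "length_bp",
]

COVERAGE_COLUMNS = ["site_id", "gene_id", "mapped_reads"]

HIT_COLUMNS = [
    "query_gene_id",
    "subject_id",
    "percent_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
    "taxon_domain",
    "taxon_label",
]

ANNOTATION_COLUMNS = ["site_id", "gene_id", "family_id", "category"]

BIN_COLUMNS = ["bin_id", "contig_id", "site_id", "completeness_pct", "redundancy_pct"]

SITE_TOTAL_COLUMNS = ["site_id", "total_reads", "total_genes"]

# preferred sort precedence for canonical output ordering
_SORT_PRECEDENCE = [
    "site_id",
    "bin_id",
    "pathway_id",
    "family_id",
    "contig_id",
    "gene_id",
    "query_gene_id",
]


# ---------------------------------------------------------------------------
# GFF3 gene calls
# ---------------------------------------------------------------------------

def read_gene_calls(path: str | Path, site_id: str) -> pd.DataFrame:
    """Read CDS features from a Prodigal-style GFF3 file.

    Parameters
    ----------
    path
        GFF3 file whose CDS features carry an ``ID`` attribute.
    site_id
        Site label attached to every returned gene call.

    Returns
    -------
    DataFrame with :data:`GENE_CALL_COLUMNS`; one row per CDS, coordinates
    1-based inclusive, ``length_bp = end - start + 1``.

    Raises
    ------
    FormatError
        On a malformed line (the message names the line number), a CDS
        without an ``ID``, or a duplicated ``ID`` within the file.
    """
    rows: list[tuple] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                break  # trailing FASTA section, as emitted by some callers
            if line.count("\t") != 8:
                raise FormatError(
                    f"{path}: malformed GFF3 line {lineno}: expected 9 "
                    f"tab-separated columns, got {line.count(chr(9)) + 1}"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(
                    f"{path}: malformed GFF3 line {lineno}: {exc}"
                ) from exc
            if feat.featuretype != "CDS":
                continue
            ids = feat.attributes.get("ID")
            if not ids:
                raise FormatError(
                    f"{path}: CDS on line {lineno} has no ID attribute"
                )
            gene_id = ids[0]
            if gene_id in seen:
                raise FormatError(
                    f"{path}: duplicate CDS ID {gene_id!r} on line {lineno}"
                )
            seen.add(gene_id)
            start, end = int(feat.start), int(feat.end)
            if start < 1 or end < start:
                raise FormatError(
                    f"{path}: invalid coordinates {start}..{end} on line {lineno}"
                )
            rows.append(
                (gene_id, feat.seqid, site_id, start, end, feat.strand,
                 end - start + 1)
            )
    return pd.DataFrame(rows, columns=GENE_CALL_COLUMNS)


def write_gene_calls_gff(gene_calls: pd.DataFrame, path: str | Path) -> None:
    """Write gene calls as a minimal Prodigal-dialect GFF3 (CDS features)."""
    df = gene_calls.sort_values(["contig_id", "start", "gene_id"])
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.contig_id}\tsedimeta\tCDS\t{row.start}\t{row.end}\t."
                f"\t{row.strand}\t0\tID={row.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# tabular hits
# ---------------------------------------------------------------------------

_HIT_NUMERIC = {
    "percent_identity": float,
    "aln_length": int,
    "mismatches": int,
    "gap_opens": int,
    "q_start": int,
    "q_end": int,
    "s_start": int,
    "s_end": int,
    "e_value": float,
    "bit_score": float,
}


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a DIAMOND/BLAST outfmt-6 table with two appended taxonomy columns.

    Rows may carry 14 fields (full) or the bare 12 alignment fields, in which
    case the taxonomy columns are set to ``"NA"``.  Any other field count is
    an error naming the offending row.
    """
    rows: list[list] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, fields in enumerate(reader, start=1):
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) == 12:
                fields = fields + ["NA", "NA"]
            elif len(fields) != 14:
                raise FormatError(
                    f"{path}: row {lineno} has {len(fields)} columns, "
                    "expected 12 or 14"
                )
            if fields[12] == "":
                fields[12] = "NA"
            if fields[13] == "":
                fields[13] = "NA"
            rows.append(fields)
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    for col, typ in _HIT_NUMERIC.items():
        df[col] = df[col].astype(typ)
    if not df.empty:
        pid = df["percent_identity"]
        if (pid < 0).any() or (pid > 100).any():
            raise FormatError(f"{path}: percent_identity outside [0, 100]")
        if (df["e_value"] < 0).any():
            raise FormatError(f"{path}: negative e-value")
    return df


# ---------------------------------------------------------------------------
# simple TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, columns: list[str],
              dtypes: Mapping[str, type]) -> pd.DataFrame:
    rows: list[list] = []
    header_skipped = False
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, fields in enumerate(reader, start=1):
            if not fields or fields[0].startswith("#"):
                continue
            if not header_skipped and fields == columns:
                header_skipped = True
                continue
            header_skipped = True
            if len(fields) != len(columns):
                raise FormatError(
                    f"{path}: row {lineno} has {len(fields)} columns, "
                    f"expected {len(columns)}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=columns)
    for col, typ in dtypes.items():
        df[col] = df[col].astype(typ)
    return df


def read_coverage(path: str | Path) -> pd.DataFrame:
    """Read per-gene mapped-read counts; fractional counts are valid."""
    df = _read_tsv(path, COVERAGE_COLUMNS, {"mapped_reads": float})
    if not df.empty and (df["mapped_reads"] < 0).any():
        raise FormatError(f"{path}: negative mapped_reads")
    if df.duplicated(["site_id", "gene_id"]).any():
        raise FormatError(f"{path}: duplicate (site_id, gene_id) rows")
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ANNOTATION_COLUMNS, {})
    if not df.empty and (df["family_id"] == "").any():
        raise FormatError(f"{path}: empty family_id")
    return df


def read_bin_membership(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(
        path, BIN_COLUMNS, {"completeness_pct": float, "redundancy_pct": float}
    )
    if not df.empty:
        c = df["completeness_pct"]
        if (c < 0).any() or (c > 100).any():
            raise FormatError(f"{path}: completeness_pct outside [0, 100]")
        if (df["redundancy_pct"] < 0).any():
            raise FormatError(f"{path}: negative redundancy_pct")
        if df.duplicated("contig_id").any():
            raise FormatError(f"{path}: a contig belongs to more than one bin")
    return df


def read_site_totals(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(
        path, SITE_TOTAL_COLUMNS, {"total_reads": float, "total_genes": float}
    )
    if not df.empty and ((df["total_reads"] <= 0) | (df["total_genes"] <= 0)).any():
        raise FormatError(f"{path}: site totals must be positive")
    if df.duplicated("site_id").any():
        raise FormatError(f"{path}: duplicate site_id")
    return df


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_contigs(path: str | Path) -> dict[str, str]:
    """Read contig sequences; returns ``{contig_id: uppercase sequence}``."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_contigs(seqs: Mapping[str, str], path: str | Path) -> None:
    """Write contigs as single-line FASTA in sorted ID order."""
    with open(path, "w") as fh:
        for cid in sorted(seqs):
            fh.write(f">{cid}\n{seqs[cid]}\n")


def contig_lengths(path_or_seqs) -> pd.Series:
    """Per-contig length in bp from a FASTA path or a ``{id: seq}`` mapping."""
    if isinstance(path_or_seqs, (str, Path)):
        path_or_seqs = read_contigs(path_or_seqs)
    s = pd.Series({k: len(v) for k, v in path_or_seqs.items()}, dtype=int)
    s.index.name = "contig_id"
    return s


# ---------------------------------------------------------------------------
# canonical long-format output
# ---------------------------------------------------------------------------

def canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Sort rows by the canonical key columns present in ``df``."""
    keys = [c for c in _SORT_PRECEDENCE if c in df.columns]
    if not keys:
        keys = list(df.columns)
    return df.sort_values(keys, kind="mergesort").reset_index(drop=True)


def write_long_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as canonical TSV (sorted, lossless round-trip)."""
    out = canonicalize(df)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_long_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_long_table`."""
    return pd.read_csv(path, sep="\t")
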