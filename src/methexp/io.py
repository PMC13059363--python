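"""Readers and writers for every external table the pipeline touches.

All genomic intervals are held internally as 0-based half-open ``[start, end)``;
1-based closed coordinates appear only at the GFF3 and CX-report boundaries.
Parsers validate strictly and raise rather than coerce malformed records.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXTS",
    "ParseError",
    "ValidationError",
    "subgenome_of",
    "read_cx_report",
    "write_cx_report",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_term_map",
    "write_term_map",
    "translate_gene_ids",
]

#: The three cytosine sequence contexts: symmetric CG and CHG, asymmetric CHH
#: (H = A, T or C).
CONTEXTS = ("CG", "CHG", "CHH")

_SUBGENOME_A = re.compile(r"^A\d+", re.IGNORECASE)
_SUBGENOME_C = re.compile(r"^C\d+", re.IGNORECASE)


class ParseError(ValueError):
    """A file does not conform to its expected column layout."""


class ValidationError(ValueError):
    """A record parses but violates a field-level invariant."""


def subgenome_of(chrom: str) -> str:
    """Assign an allopolyploid subgenome from the chromosome name.

    ``A##``-style names map to the A subgenome, ``C##`` to C; anything else
    (scaffolds, organellar contigs) is ``other``.
    """
    if _SUBGENOME_A.match(chrom):
        return "A"
    if _SUBGENOME_C.match(chrom):
        return "C"
    return "other"


# ---------------------------------------------------------------------------
# Bismark CX report
# ---------------------------------------------------------------------------

_CX_COLUMNS = ["chrom", "pos", "strand", "count_meth", "count_unmeth", "context", "trinucleotide"]


def read_cx_report(path) -> pd.DataFrame:
    """Read a Bismark-style per-cytosine CX report (7-column TSV).

    Returns a frame with columns ``chrom, pos, strand, context, n_meth,
    n_total, trinucleotide`` where ``pos`` is 1-based and
    ``n_total = count_meth + count_unmeth``. Cytosines with ``n_total == 0``
    are retained (they carry positional information for binning) and are
    excluded later by coverage filters.

    Raises
    ------
    ParseError
        wrong column count, with the offending line number.
    ValidationError
        negative counts, unknown context or strand, non-positive position.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=_CX_COLUMNS, dtype={"chrom": str},
            comment=None,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(
            {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
             "strand": pd.Series(dtype=str), "context": pd.Series(dtype=str),
             "n_meth": pd.Series(dtype=np.int64), "n_total": pd.Series(dtype=np.int64),
             "trinucleotide": pd.Series(dtype=str)}
        )
    except pd.errors.ParserError:
        _raise_cx_line_error(path)
        raise  # unreachable
    # pandas pads short rows with NaN instead of erroring; detect those too.
    if df.isna().any().any():
        _raise_cx_line_error(path)

    for col in ("pos", "count_meth", "count_unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(vals.index[vals.isna()][0]) + 1
            raise ValidationError(f"{path}: non-numeric {col!r} at line {bad}")
        df[col] = vals.astype(np.int64)
    if (df[["count_meth", "count_unmeth"]] < 0).any().any():
        raise ValidationError(f"{path}: negative read counts")
    if (df["pos"] < 1).any():
        raise ValidationError(f"{path}: positions must be 1-based (>= 1)")
    bad_context = ~df["context"].isin(CONTEXTS)
    if bad_context.any():
        offender = df.loc[bad_context, "context"].iloc[0]
        raise ValidationError(f"{path}: unknown context {offender!r}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValidationError(f"{path}: strand must be '+' or '-'")

    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "strand": df["strand"],
            "context": df["context"],
            "n_meth": df["count_meth"],
            "n_total": df["count_meth"] + df["count_unmeth"],
            "trinucleotide": df["trinucleotide"],
        }
    )
    return out


def _raise_cx_line_error(path: Path):
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.strip() and len(line.rstrip("\n").split("\t")) != 7:
                raise ParseError(f"{path}: expected 7 tab-separated columns at line {i}")
    raise ParseError(f"{path}: malformed CX report")


def write_cx_report(records: pd.DataFrame, path) -> None:
    """Write records (as returned by :func:`read_cx_report`) as a CX report."""
    out = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "pos": records["pos"],
            "strand": records["strand"],
            "count_meth": records["n_meth"],
            "count_unmeth": records["n_total"] - records["n_meth"],
            "context": records["context"],
            "trinucleotide": records.get(
                "trinucleotide", pd.Series(["CNN"] * len(records), index=records.index)
            ),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Gene annotation (GFF3 / BED6)
# ---------------------------------------------------------------------------

def read_gene_annotation(path, format: str = "GFF3") -> pd.DataFrame:
    """Read gene models from GFF3 (``gene`` rows) or 6-column BED.

    GFF3 1-based closed coordinates are converted to internal 0-based
    half-open ``(start-1, end)``; BED intervals pass through unchanged.
    The returned frame has columns ``gene_id, chrom, start, end, strand,
    subgenome`` and requires an explicit strand on every record.
    """
    fmt = format.upper()
    if fmt == "GFF3":
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9:
                    raise ParseError(f"{path}: expected 9 GFF3 columns at line {i}")
                chrom, _, ftype, start, end, _, strand, _, attrs = parts
                if ftype != "gene":
                    continue
                if strand not in ("+", "-"):
                    raise ValidationError(f"{path}: missing strand at line {i}")
                m = re.search(r"ID=([^;]+)", attrs)
                if not m:
                    raise ParseError(f"{path}: gene without ID attribute at line {i}")
                s, e = int(start) - 1, int(end)
                if e <= s:
                    raise ValidationError(f"{path}: empty interval after conversion at line {i}")
                rows.append((m.group(1), chrom, s, e, strand))
    elif fmt == "BED":
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 6:
                    raise ParseError(f"{path}: expected 6 BED columns at line {i}")
                chrom, start, end, name, _, strand = parts[:6]
                if strand not in ("+", "-"):
                    raise ValidationError(f"{path}: missing strand at line {i}")
                s, e = int(start), int(end)
                if e <= s:
                    raise ValidationError(f"{path}: empty interval at line {i}")
                rows.append((name, chrom, s, e, strand))
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    df["subgenome"] = df["chrom"].map(subgenome_of)
    return df


def write_gene_annotation(genes: pd.DataFrame, path, format: str = "GFF3") -> None:
    """Write gene models; inverse of :func:`read_gene_annotation`."""
    fmt = format.upper()
    if fmt == "GFF3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in genes.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\tmethexp\tgene\t{row.start + 1}\t{row.end}\t.\t"
                    f"{row.strand}\t.\tID={row.gene_id}\n"
                )
    elif fmt == "BED":
        with open(path, "w") as fh:
            for row in genes.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t.\t{row.strand}\n")
    else:
        raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

def read_count_matrix(path) -> pd.DataFrame:
    """Read a gene x sample TSV of non-negative integer counts.

    First column is ``gene_id``; the header row carries sample ids whose
    order is preserved. Duplicate gene ids, ragged rows and non-integer
    cells all raise.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged rows ({exc})") from exc
    if df.isna().any().any():
        raise ParseError(f"{path}: ragged or missing cells")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene_id {dup!r}")
    for col in df.columns:
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            as_int = df[col].astype(np.int64, errors="ignore")
            if not np.array_equal(as_int.to_numpy(), vals):
                raise ValidationError(f"{path}: non-integer counts in column {col!r}")
            df[col] = as_int
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative counts")
    df.index.name = "gene_id"
    return df


def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Sample sheet, term map, id mapping
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ["sample_id", "genotype_id", "group", "treatment", "replicate"]


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet (sample_id, genotype_id, group, treatment, replicate).

    Enforces: unique (genotype, treatment, replicate), each genotype in exactly
    one phenotype group, groups in {tolerant, sensitive}, treatments in
    {control, drought}.
    """
    df = pd.read_csv(path, sep="\t", dtype={"replicate": np.int64})
    missing = set(_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df = df[_SHEET_COLUMNS]
    if not df["group"].isin(["tolerant", "sensitive"]).all():
        raise ValidationError(f"{path}: group must be tolerant/sensitive")
    if not df["treatment"].isin(["control", "drought"]).all():
        raise ValidationError(f"{path}: treatment must be control/drought")
    if df.duplicated(["genotype_id", "treatment", "replicate"]).any():
        raise ValidationError(f"{path}: duplicate (genotype, treatment, replicate)")
    ngroups = df.groupby("genotype_id")["group"].nunique()
    if (ngroups > 1).any():
        raise ValidationError(f"{path}: a genotype appears in more than one group")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[_SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_term_map(path) -> pd.DataFrame:
    """Read a gene->term map (gene_id, term_id, term_name)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "term_id", "term_name"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df[["gene_id", "term_id", "term_name"]]


def write_term_map(term_map: pd.DataFrame, path) -> None:
    term_map[["gene_id", "term_id", "term_name"]].to_csv(path, sep="\t", index=False)


def translate_gene_ids(mapping, ids) -> tuple[list[str], list[str]]:
    """Translate gene ids through a two-column source->target homolog table.

    ``mapping`` is a path to a two-column TSV (header ``source\\ttarget``) or
    an equivalent DataFrame. One-to-many mappings expand in source order;
    unmapped ids are returned separately and never silently dropped.

    Returns ``(mapped_ids, unmapped_ids)``.
    """
    if not isinstance(mapping, pd.DataFrame):
        mapping = pd.read_csv(mapping, sep="\t")
    if mapping.empty:
        raise ValidationError("empty gene-id mapping table")
    src_col, tgt_col = mapping.columns[:2]
    lookup: dict[str, list[str]] = {}
    for s, t in zip(mapping[src_col], mapping[tgt_col]):
        lookup.setdefault(str(s), []).append(str(t))
    mapped: list[str] = []
    unmapped: list[str] = []
    for gid in ids:
        targets = lookup.get(str(gid))
        if targets is None:
            unmapped.append(str(gid))
        else:
            mapped.extend(targets)
    return mapped, unmapped
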