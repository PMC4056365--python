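"""Readers and writers for the pipeline's text formats.

Tables are tab-separated with a header row; lines starting with '#' are a
provenance header (package version, root seed, JSON-encoded config) that
is sufficient to regenerate the file.  Annotation is BED6 or GFF3 (gene
features); internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__


def write_table(df: pd.DataFrame, path, provenance: dict | None = None,
                index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# promcoupling {__version__}\n")
        for key, val in (provenance or {}).items():
            if isinstance(val, (dict, list)):
                val = json.dumps(val, sort_keys=True)
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, schema: list[str] | None = None) -> pd.DataFrame:
    """Read a provenance-headed TSV; optionally enforce required columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if schema is not None:
        missing = set(schema) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_provenance(path) -> dict:
    """Parse the '# key=value' provenance header of a table."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                try:
                    out[key.strip()] = json.loads(val)
                except json.JSONDecodeError:
                    out[key.strip()] = val
    return out


def write_bed(genes: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write gene records as BED6 (0-based half-open, score 0)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# promcoupling {__version__}\n")
        for key, val in (provenance or {}).items():
            if isinstance(val, (dict, list)):
                val = json.dumps(val, sort_keys=True)
            fh.write(f"# {key}={val}\n")
        for _, row in genes.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                f"{row['gene']}\t0\t{row['strand']}\n"
            )


def _read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 fields")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append((name, chrom, start_i, end_i, strand))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])


def _read_gff3(path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"{path}: gene {feat.id}: bad strand {feat.strand!r}")
        # GFF3 is 1-based closed; internal is 0-based half-open
        rows.append((feat.id, feat.seqid, feat.start - 1, feat.end, feat.strand))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])


def read_annotation(path) -> pd.DataFrame:
    """Gene records from BED6 or GFF3, as (gene, chrom, start, end, strand)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return _read_bed(path)
    if suffix in (".gff", ".gff3"):
        return _read_gff3(path)
    raise ValueError(f"unknown annotation extension {suffix!r} (use .bed/.gff3)")


def read_matrix(path) -> pd.DataFrame:
    """Genes x columns matrix from TSV whose first column is the gene id."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "gene"
    return df
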