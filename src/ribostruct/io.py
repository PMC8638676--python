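"""Readers and writers for the plain-text formats the pipeline exchanges.

Count tables, sample sheets and energy tables are TSV; occupancy and
reactivity tracks are bedGraph in transcript coordinates; footprints travel
as TSV (or BED6 with the length in the name field); annotations as GTF or
BED12 (see :mod:`ribostruct.annotation`).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import UnionGeneModel
from .footprints import FOOTPRINT_COLUMNS


class FormatError(ValueError):
    pass


# -- count tables -----------------------------------------------------------

def write_counts(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample TSV of integer counts; names the offending
    row/column on a non-integer cell."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    for col in df.columns:
        values = df[col]
        numeric = pd.to_numeric(values, errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = values.index[bad][0]
            raise FormatError(
                f"non-integer count at gene {row!r}, sample {col!r}: {values.loc[row]!r}"
            )
    return df.astype(np.int64)


# -- sample sheets and simple tables ---------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "library_type", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    bad = ~df["library_type"].isin(["ribo", "rna"])
    if bad.any():
        raise FormatError(f"library_type must be 'ribo' or 'rna' (row {bad.idxmax()})")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_energy_table(path) -> pd.DataFrame:
    """TSV with gene_id, utr5_energy and optional utr3_energy (kcal/mol)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "utr5_energy" not in df.columns:
        raise FormatError("energy table needs gene_id and utr5_energy columns")
    return df.set_index("gene_id")


def write_energy_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


# -- footprints -------------------------------------------------------------

def write_footprints(footprints: pd.DataFrame, path) -> None:
    footprints[FOOTPRINT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_footprints(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FOOTPRINT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"footprint table missing columns: {sorted(missing)}")
    return df[FOOTPRINT_COLUMNS]


def write_footprints_bed6(footprints: pd.DataFrame, path) -> None:
    """BED6 export; the name field carries the footprint length."""
    with open(path, "w") as fh:
        for row in footprints.itertuples(index=False):
            if row.strand == "+":
                start, end = row.five_prime, row.five_prime + row.length
            else:
                start, end = row.five_prime - row.length + 1, row.five_prime + 1
            fh.write(
                f"{row.reference}\t{start}\t{end}\t{row.length}\t0\t{row.strand}\n"
            )


# -- tracks -----------------------------------------------------------------

def write_bedgraph(values_by_ref: Mapping[str, np.ndarray], path) -> None:
    """Write per-position values as bedGraph (runs of equal value merged)."""
    with open(path, "w") as fh:
        for ref in sorted(values_by_ref):
            vals = np.asarray(values_by_ref[ref])
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vals.size]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{ref}\t{s}\t{e}\t{v:g}\n")


def read_reactivity_tsv(path) -> dict[str, np.ndarray]:
    """TSV with gene_id, position, value -> dense per-gene vectors (NaN gaps)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "position", "value"):
        if col not in df.columns:
            raise FormatError(f"reactivity table missing column {col!r}")
    out: dict[str, np.ndarray] = {}
    for g, sub in df.groupby("gene_id"):
        pos = sub["position"].to_numpy(dtype=int)
        vec = np.full(pos.max() + 1, np.nan)
        vec[pos] = sub["value"].to_numpy(dtype=float)
        out[g] = vec
    return out


def write_reactivity_tsv(reactivity: Mapping[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tposition\tvalue\n")
        for g in sorted(reactivity):
            vec = np.asarray(reactivity[g], dtype=float)
            for i, v in enumerate(vec):
                if np.isfinite(v):
                    fh.write(f"{g}\t{i}\t{v:.6g}\n")


# -- annotation / sequence export ------------------------------------------

def write_gtf(models: Iterable[UnionGeneModel], path) -> None:
    """One transcript per gene; exon and CDS features (GTF 1-based closed)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
            for a, b in m.exon_union:
                fh.write(
                    f"{m.reference}\tribostruct\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            for a, b in m.cds_union:
                fh.write(
                    f"{m.reference}\tribostruct\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (pd.Index,)):
        return o.tolist()
    raise TypeError(f"cannot serialize {type(o)!r}")
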