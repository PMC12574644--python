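"""File-format plumbing: FASTA with key=value metadata, chromatogram CSV, JSON.

FASTA records are read and written through Biopython; design metadata rides
in the description line as space-separated ``key=value`` pairs.  Chromatogram
tables are two-column CSV with a ``time_min,signal`` header (a headerless
whitespace-separated table is also accepted).  All report objects serialize
to JSON via their ``to_dict`` methods.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputFormatError
from .hplc import Chromatogram


def metadata_to_description(meta: dict) -> str:
    return " ".join(f"{k}={v}" for k, v in meta.items())


def description_to_metadata(description: str, record_id: str = "") -> dict:
    meta = {}
    for token in description.split():
        if token == record_id:
            continue
        if "=" in token:
            k, _, v = token.partition("=")
            meta[k] = v
    return meta


def write_fasta(path, records: list[tuple[str, str, dict]]) -> None:
    """Write records given as (id, sequence, metadata) triples, 70-col wrapped."""
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description=metadata_to_description(meta))
        for rid, seq, meta in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(seq_records)


def read_fasta(path) -> list[tuple[str, str, dict]]:
    """Read records back as (id, sequence, metadata) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper(),
                    description_to_metadata(rec.description, rec.id)))
    return out


def write_chromatogram_csv(path, chrom: Chromatogram) -> None:
    pd.DataFrame({"time_min": chrom.time, "signal": chrom.signal}).to_csv(
        path, index=False)


def read_chromatogram_csv(path) -> Chromatogram:
    """Read a two-column trace; accepts the canonical header or none at all.

    Raises :class:`InputFormatError` with a 1-based data row number on a
    malformed value or non-monotone time axis.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise InputFormatError(f"cannot parse {path}: {err}") from err
    if "time_min" in df.columns and "signal" in df.columns:
        df = df[["time_min", "signal"]]
        header_rows = 1
    else:
        try:
            df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
        except Exception as err:
            raise InputFormatError(f"cannot parse {path}: {err}") from err
        if df.shape[1] != 2:
            raise InputFormatError(
                f"{path}: expected two columns (time_min, signal), got {df.shape[1]}")
        df.columns = ["time_min", "signal"]
        header_rows = 0
    t = pd.to_numeric(df["time_min"], errors="coerce").to_numpy()
    y = pd.to_numeric(df["signal"], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(t) | ~np.isfinite(y))
    if bad.size:
        raise InputFormatError("non-numeric or missing value",
                               line=int(bad[0]) + 1 + header_rows)
    non_mono = np.flatnonzero(np.diff(t) <= 0)
    if non_mono.size:
        raise InputFormatError("time not strictly increasing",
                               line=int(non_mono[0]) + 2 + header_rows)
    return Chromatogram(t, y)


def _jsonify(obj):
    if hasattr(obj, "to_dict"):
        return _jsonify(obj.to_dict())
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json_report(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=2)
        fh.write("\n")
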