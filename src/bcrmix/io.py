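"""Readers and writers for the package's tabular formats.

All tables are tab-delimited UTF-8 with a header row and '.' decimals.
Repertoire input comes as a plain TSV (sequence, individual, time, count),
an AIRR-rearrangement-style TSV (junction / junction_aa plus a samples map),
or FASTA with ``id|individual|time|count`` headers.  Output files carry a
comment header with the tool version, seed and effective parameters.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd
from Bio import SeqIO

from . import __version__
from .clones import CloneSet, RepertoireTable
from .tensor import AbundanceTensor

PathLike = Union[str, Path]


def read_repertoire_tsv(path: PathLike, alphabet: str = "") -> RepertoireTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sequence": str})
    missing = {"sequence", "individual", "time", "count"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required columns {sorted(missing)} "
            "(expected sequence, individual, time, count)"
        )
    return RepertoireTable(df, alphabet=alphabet)


def read_airr_tsv(path: PathLike, samples: dict, alphabet: str = "nt") -> RepertoireTable:
    """AIRR rearrangement TSV: junction (nt) or junction_aa (aa) column plus
    a ``samples`` mapping of sample/repertoire ids to (individual, time)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    seq_col = "junction" if alphabet == "nt" else "junction_aa"
    if seq_col not in df.columns:
        raise ValueError(f"{path}: AIRR table lacks the {seq_col!r} column")
    id_col = next((c for c in ("repertoire_id", "sample_id") if c in df.columns), None)
    if id_col is None:
        raise ValueError(f"{path}: AIRR table lacks repertoire_id/sample_id")
    count_col = next(
        (c for c in ("duplicate_count", "consensus_count") if c in df.columns), None)
    records = []
    for row in df.itertuples(index=False):
        sample = getattr(row, id_col)
        if sample not in samples:
            raise ValueError(f"sample {sample!r} missing from the samples config")
        individual, time = samples[sample]
        count = int(getattr(row, count_col)) if count_col else 1
        records.append({"sequence": getattr(row, seq_col), "individual": individual,
                        "time": int(time), "count": count})
    return RepertoireTable(pd.DataFrame(records), alphabet=alphabet)


def read_repertoire_fasta(path: PathLike, alphabet: str = "") -> RepertoireTable:
    """FASTA with ``id|individual|time|count`` headers."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) < 4:
            raise ValueError(
                f"{path}: FASTA header {rec.description!r} is not id|individual|time|count")
        records.append({"sequence": str(rec.seq).upper(), "individual": parts[1],
                        "time": int(parts[2]), "count": int(parts[3])})
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return RepertoireTable(pd.DataFrame(records), alphabet=alphabet)


def read_truth_sequences(path: PathLike) -> list:
    """Truth sequences from FASTA or from a TSV with a ``sequence`` column."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna", ".faa"):
        return [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sequence" not in df.columns:
        raise ValueError(f"{path}: truth TSV needs a 'sequence' column")
    return df["sequence"].astype(str).tolist()


def _header_comment(seed=None, **params) -> str:
    fields = [f"bcrmix v{__version__}"]
    if seed is not None:
        fields.append(f"seed={seed}")
    fields.extend(f"{k}={v}" for k, v in params.items())
    return "# " + " ".join(fields) + "\n"


def write_table(df: pd.DataFrame, path: PathLike, seed=None, **params) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed=seed, **params))
        df.to_csv(fh, sep="\t", index=False)


def write_clones_tsv(clone_set: CloneSet, table: RepertoireTable, path: PathLike,
                     seed=None) -> None:
    lookup = clone_set.member_lookup()
    df = table.records.assign(clone_id=table.records["sequence"].map(lookup))
    centres = {c.clone_id: c.centre for c in clone_set.clones}
    df["centre"] = df["clone_id"].map(centres)
    df = df.rename(columns={"sequence": "member"})[
        ["clone_id", "centre", "member", "individual", "time", "count"]]
    write_table(df, path, seed=seed, threshold=clone_set.similarity_threshold,
                alphabet=clone_set.alphabet)


def write_tensor_tsv(tensor: AbundanceTensor, path: PathLike, seed=None, **params) -> None:
    write_table(tensor.to_frame(), path, seed=seed, **params)


def write_labels_tsv(clone_ids, responsibilities, labels, path: PathLike,
                     centres=None, seed=None, **params) -> None:
    df = pd.DataFrame({
        "clone_id": clone_ids,
        "P_bg": responsibilities[:, 0],
        "P_ns": responsibilities[:, 1],
        "P_vs": responsibilities[:, 2],
        "label": labels,
    })
    if centres is not None:
        df.insert(1, "centre", centres)
    write_table(df, path, seed=seed, **params)


def read_labels_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
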