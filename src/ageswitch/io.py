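"""Plain-text readers and writers for the pipeline's standard files.

Everything is text: FASTA for sequences, TSV for matrices and tables, a
two-line GMT file for query signatures, JSON for truth sidecars and reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidInputError
from .synthetic import CompoundTruth


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_query_gmt(up_genes, down_genes, path, name: str = "age_signature") -> None:
    """Two-line GMT-like file: one row of up-genes, one of down-genes."""
    with open(path, "w") as fh:
        fh.write("\t".join([f"{name}_up", "direction:+1", *sorted(up_genes)]) + "\n")
        fh.write("\t".join([f"{name}_down", "direction:-1", *sorted(down_genes)]) + "\n")


def read_query_gmt(path) -> tuple[set, set]:
    lines = [ln.rstrip("\n").split("\t") for ln in open(path) if ln.strip()]
    if len(lines) != 2:
        raise InvalidInputError("query GMT must hold exactly two lines (up, down)")
    return set(lines[0][2:]), set(lines[1][2:])


def write_library(library, path) -> None:
    """Compound library TSV: compound_id, class_label, compound_class, ranking."""
    rows = [
        {
            "compound_id": c.compound_id,
            "class_label": c.class_label,
            "compound_class": c.compound_class,
            "ranking": ",".join(c.ranking),
        }
        for c in library
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_library(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        CompoundTruth(
            row.compound_id,
            row.class_label,
            row.compound_class,
            tuple(row.ranking.split(",")),
        )
        for row in df.itertuples(index=False)
    ]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
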