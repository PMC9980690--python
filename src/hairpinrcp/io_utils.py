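"""Readers and writers for the pipeline's on-disk formats.

All tables are tab-separated with a header row, UTF-8, '.' decimal.
FASTQ uses 4-line records with Phred+33 qualities (synthetic reads get
a constant quality).  The reference amplicon travels as FASTA plus a
BED of CpG positions (0-based half-open two-base intervals).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SYNTHETIC_QUAL = "I"  # Q40


class FastqFormatError(ValueError):
    pass


def write_fastq(records, path) -> None:
    """Write (read_id, sequence) pairs with constant quality."""
    seqrecords = []
    for read_id, seq in records:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        seqrecords.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fastq")


def read_fastq(path):
    """Yield (read_id, sequence); malformed records raise FastqFormatError
    naming the file and approximate record index."""
    i = 0
    try:
        with open(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                i += 1
                yield rec.id, str(rec.seq)
    except ValueError as e:
        raise FastqFormatError(f"{path}: malformed FASTQ near record {i + 1}: {e}") from e


def write_reference(sequence: str, cpg_positions, fasta_path, bed_path, name="amplicon") -> None:
    with open(fasta_path, "w") as fh:
        SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], fh, "fasta")
    with open(bed_path, "w") as fh:
        for p in cpg_positions:
            fh.write(f"{name}\t{p}\t{p + 2}\n")


def read_reference(fasta_path, bed_path) -> tuple[str, tuple[int, ...]]:
    recs = list(SeqIO.parse(fasta_path, "fasta"))
    if len(recs) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one reference sequence")
    seq = str(recs[0].seq).upper()
    positions = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{bed_path}:{ln}: need at least 3 BED columns")
            positions.append(int(parts[1]))
    for p in positions:
        if seq[p : p + 2] != "CG":
            raise ValueError(f"{bed_path}: position {p} is not a CpG in {fasta_path}")
    return seq, tuple(sorted(positions))


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
    return df


def write_molecule_table(records, path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "umi": r.umi,
            "states": "".join(r.dyad_states),
            "n_control": r.control_c_total,
            "n_unconverted": r.control_c_unconverted,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "umi", "states", "n_control", "n_unconverted"]
    ).to_csv(path, sep="\t", index=False)


def read_molecule_table(path):
    from .hairpin_fold import MoleculeRecord

    df = pd.read_csv(path, sep="\t", dtype={"states": str, "umi": str})
    records = []
    for _, row in df.iterrows():
        records.append(
            MoleculeRecord(
                sample_id=str(row["sample_id"]),
                umi=str(row["umi"]),
                dyad_states=tuple(str(row["states"])),
                control_c_total=int(row.get("n_control", 0)),
                control_c_unconverted=int(row.get("n_unconverted", 0)),
            )
        )
    return records


def write_dyad_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_dyad_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "M", "U", "H"} <= set(df.columns):
        raise ValueError(f"{path}: dyad count table needs sample_id, M, U, H")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
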