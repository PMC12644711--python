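"""File I/O: FASTQ/FASTA via Biopython, tidy TSV tables, YAML locus configs."""

from __future__ import annotations

import gzip
from os import PathLike
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio import SeqIO

from .locus import JunctionReference, LocusSpec, build_junction_reference

__all__ = [
    "write_fastq",
    "read_fastq",
    "junction_to_fasta",
    "load_loci",
    "load_junction",
    "write_table",
    "read_table",
]

DEFAULT_QUALITY = 37  # constant Q37: the classifier is quality-agnostic


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(reads: Iterable[tuple[str, str]], path, quality: int = DEFAULT_QUALITY) -> int:
    """Write ``(read_id, sequence)`` pairs as 4-line FASTQ with constant quality.

    Byte-deterministic for identical input. Returns the number of records.
    """
    qchar = chr(quality + 33)
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")
            n += 1
    return n


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Iterate ``(read_id, sequence)`` from a FASTQ file (gz-transparent)."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq)


def junction_to_fasta(junction: JunctionReference, path) -> None:
    """Export the junction reference as FASTA with the junction coordinate."""
    with open(path, "w") as fh:
        fh.write(
            f">{junction.name} junction={junction.junction} "
            f"flank_left={junction.flank_left} flank_right={junction.flank_right}\n"
        )
        seq = junction.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def load_loci(config_path) -> list[LocusSpec]:
    """Load locus specifications from a YAML config.

    The config holds a ``loci`` list; each entry gives ``name``,
    ``protospacer``, ``orientation``, ``retained_side`` and either an inline
    ``context`` or a ``fasta`` path (with optional ``record`` id) next to the
    config file.
    """
    from pathlib import Path

    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    loci = []
    for entry in cfg["loci"]:
        if "context" in entry:
            context = entry["context"]
        else:
            fasta = config_path.parent / entry["fasta"]
            records = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")}
            context = records[entry["record"]] if "record" in entry else next(iter(records.values()))
        loci.append(
            LocusSpec(
                name=entry["name"],
                context=context.upper(),
                protospacer=entry["protospacer"].upper(),
                orientation=entry["orientation"],
                retained_side=entry["retained_side"],
            )
        )
    return loci


def load_junction(config_path) -> JunctionReference:
    """Build the junction reference described by a two-locus YAML config."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    loci = load_loci(config_path)
    if len(loci) != 2:
        raise ValueError(f"expected exactly 2 loci, found {len(loci)}")
    flank = int(cfg.get("flank", 60))
    flank_right = cfg.get("flank_right")
    return build_junction_reference(
        loci[0], loci[1], flank, None if flank_right is None else int(flank_right)
    )


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy TSV (no index, '\\n' line endings; byte-deterministic)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
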