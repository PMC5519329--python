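"""Readers and writers shared by the pipeline stages.

Conventions: BED-style interval tables (0-based half-open) as TSV without
header, contig sizes as two-column ``chrom\tlength``, protein and genome
sequences as FASTA (via Biopython), PWMs in MEME minimal format (see
:mod:`prdm9kit.motif`).  TSV outputs carry a ``#`` provenance header
echoing the run configuration and seed.
"""

from __future__ import annotations

from importlib.metadata import PackageNotFoundError, version
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

try:
    __version__ = version("prdm9kit")
except PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"

BED_COLUMNS = ["chrom", "start", "end"]


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {record id: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: Mapping[str, str] | list[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in items),
        str(path),
        "fasta",
    )


def read_bed(path) -> pd.DataFrame:
    """BED3(+) -> DataFrame with chrom/start/end (extra columns ignored)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=BED_COLUMNS,
        dtype={"chrom": str, "start": int, "end": int},
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: interval with start >= end")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_contig_sizes(path) -> dict[str, int]:
    """Two-column chrom\tlength file -> dict."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=["chrom", "length"],
        dtype={"chrom": str, "length": int},
    )
    return dict(zip(df["chrom"], df["length"]))


def write_contig_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def write_tsv(df: pd.DataFrame, path, config: Mapping | None = None) -> None:
    """TSV with a commented provenance header (config echo + version)."""
    with open(path, "w") as fh:
        fh.write(f"# prdm9kit {__version__}\n")
        for key, value in (config or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_config(path) -> dict[str, str]:
    """Plain key = value text config; '#' comments and blank lines ignored."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{line_no}: expected 'key = value'")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
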