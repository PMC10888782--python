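"""CEL-seq-style read ingestion: read-2 structure parsing, exact-match
barcode demultiplexing, and unique-UMI counting into a gene x sample matrix.

Read 1 carries the transcript (gene assignment is supplied upstream, either
by a mapper or by the simulator); read 2 is consumed entirely as a 10-nt UMI
followed by a 6-nt sample barcode.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

UMI_LENGTH = 10
BARCODE_LENGTH = 6

__all__ = [
    "ReadRecord",
    "ReadStructureError",
    "parse_read_structure",
    "demultiplex",
    "count_unique_umis",
    "read_fastq_pairs",
    "read_assigned_table",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_mtx",
]


class ReadStructureError(ValueError):
    """Raised when read 2 is too short to contain UMI + barcode."""


@dataclass
class ReadRecord:
    read_id: str
    read1_seq: str
    read2_seq: str
    gene: str | None = None  # None = unassigned

    @property
    def umi(self) -> str:
        return parse_read_structure(self.read2_seq, read_id=self.read_id)[0]

    @property
    def barcode(self) -> str:
        return parse_read_structure(self.read2_seq, read_id=self.read_id)[1]


def parse_read_structure(read2_seq: str, read_id: str = "") -> tuple[str, str]:
    """Split read 2 into (10-nt UMI, 6-nt barcode); bases beyond 16 (polyT)
    are discarded."""
    if len(read2_seq) < UMI_LENGTH + BARCODE_LENGTH:
        where = f" in read {read_id!r}" if read_id else ""
        raise ReadStructureError(
            f"read 2 length {len(read2_seq)} < {UMI_LENGTH + BARCODE_LENGTH}{where}"
        )
    return read2_seq[:UMI_LENGTH], read2_seq[UMI_LENGTH : UMI_LENGTH + BARCODE_LENGTH]


def _validate_whitelist(whitelist: Iterable[str]) -> set[str]:
    wl = list(whitelist)
    if not wl:
        raise ValueError("barcode whitelist is empty")
    if len(set(wl)) != len(wl):
        dupes = sorted({b for b in wl if wl.count(b) > 1})
        raise ValueError(f"duplicate whitelist barcodes: {dupes}")
    for b in wl:
        if len(b) != BARCODE_LENGTH:
            raise ValueError(f"barcode {b!r} is not {BARCODE_LENGTH} nt")
    return set(wl)


def demultiplex(
    records: Iterable[ReadRecord],
    whitelist: Iterable[str],
) -> tuple[dict[str, list[ReadRecord]], int]:
    """Assign records to samples by exact barcode match.

    Returns (per-barcode record lists, discard count). A record is kept iff
    its barcode matches a whitelist entry exactly — single-mismatch rescue is
    deliberately not attempted.
    """
    wl = _validate_whitelist(whitelist)
    by_sample: dict[str, list[ReadRecord]] = {b: [] for b in sorted(wl)}
    discarded = 0
    for rec in records:
        bc = parse_read_structure(rec.read2_seq, read_id=rec.read_id)[1]
        if bc in wl:
            by_sample[bc].append(rec)
        else:
            discarded += 1
    return by_sample, discarded


def count_unique_umis(
    assigned: Mapping[str, Iterable[ReadRecord]],
) -> pd.DataFrame:
    """Count distinct UMIs per (gene, sample); unassigned reads are ignored.

    Deduplication is exact-match on the UMI sequence, scoped per gene: the
    same UMI on two genes counts once for each.
    """
    umis: dict[tuple[str, str], set[str]] = {}
    for sample, recs in assigned.items():
        for rec in recs:
            if rec.gene is None:
                continue
            umi = parse_read_structure(rec.read2_seq, read_id=rec.read_id)[0]
            umis.setdefault((rec.gene, str(sample)), set()).add(umi)
    if not umis:
        return pd.DataFrame(
            index=pd.Index([], name="gene"), columns=list(assigned), dtype=int
        ).fillna(0).astype(int)
    counts = pd.Series({k: len(v) for k, v in umis.items()})
    mat = counts.unstack(fill_value=0)
    mat = mat.reindex(columns=sorted(assigned), fill_value=0)
    mat.index.name = "gene"
    return mat.astype(int)


# ---------------------------------------------------------------------------
# I/O


def read_fastq_pairs(fastq1: str | os.PathLike, fastq2: str | os.PathLike):
    """Yield ReadRecords from paired FASTQ files (read order must match)."""
    from Bio import SeqIO

    it1 = SeqIO.parse(str(fastq1), "fastq")
    it2 = SeqIO.parse(str(fastq2), "fastq")
    for r1, r2 in zip(it1, it2, strict=True):
        yield ReadRecord(read_id=r1.id, read1_seq=str(r1.seq), read2_seq=str(r2.seq))


def read_assigned_table(path: str | os.PathLike) -> list[ReadRecord]:
    """Read a pre-assigned read table (columns read_id, gene, umi, barcode).

    The UMI and barcode are re-packed into a synthetic read-2 sequence so the
    records flow through the same demultiplex/count path as FASTQ input.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"read_id", "gene", "umi", "barcode"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assigned table missing columns: {sorted(missing)}")
    records = []
    for r in df.itertuples():
        gene = None if pd.isna(r.gene) or r.gene == "" else r.gene
        records.append(
            ReadRecord(read_id=r.read_id, read1_seq="", read2_seq=r.umi + r.barcode, gene=gene)
        )
    return records


def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_mtx(counts: pd.DataFrame, prefix: str | os.PathLike) -> None:
    """Write MatrixMarket triplet plus gene/sample sidecar files."""
    from scipy import io as spio
    from scipy import sparse

    prefix = str(prefix)
    spio.mmwrite(prefix + ".mtx", sparse.csr_matrix(counts.to_numpy()))
    with open(prefix + ".genes.txt", "w") as fh:
        fh.write("\n".join(map(str, counts.index)) + "\n")
    with open(prefix + ".samples.txt", "w") as fh:
        fh.write("\n".join(map(str, counts.columns)) + "\n")
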