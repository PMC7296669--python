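"""Genome container and FASTA/BED input-output.

Coordinates are 0-based half-open everywhere inside the package; BED files
keep that convention, VCF positions are converted to 1-based at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: column layout for every interval table in the package
BED_COLUMNS = ["contig", "start", "end"]


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 codes 0..3 (A,C,G,T)."""
    raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(raw.size, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    if (codes == 255).any():
        bad = chr(raw[codes == 255][0])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def gc_fraction(codes: np.ndarray) -> float:
    if codes.size == 0:
        return float("nan")
    return float(np.isin(codes, (1, 2)).mean())


@dataclass
class GenomeAssembly:
    """Named contigs plus truth/annotation interval tables.

    ``sequences`` maps contig name to a uint8 code array; the interval
    tables (``duplicates``, ``cds``, ``centromeres``) use BED_COLUMNS and
    may carry extra columns (``pair_id``, ``kind`` for duplicates).
    """

    sequences: dict[str, np.ndarray]
    duplicates: pd.DataFrame = field(default_factory=lambda: empty_intervals())
    cds: pd.DataFrame = field(default_factory=lambda: empty_intervals())
    centromeres: pd.DataFrame = field(default_factory=lambda: empty_intervals())

    @property
    def contigs(self) -> list[str]:
        return list(self.sequences)

    @property
    def size(self) -> int:
        return int(sum(s.size for s in self.sequences.values()))

    def contig_lengths(self) -> dict[str, int]:
        return {c: int(s.size) for c, s in self.sequences.items()}

    def sequence(self, contig: str, start: int = 0, end: int | None = None) -> str:
        return decode(self.sequences[contig][start:end])

    def gc(self, intervals: pd.DataFrame | None = None) -> float:
        """GC fraction of the whole genome or of a set of intervals."""
        if intervals is None:
            counts = np.concatenate(list(self.sequences.values()))
            return gc_fraction(counts)
        parts = [
            self.sequences[r.contig][int(r.start): int(r.end)]
            for r in intervals.itertuples()
        ]
        if not parts:
            return float("nan")
        return gc_fraction(np.concatenate(parts))

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(decode(codes)), id=name, description="")
            for name, codes in self.sequences.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeAssembly":
        seqs = {
            rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
        }
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls(sequences=seqs)


def empty_intervals(extra: list[str] | None = None) -> pd.DataFrame:
    cols = BED_COLUMNS + (extra or [])
    return pd.DataFrame({c: pd.Series(dtype=int if c in ("start", "end") else object)
                         for c in cols})


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = BED_COLUMNS
    return df.astype({"start": int, "end": int})


def write_bed(df: pd.DataFrame, path: str | Path, extra: list[str] | None = None) -> None:
    cols = BED_COLUMNS + [c for c in (extra or []) if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per contig; result sorted."""
    if len(df) == 0:
        return empty_intervals()
    out = []
    for contig, sub in df.sort_values(["contig", "start"]).groupby("contig", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e + gap:
                cur_e = max(cur_e, int(e))
            else:
                out.append((contig, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((contig, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED_COLUMNS)


def total_length(df: pd.DataFrame) -> int:
    merged = merge_intervals(df)
    return int((merged["end"] - merged["start"]).sum())


def points_in_intervals(
    contigs: np.ndarray, positions: np.ndarray, merged: pd.DataFrame
) -> np.ndarray:
    """Boolean mask: is each (contig, pos) inside the merged interval set."""
    mask = np.zeros(len(positions), dtype=bool)
    for contig, sub in merged.groupby("contig"):
        sel = contigs == contig
        if not sel.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, positions[sel], side="right") - 1
        ok = idx >= 0
        inside = np.zeros(sel.sum(), dtype=bool)
        inside[ok] = positions[sel][ok] < ends[idx[ok]]
        mask[sel] = inside
    return mask
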