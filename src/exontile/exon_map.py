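"""Exon boundaries on transcripts from genomic alignment blocks.

Aligning a transcript back to genomic sequence breaks it into blocks
separated by introns on the genomic side.  Blocks from the single best
(minimum E-value) alignment that passes the significance cut-off
(E < 1e-15) are merged when both the transcript-side and genomic-side
gaps are small (small indels), and split into separate exons when the
genomic gap looks intronic.  Transcripts without usable alignment get a
single-exon uniform fallback so probes are spread evenly along them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from .io_model import DesignParams, SequenceRecord

__all__ = [
    "ExonProvenance",
    "ExonStructure",
    "AlignmentBlock",
    "exon_blocks_from_alignment",
    "uniform_fallback",
    "read_blocks",
    "write_exon_structures",
    "read_exon_structures",
]

# Transcript-side gap up to this many bases is treated as an indel, not
# a boundary.
TRANSCRIPT_GAP_TOLERANCE = 3


class ExonProvenance(str, Enum):
    ALIGNMENT_DERIVED = "alignment_derived"
    UNIFORM_FALLBACK = "uniform_fallback"


@dataclass(frozen=True)
class ExonStructure:
    """Ordered exon intervals [start, end) on a transcript, 0-based."""

    record_id: str
    exons: tuple[tuple[int, int], ...]
    provenance: ExonProvenance

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"empty exon [{start},{end}) on {self.record_id}")
            if start < prev_end:
                raise ValueError(f"overlapping/unsorted exons on {self.record_id}")
            prev_end = end
        if self.provenance is ExonProvenance.ALIGNMENT_DERIVED and not self.exons:
            raise ValueError("alignment-derived structure must have >= 1 exon")


@dataclass(frozen=True)
class AlignmentBlock:
    """One gapless block of a transcript-to-genome alignment."""

    record_id: str
    q_start: int
    q_end: int  # transcript coords, 0-based half-open
    g_start: int
    g_end: int  # genomic coords
    e_value: float

    def __post_init__(self) -> None:
        if self.q_start >= self.q_end:
            raise ValueError("block requires q_start < q_end")


def exon_blocks_from_alignment(
    record: SequenceRecord,
    blocks: Iterable[AlignmentBlock],
    params: DesignParams | None = None,
) -> ExonStructure | None:
    """Derive exon boundaries from alignment blocks, or None if unusable.

    Blocks whose parent alignment fails E < exon_evalue are discarded;
    among surviving alignments (grouped by their parent E-value) only the
    minimum-E one is used.  Consecutive blocks merge into one exon when
    the transcript gap is < 3 bases and the genomic gap is below
    ``min_intron_gap``; otherwise a boundary is placed between them.
    """
    params = params or DesignParams()
    blocks = [b for b in blocks if b.record_id == record.id]
    survivors = [b for b in blocks if b.e_value < params.exon_evalue]
    if not survivors:
        return None
    best_e = min(b.e_value for b in survivors)
    chain = sorted(
        (b for b in survivors if b.e_value == best_e), key=lambda b: b.q_start
    )
    for prev, cur in zip(chain, chain[1:]):
        if cur.q_start < prev.q_end:
            raise ValueError(
                f"overlapping transcript blocks on {record.id}: "
                f"[{prev.q_start},{prev.q_end}) and [{cur.q_start},{cur.q_end})"
            )
    exons: list[list[int]] = [[chain[0].q_start, chain[0].q_end]]
    for prev, cur in zip(chain, chain[1:]):
        t_gap = cur.q_start - prev.q_end
        g_gap = abs(cur.g_start - prev.g_end)
        if t_gap < TRANSCRIPT_GAP_TOLERANCE and g_gap < params.min_intron_gap:
            exons[-1][1] = cur.q_end
        else:
            exons.append([cur.q_start, cur.q_end])
    clipped = tuple(
        (start, min(end, len(record.sequence)))
        for start, end in exons
        if start < len(record.sequence)
    )
    return ExonStructure(
        record_id=record.id,
        exons=clipped,
        provenance=ExonProvenance.ALIGNMENT_DERIVED,
    )


def uniform_fallback(record: SequenceRecord) -> ExonStructure:
    """Single exon spanning the whole transcript (probes spread evenly)."""
    return ExonStructure(
        record_id=record.id,
        exons=((0, len(record.sequence)),),
        provenance=ExonProvenance.UNIFORM_FALLBACK,
    )


# ---------------------------------------------------------------------------
# TSV IO (1-based inclusive on disk, converted on read/write)


def read_blocks(path: str | Path) -> list[AlignmentBlock]:
    """Read alignment blocks from TSV with header
    record_id, q_start, q_end, g_start, g_end, e_value (1-based inclusive)."""
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                blocks.append(
                    AlignmentBlock(
                        record_id=row["record_id"],
                        q_start=int(row["q_start"]) - 1,
                        q_end=int(row["q_end"]),
                        g_start=int(row["g_start"]) - 1,
                        g_end=int(row["g_end"]),
                        e_value=float(row["e_value"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"malformed block row at line {lineno}: {exc}") from None
    return blocks


def write_exon_structures(
    structures: Iterable[ExonStructure], path: str | Path
) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("record_id\texon_index\tstart\tend\tprovenance\n")
        for s in structures:
            for i, (start, end) in enumerate(s.exons):
                fh.write(f"{s.record_id}\t{i}\t{start + 1}\t{end}\t{s.provenance.value}\n")


def read_exon_structures(path: str | Path) -> dict[str, ExonStructure]:
    rows: dict[str, list[tuple[int, int, int, str]]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.setdefault(row["record_id"], []).append(
                (
                    int(row["exon_index"]),
                    int(row["start"]) - 1,
                    int(row["end"]),
                    row["provenance"],
                )
            )
    out: dict[str, ExonStructure] = {}
    for rid, exon_rows in rows.items():
        exon_rows.sort()
        out[rid] = ExonStructure(
            record_id=rid,
            exons=tuple((s, e) for _, s, e, _ in exon_rows),
            provenance=ExonProvenance(exon_rows[0][3]),
        )
    return out
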