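"""Transcript orientation by a five-stage evidence cascade.

Each sequence is oriented 5'->3' using, in fixed order of decreasing
reliability: (1) protein alignment evidence, (2) genomic alignment
evidence, (3) hybridisation signal from a prior expression array,
(4) the longest open reading frame, and (5) a poly-A (or 5' poly-T)
tail.  The first stage that yields a confident call decides; a reverse
call replaces the stored sequence by its reverse complement.  Records
with no confident evidence remain unorientated but are kept — they are
tiled later with the uniform fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping

from .io_model import (
    AlignmentHit,
    DesignParams,
    OrientationEvidence,
    OrientationStatus,
    SequenceRecord,
    Strand,
    reverse_complement,
)

__all__ = [
    "Direction",
    "SignalState",
    "OrientationVote",
    "orient_by_alignment",
    "orient_by_signal",
    "orient_by_longest_orf",
    "orient_by_polya",
    "resolve_orientation",
    "longest_orf_codons",
]


class Direction(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"
    NONE = "none"


class SignalState(str, Enum):
    SENSE_DETECTED = "sense_detected"
    ANTISENSE_DETECTED = "antisense_detected"
    ABSENT = "absent"


@dataclass(frozen=True)
class OrientationVote:
    record_id: str
    direction: Direction
    evidence: OrientationEvidence
    score: float = 0.0


_NO_VOTE_EVIDENCE = OrientationEvidence.NONE


def _none_vote(record_id: str, evidence: OrientationEvidence) -> OrientationVote:
    return OrientationVote(record_id, Direction.NONE, evidence, 0.0)


def orient_by_alignment(
    record: SequenceRecord,
    hits: Iterable[AlignmentHit],
    evidence_class: OrientationEvidence,
    e_threshold: float,
) -> OrientationVote:
    """Vote from the best alignment hit (minimum E, then max bit score).

    For protein evidence the strand is taken from the sign of the query
    frame (13th tabular column); otherwise from the subject strand.
    """
    mine = [h for h in hits if h.query_id == record.id]
    if not mine:
        return _none_vote(record.id, evidence_class)
    best = min(mine, key=lambda h: (h.e_value, -h.bit_score, h.subject_id))
    if not best.e_value < e_threshold:
        return _none_vote(record.id, evidence_class)
    if evidence_class is OrientationEvidence.PROTEIN_HIT and best.query_frame is not None:
        reverse = best.query_frame < 0
    else:
        reverse = best.subject_strand is Strand.MINUS
    score = 300.0 if best.e_value == 0 else -math.log10(best.e_value)
    return OrientationVote(
        record.id,
        Direction.REVERSE if reverse else Direction.FORWARD,
        evidence_class,
        score,
    )


def orient_by_signal(
    record: SequenceRecord,
    signal_table: Mapping[str, SignalState],
) -> OrientationVote:
    """Vote from prior-array hybridisation signal: a sense-strand signal
    means the stored sequence already matches the transcribed strand."""
    state = signal_table.get(record.id, SignalState.ABSENT)
    if state is SignalState.SENSE_DETECTED:
        return OrientationVote(
            record.id, Direction.FORWARD, OrientationEvidence.ARRAY_SIGNAL, 1.0
        )
    if state is SignalState.ANTISENSE_DETECTED:
        return OrientationVote(
            record.id, Direction.REVERSE, OrientationEvidence.ARRAY_SIGNAL, 1.0
        )
    return _none_vote(record.id, OrientationEvidence.ARRAY_SIGNAL)


_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf_codons(seq: str) -> int:
    """Longest ATG..stop open reading frame on the given strand, in codons
    (ATG included, stop excluded); 0 if none is complete."""
    best = 0
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if start is not None:
                    best = max(best, (i - start) // 3)
                    start = None
            elif codon == "ATG" and start is None:
                start = i
    return best


def orient_by_longest_orf(
    record: SequenceRecord,
    orf_min_codons: int = 100,
    orf_margin_ratio: float = 1.5,
) -> OrientationVote:
    """Vote for the strand carrying the clearly longest complete ORF.

    Confident only when the winning strand's ORF reaches ``orf_min_codons``
    AND exceeds the other strand's by the margin ratio; ties abstain.
    """
    if len(record.sequence) < 3:
        return _none_vote(record.id, OrientationEvidence.LONGEST_ORF)
    fwd = longest_orf_codons(record.sequence)
    rev = longest_orf_codons(reverse_complement(record.sequence))
    if fwd >= orf_min_codons and fwd >= orf_margin_ratio * rev and fwd > rev:
        return OrientationVote(
            record.id, Direction.FORWARD, OrientationEvidence.LONGEST_ORF, float(fwd)
        )
    if rev >= orf_min_codons and rev >= orf_margin_ratio * fwd and rev > fwd:
        return OrientationVote(
            record.id, Direction.REVERSE, OrientationEvidence.LONGEST_ORF, float(rev)
        )
    return _none_vote(record.id, OrientationEvidence.LONGEST_ORF)


def _longest_run(seq: str, base: str) -> int:
    best = run = 0
    for c in seq:
        run = run + 1 if c == base else 0
        best = max(best, run)
    return best


def orient_by_polya(
    record: SequenceRecord,
    polya_min_run: int = 10,
    polya_window: int = 25,
) -> OrientationVote:
    """Vote from a terminal poly-A tail (forward) or 5' poly-T head
    (reverse: the read is the reverse complement of a polyadenylated
    transcript).  Both present -> conflicting evidence, abstain."""
    tail = record.sequence[-polya_window:]
    head = record.sequence[:polya_window]
    a_run = _longest_run(tail, "A")
    t_run = _longest_run(head, "T")
    has_a = a_run >= polya_min_run
    has_t = t_run >= polya_min_run
    if has_a and not has_t:
        return OrientationVote(
            record.id, Direction.FORWARD, OrientationEvidence.POLYA_TAIL, float(a_run)
        )
    if has_t and not has_a:
        return OrientationVote(
            record.id, Direction.REVERSE, OrientationEvidence.POLYA_TAIL, float(t_run)
        )
    return _none_vote(record.id, OrientationEvidence.POLYA_TAIL)


def resolve_orientation(
    record: SequenceRecord,
    protein_hits: Iterable[AlignmentHit] = (),
    genomic_hits: Iterable[AlignmentHit] = (),
    signal_table: Mapping[str, SignalState] | None = None,
    params: DesignParams | None = None,
) -> SequenceRecord:
    """Run the cascade and return the (possibly reverse-complemented) record.

    Stage order: protein -> genomic -> array signal -> longest ORF ->
    poly-A; the first non-abstaining vote decides and its evidence class
    is recorded.  No vote at all leaves the record unorientated.
    """
    params = params or DesignParams()
    signal_table = signal_table or {}
    stages = (
        lambda: orient_by_alignment(
            record, protein_hits, OrientationEvidence.PROTEIN_HIT,
            params.orientation_evalue,
        ),
        lambda: orient_by_alignment(
            record, genomic_hits, OrientationEvidence.GENOMIC_HIT,
            params.orientation_evalue,
        ),
        lambda: orient_by_signal(record, signal_table),
        lambda: orient_by_longest_orf(
            record, params.orf_min_codons, params.orf_margin_ratio
        ),
        lambda: orient_by_polya(record, params.polya_min_run, params.polya_window),
    )
    for stage in stages:
        vote = stage()
        if vote.direction is Direction.NONE:
            continue
        if vote.direction is Direction.REVERSE:
            return replace(
                record,
                sequence=reverse_complement(record.sequence),
                orientation_status=OrientationStatus.REVERSE_COMPLEMENTED,
                orientation_evidence=vote.evidence,
            )
        return replace(
            record,
            orientation_status=OrientationStatus.FORWARD,
            orientation_evidence=vote.evidence,
        )
    return replace(
        record,
        orientation_status=OrientationStatus.UNORIENTATED,
        orientation_evidence=OrientationEvidence.NONE,
    )
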