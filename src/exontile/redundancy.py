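"""Redundancy elimination for combined unigene / gene-prediction sets.

A sequence is redundant when, as BLAST *query*, it aligns to an
already-retained sequence with >98 % identity over >75 % of its own length
at E < 1e-5 (all strict).  Collapse is greedy in a deterministic priority
order that prefers gene predictions over unigenes, longer sequences over
shorter, and finally lexicographic id — so a redundant unigene is always
eliminated in favour of the gene prediction it matches.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_model import (
    AlignmentHit,
    DesignParams,
    SequenceRecord,
    SourceClass,
    Strand,
    reverse_complement,
)

__all__ = [
    "EliminationRecord",
    "hit_redundant",
    "collapse_redundant",
    "align_pair",
]

# Retention priority: higher rank wins. Controls are exempt from the
# collapse entirely (they are added to the design after filtering).
_CLASS_RANK = {
    SourceClass.GENE_PREDICTION: 5,
    SourceClass.SCAFFOLD_MODEL: 4,
    SourceClass.AT_MODEL: 3,
    SourceClass.VELVET_CONTIG: 2,
    SourceClass.UNIGENE: 1,
    SourceClass.CONTROL: 0,
}


@dataclass(frozen=True)
class EliminationRecord:
    """One collapse decision: which record was dropped, against which."""

    eliminated_id: str
    retained_id: str
    percent_identity: float
    query_aligned_fraction: float
    e_value: float

    def __post_init__(self) -> None:
        if self.eliminated_id == self.retained_id:
            raise ValueError("a record cannot eliminate itself")


def hit_redundant(hit: AlignmentHit, params: DesignParams) -> bool:
    """True iff the hit satisfies the redundancy rule (all bounds strict)."""
    return (
        hit.percent_identity > params.redundancy_identity_pct
        and hit.query_aligned_fraction > params.redundancy_query_fraction
        and hit.e_value < params.redundancy_evalue
    )


def _priority_key(rec: SequenceRecord):
    # Sort descending rank, descending length, ascending id.
    return (-_CLASS_RANK[rec.source_class], -len(rec.sequence), rec.id)


def collapse_redundant(
    records: list[SequenceRecord],
    hits: list[AlignmentHit],
    params: DesignParams,
) -> tuple[list[SequenceRecord], list[EliminationRecord]]:
    """Greedy rank-order collapse of redundant records.

    Records are visited in priority order; a record is eliminated iff some
    already-retained record is the subject of a redundancy-qualifying hit
    with the visited record as query.  Returns (retained records in input
    order, elimination log).
    """
    ids = {r.id for r in records}
    for h in hits:
        if h.query_id not in ids or h.subject_id not in ids:
            missing = h.query_id if h.query_id not in ids else h.subject_id
            raise ValueError(f"hit references unknown record id {missing!r}")

    qualifying: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if hit_redundant(h, params):
            qualifying.setdefault(h.query_id, []).append(h)

    by_id = {r.id: r for r in records}
    retained_ids: set[str] = set()
    log: list[EliminationRecord] = []
    for rec in sorted(records, key=_priority_key):
        if rec.source_class is SourceClass.CONTROL:
            retained_ids.add(rec.id)  # exempt; also never a collapse subject
            continue
        trigger = None
        for h in sorted(
            qualifying.get(rec.id, ()), key=lambda h: (h.e_value, h.subject_id)
        ):
            if h.subject_id in retained_ids:
                if by_id[h.subject_id].source_class is not SourceClass.CONTROL:
                    trigger = h
                    break
        if trigger is None:
            retained_ids.add(rec.id)
        else:
            log.append(
                EliminationRecord(
                    eliminated_id=rec.id,
                    retained_id=trigger.subject_id,
                    percent_identity=trigger.percent_identity,
                    query_aligned_fraction=trigger.query_aligned_fraction,
                    e_value=trigger.e_value,
                )
            )
    retained = [r for r in records if r.id in retained_ids]
    return retained, log


# ---------------------------------------------------------------------------
# Desk-scale seeded aligner (fixture tool; production input is tabular)


def _seeds(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _extend(a: str, b: str, qpos: int, spos: int, k: int, xdrop: int = 10):
    """Ungapped extension of an exact k-mer seed; +1 match / -2 mismatch."""
    score = k
    # extend right
    best, best_r = score, (qpos + k, spos + k)
    i, j, cur = qpos + k, spos + k, score
    while i < len(a) and j < len(b):
        cur += 1 if a[i] == b[j] else -2
        i += 1
        j += 1
        if cur > best:
            best, best_r = cur, (i, j)
        if best - cur > xdrop:
            break
    # extend left
    score = best
    best_l = (qpos, spos)
    i, j, cur = qpos - 1, spos - 1, score
    while i >= 0 and j >= 0:
        cur += 1 if a[i] == b[j] else -2
        if cur > score:
            score, best_l = cur, (i, j)
        if score - cur > xdrop:
            break
        i -= 1
        j -= 1
    q0, s0 = best_l
    q1, s1 = best_r
    matches = sum(1 for x, y in zip(a[q0:q1], b[s0:s1]) if x == y)
    return score, q0, q1, matches


def align_pair(
    a: SequenceRecord, b: SequenceRecord, seed_k: int = 18
) -> AlignmentHit | None:
    """Seeded ungapped local alignment between two records (both strands).

    Fixture-scale stand-in for an external aligner: exact seed_k-mer seeds
    are extended ungapped (+1/-2, X-drop 10) and the best segment reported.
    The E-value is a documented surrogate, 2**(-bit) with bit = score / 2,
    monotone in the alignment score; absent (None) when no seed is shared.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("align_pair requires non-empty sequences")
    best = None  # (score, q0, q1, matches, strand)
    for strand, bseq in (
        (Strand.PLUS, b.sequence),
        (Strand.MINUS, reverse_complement(b.sequence)),
    ):
        sidx = _seeds(bseq, seed_k)
        seen: set[tuple[int, int]] = set()
        for qpos in range(len(a.sequence) - seed_k + 1):
            kmer = a.sequence[qpos : qpos + seed_k]
            for spos in sidx.get(kmer, ()):
                diag = (qpos - spos, strand is Strand.MINUS)
                if diag in seen:
                    continue
                seen.add(diag)
                score, q0, q1, matches = _extend(
                    a.sequence, bseq, qpos, spos, seed_k
                )
                if best is None or score > best[0]:
                    best = (score, q0, q1, matches, strand)
    if best is None:
        return None
    score, q0, q1, matches, strand = best
    aligned = q1 - q0
    bit = 0.5 * score
    return AlignmentHit(
        query_id=a.id,
        subject_id=b.id,
        percent_identity=100.0 * matches / aligned,
        query_aligned_fraction=aligned / len(a.sequence),
        e_value=2.0 ** (-bit),
        subject_strand=strand,
        bit_score=bit,
    )
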