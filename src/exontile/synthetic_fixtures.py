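"""Seeded synthetic inputs with known truth for every pipeline stage.

The generators emulate the study design at desk scale: unigene sets with
planted duplicates (controlled identity and query coverage), planted
orientations each backed by exactly one unambiguous evidence class, and
two-condition (leaf/root-style) expression matrices with planted
differential-expression and exon-splicing effects.  Base genes are
screened to share no 18-mer, so the cross-hybridisation filter fires
only on planted collisions.  Every generator is a pure function of its
parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    AlignmentHit,
    DesignParams,
    ExpressionMatrix,
    SequenceRecord,
    SourceClass,
    Strand,
)
from .array_analysis import BiasPair
from .orientation import (
    Direction,
    OrientationEvidence,
    SignalState,
    longest_orf_codons,
    orient_by_longest_orf,
    orient_by_polya,
)
from .probe_tiling import ArrayDesign, canonical_kmer

__all__ = [
    "DuplicateTruth",
    "FixtureTruth",
    "UnigeneFixture",
    "make_unigene_set",
    "make_expression_matrix",
    "make_control_pairs",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - _STOPS - {"ATG"}
)

EVIDENCE_CYCLE = (
    OrientationEvidence.PROTEIN_HIT,
    OrientationEvidence.GENOMIC_HIT,
    OrientationEvidence.ARRAY_SIGNAL,
    OrientationEvidence.LONGEST_ORF,
    OrientationEvidence.POLYA_TAIL,
)


@dataclass(frozen=True)
class DuplicateTruth:
    duplicate_id: str
    parent_id: str
    percent_identity: float  # realised, from the edit script
    query_aligned_fraction: float  # realised


@dataclass
class FixtureTruth:
    """Ground truth for a generated fixture set."""

    seed: int
    duplicates: list[DuplicateTruth] = field(default_factory=list)
    orientation: dict[str, tuple[Direction, OrientationEvidence]] = field(
        default_factory=dict
    )
    de_log2fc: dict[str, float] = field(default_factory=dict)
    spliced_ratio: dict[str, float] = field(default_factory=dict)


@dataclass
class UnigeneFixture:
    records: list[SequenceRecord]
    protein_hits: list[AlignmentHit]
    genomic_hits: list[AlignmentHit]
    signal_table: dict[str, SignalState]
    redundancy_hits: list[AlignmentHit]
    truth: FixtureTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _kmers(seq: str, k: int) -> set[str]:
    return {canonical_kmer(seq[i : i + k]) for i in range(len(seq) - k + 1)}


def _disjoint_random_seq(
    rng: np.random.Generator,
    length: int,
    used: set[str],
    k: int = 18,
    max_tries: int = 50,
) -> str:
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        if not (_kmers(seq, k) & used):
            return seq
    raise RuntimeError(
        f"could not generate an 18-mer-disjoint sequence of length {length}; "
        "parameters infeasible"
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def make_unigene_set(
    n_genes: int,
    length_range: tuple[int, int] = (800, 1200),
    dup_fraction: float = 0.0,
    dup_identity: float = 99.5,
    dup_coverage: float = 0.9,
    seed: int = 0,
    rc_fraction: float = 0.5,
    plant_evidence: bool = True,
    params: DesignParams | None = None,
) -> UnigeneFixture:
    """Generate a unigene set with planted duplicates and orientations.

    Base genes are mutually 18-mer disjoint uniform-random sequences.
    When ``plant_evidence`` is set, each base gene receives exactly one
    unambiguous orientation evidence source, assigned round-robin over
    the five evidence classes (alignment/signal rows emitted, or an ORF
    cassette / poly-A tail written into the sequence); a ``rc_fraction``
    of records is then stored reverse-complemented, with the evidence
    flipped to match and the expected direction recorded as truth.
    Duplicates copy a ``dup_coverage`` fraction of a parent and are
    mutated by substitutions to the requested identity, so the realised
    identity/coverage of each planted duplicate are known exactly.
    """
    if not 80.0 <= dup_identity <= 100.0:
        raise ValueError("dup_identity must lie in [80, 100]")
    params = params or DesignParams()
    rng = np.random.default_rng(seed)
    truth = FixtureTruth(seed=seed)
    protein_hits: list[AlignmentHit] = []
    genomic_hits: list[AlignmentHit] = []
    signal_table: dict[str, SignalState] = {}
    used_kmers: set[str] = set()

    sequences: dict[str, str] = {}
    ids: list[str] = []
    for g in range(n_genes):
        gid = f"gene{g:03d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        evidence = EVIDENCE_CYCLE[g % len(EVIDENCE_CYCLE)] if plant_evidence else None
        seq = None
        for _ in range(50):
            cand = _disjoint_random_seq(rng, length, used_kmers)
            if evidence is OrientationEvidence.LONGEST_ORF:
                cand = _insert_orf_cassette(rng, cand, params)
                if cand is None:
                    continue
                if _kmers(cand, 18) & used_kmers:
                    continue
            elif evidence is OrientationEvidence.POLYA_TAIL:
                cand = cand + "A" * (params.polya_min_run + 2)
                probe_rec = SequenceRecord(id=gid, sequence=cand)
                vote = orient_by_polya(
                    probe_rec, params.polya_min_run, params.polya_window
                )
                if vote.direction is not Direction.FORWARD:
                    continue
                if _kmers(cand, 18) & used_kmers:
                    continue
            elif evidence is None or evidence in (
                OrientationEvidence.PROTEIN_HIT,
                OrientationEvidence.GENOMIC_HIT,
                OrientationEvidence.ARRAY_SIGNAL,
            ):
                pass
            if evidence in (
                OrientationEvidence.ARRAY_SIGNAL,
                OrientationEvidence.LONGEST_ORF,
                OrientationEvidence.POLYA_TAIL,
                None,
            ):
                # these records must abstain at earlier cascade stages;
                # alignment stages abstain by construction (no hits emitted)
                pass
            if evidence is OrientationEvidence.POLYA_TAIL:
                # must abstain at the ORF stage for the planted class to win
                rec = SequenceRecord(id=gid, sequence=cand)
                if (
                    orient_by_longest_orf(
                        rec, params.orf_min_codons, params.orf_margin_ratio
                    ).direction
                    is not Direction.NONE
                ):
                    continue
            seq = cand
            break
        if seq is None:
            raise RuntimeError(f"could not plant evidence {evidence} for {gid}")
        used_kmers |= _kmers(seq, 18)
        sequences[gid] = seq
        ids.append(gid)

        if plant_evidence:
            flip = bool(rng.random() < rc_fraction)
            if evidence is OrientationEvidence.PROTEIN_HIT:
                protein_hits.append(
                    AlignmentHit(
                        query_id=gid,
                        subject_id="uniref_protein_1",
                        percent_identity=85.0,
                        query_aligned_fraction=0.6,
                        e_value=1e-20,
                        subject_strand=Strand.PLUS,
                        bit_score=200.0,
                        query_frame=-1 if flip else 1,
                    )
                )
            elif evidence is OrientationEvidence.GENOMIC_HIT:
                genomic_hits.append(
                    AlignmentHit(
                        query_id=gid,
                        subject_id="scaffold_1",
                        percent_identity=95.0,
                        query_aligned_fraction=0.8,
                        e_value=1e-30,
                        subject_strand=Strand.MINUS if flip else Strand.PLUS,
                        bit_score=300.0,
                    )
                )
            elif evidence is OrientationEvidence.ARRAY_SIGNAL:
                signal_table[gid] = (
                    SignalState.ANTISENSE_DETECTED if flip else SignalState.SENSE_DETECTED
                )
            if flip:
                sequences[gid] = _revcomp(sequences[gid])
            truth.orientation[gid] = (
                Direction.REVERSE if flip else Direction.FORWARD,
                evidence,
            )

    # planted duplicates
    redundancy_hits: list[AlignmentHit] = []
    n_dups = round(dup_fraction * n_genes)
    for d in range(n_dups):
        parent = ids[int(rng.integers(0, len(ids)))]
        parent_seq = sequences[parent]
        dup_len = min(len(parent_seq), int(rng.integers(*length_range)))
        copied_len = max(50, round(dup_coverage * dup_len))
        copied_len = min(copied_len, len(parent_seq))
        start = int(rng.integers(0, len(parent_seq) - copied_len + 1))
        segment = list(parent_seq[start : start + copied_len])
        n_mut = round((1.0 - dup_identity / 100.0) * copied_len)
        if n_mut:
            positions = rng.choice(copied_len, size=n_mut, replace=False)
            for pos in positions:
                current = segment[pos]
                choices = [b for b in "ACGT" if b != current]
                segment[pos] = choices[int(rng.integers(0, 3))]
        pad_len = dup_len - copied_len
        pad = _disjoint_random_seq(rng, pad_len, used_kmers) if pad_len >= 18 else (
            _random_seq(rng, pad_len) if pad_len else ""
        )
        dup_id = f"{parent}_dup{d}"
        dup_seq = "".join(segment) + pad
        sequences[dup_id] = dup_seq
        realised_identity = 100.0 * (copied_len - n_mut) / copied_len
        realised_coverage = copied_len / len(dup_seq)
        truth.duplicates.append(
            DuplicateTruth(
                duplicate_id=dup_id,
                parent_id=parent,
                percent_identity=realised_identity,
                query_aligned_fraction=realised_coverage,
            )
        )
        redundancy_hits.append(
            AlignmentHit(
                query_id=dup_id,
                subject_id=parent,
                percent_identity=realised_identity,
                query_aligned_fraction=realised_coverage,
                e_value=1e-30,
                subject_strand=Strand.PLUS,
                bit_score=500.0,
            )
        )

    records = [
        SequenceRecord(id=rid, sequence=seq, source_class=SourceClass.UNIGENE)
        for rid, seq in sequences.items()
    ]
    return UnigeneFixture(
        records=records,
        protein_hits=protein_hits,
        genomic_hits=genomic_hits,
        signal_table=signal_table,
        redundancy_hits=redundancy_hits,
        truth=truth,
    )


def _insert_orf_cassette(
    rng: np.random.Generator, seq: str, params: DesignParams
) -> str | None:
    """Overwrite a stretch of ``seq`` with an unambiguous long ORF.

    The cassette is ATG + stop-free sense codons + TAA, sized to clear
    ``orf_min_codons`` with margin; returns None when the resulting
    sequence does not yield a confident forward ORF vote (caller retries).
    """
    n_codons = max(params.orf_min_codons + 20, 120)
    body = "".join(
        _SENSE_CODONS[int(i)]
        for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)
    )
    cassette = "ATG" + body + "TAA"
    if len(cassette) + 6 > len(seq):
        return None
    pos = int(rng.integers(0, len(seq) - len(cassette) + 1))
    out = seq[:pos] + cassette + seq[pos + len(cassette):]
    rec = SequenceRecord(id="_cassette_check", sequence=out)
    vote = orient_by_longest_orf(rec, params.orf_min_codons, params.orf_margin_ratio)
    if vote.direction is not Direction.FORWARD:
        return None
    return out


# ---------------------------------------------------------------------------
# Expression matrices


def _probe_sets_by_gene(
    design: "ArrayDesign | Mapping[str, int]",
) -> dict[str, list[str]]:
    if isinstance(design, ArrayDesign):
        out: dict[str, list[str]] = {}
        for ps in design.probe_sets:
            out.setdefault(ps.gene_id, []).append(ps.probe_set_id)
        return out
    return {
        gene: [f"{gene}:ps{i}" for i in range(int(k))] for gene, k in design.items()
    }


def make_expression_matrix(
    design: "ArrayDesign | Mapping[str, int]",
    n_reps: int = 3,
    de_fraction: float = 0.0,
    de_log2fc: float = 2.0,
    splice_fraction: float = 0.0,
    splice_ratio: float = 8.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    de_log2fc_by_gene: Mapping[str, float] | None = None,
    splice_ratio_by_probe_set: Mapping[str, float] | None = None,
) -> tuple[ExpressionMatrix, FixtureTruth]:
    """Two-condition (leaf/root) log2 expression matrix with planted effects.

    Gene baselines ~ Normal(8, 2) log2, shared by the gene's probe sets.
    DE genes receive +/- ``de_log2fc`` on every probe set in the leaf
    condition.  A spliced probe set is planted on the *gene-normalised*
    scale: the target probe set is raised by log2(ratio) and its sibling
    probe sets lowered by log2(ratio)/(k-1) in leaf only, so the gene
    mean is unchanged and the gene-normalised contrast equals the
    planted ratio exactly.  I.i.d. Normal(0, noise_sd) noise per cell.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    truth = FixtureTruth(seed=seed)
    by_gene = _probe_sets_by_gene(design)
    if not by_gene:
        raise ValueError("design has no probe sets")
    genes = sorted(by_gene)
    probe_sets = [ps for g in genes for ps in by_gene[g]]
    samples = [f"leaf_{i+1}" for i in range(n_reps)] + [
        f"root_{i+1}" for i in range(n_reps)
    ]
    condition_of = {s: ("leaf" if s.startswith("leaf") else "root") for s in samples}
    leaf_cols = list(range(n_reps))

    baseline = {g: float(rng.normal(8.0, 2.0)) for g in genes}
    values = np.zeros((len(probe_sets), 2 * n_reps))
    row_of = {ps: i for i, ps in enumerate(probe_sets)}
    for g in genes:
        for ps in by_gene[g]:
            values[row_of[ps], :] = baseline[g]

    # planted differential expression (leaf only)
    if de_log2fc_by_gene is not None:
        de_plan = dict(de_log2fc_by_gene)
    else:
        n_de = round(de_fraction * len(genes))
        chosen = list(rng.choice(genes, size=n_de, replace=False)) if n_de else []
        de_plan = {
            g: float(de_log2fc if rng.random() < 0.5 else -de_log2fc) for g in chosen
        }
    for g, lfc in de_plan.items():
        for ps in by_gene[g]:
            values[row_of[ps], leaf_cols] += lfc
        truth.de_log2fc[g] = lfc

    # planted splicing events (leaf only, mean-compensated within the gene)
    if splice_ratio_by_probe_set is not None:
        splice_plan = dict(splice_ratio_by_probe_set)
    else:
        eligible = [g for g in genes if len(by_gene[g]) >= 2 and g not in de_plan]
        n_sp = round(splice_fraction * len(genes))
        chosen = (
            list(rng.choice(eligible, size=min(n_sp, len(eligible)), replace=False))
            if n_sp
            else []
        )
        splice_plan = {}
        for g in chosen:
            sets = by_gene[g]
            target = sets[int(rng.integers(0, len(sets)))]
            splice_plan[target] = splice_ratio
    gene_of_ps = {ps: g for g in genes for ps in by_gene[g]}
    for target, ratio in splice_plan.items():
        g = gene_of_ps[target]
        siblings = [ps for ps in by_gene[g] if ps != target]
        if not siblings:
            raise ValueError(
                f"cannot plant splicing on single-probe-set gene {g!r}"
            )
        x = math.log2(ratio)
        values[row_of[target], leaf_cols] += x
        for sib in siblings:
            values[row_of[sib], leaf_cols] -= x / len(siblings)
        truth.spliced_ratio[target] = ratio

    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_sets, columns=samples),
        condition_of=condition_of,
        gene_of=gene_of_ps,
    )
    return matrix, truth


def make_control_pairs(
    n_genes: int = 17,
    bias_factor: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    tissue: str = "leaf",
) -> list[BiasPair]:
    """Synthetic 5'/3' control-probe pairs with a known 3' bias factor.

    probe5 ~ Normal(8, 1) log2; probe3 = probe5 + log2(bias_factor) +
    Normal(0, noise_sd); the expected linear 3'/5' ratio is bias_factor.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 control genes")
    rng = np.random.default_rng(seed)
    pairs = []
    shift = math.log2(bias_factor)
    for i in range(n_genes):
        p5 = float(rng.normal(8.0, 1.0))
        p3 = p5 + shift + (float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0)
        pairs.append(
            BiasPair(
                control_gene=f"AFFX-ctl-{i:02d}",
                probe5_signal=p5,
                probe3_signal=p3,
                tissue=tissue,
            )
        )
    return pairs
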