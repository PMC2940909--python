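"""Exon-aware 25-mer probe selection.

Each gene that survives filtering is represented by exactly
``probes_per_gene`` (default 15) probes, apportioned among its exons in
proportion to usable exon length and grouped into one probe set per exon.
Candidate windows are screened for sequence quality: no ambiguous bases,
minimum nucleotide entropy, no long homopolymer or dinucleotide repeat,
and no exact (25-mer) or near-exact (shared 18-mer seed) match in any
other gene in the set.  Genes for which no acceptable selection exists
are excluded with a reason code: too_small, low_complexity,
cross_hybridisation, or indistinguishable (every probe shared with one
single other gene, so the probe set cannot tell the two apart).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .exon_map import ExonStructure, uniform_fallback
from .io_model import DesignParams, SequenceRecord, reverse_complement

__all__ = [
    "ExclusionReason",
    "Probe",
    "ProbeSet",
    "ArrayDesign",
    "complexity_ok",
    "build_kmer_index",
    "canonical_kmer",
    "cross_hybridizing",
    "allocate_probe_counts",
    "tile_gene",
    "design_array",
]


class ExclusionReason(str, Enum):
    TOO_SMALL = "too_small"
    CROSS_HYBRIDISATION = "cross_hybridisation"
    LOW_COMPLEXITY = "low_complexity"
    INDISTINGUISHABLE = "indistinguishable"


@dataclass(frozen=True)
class Probe:
    """One oligo probe anchored at a transcript offset within an exon."""

    gene_id: str
    exon_index: int
    start: int  # transcript offset, 0-based
    length: int
    sequence: str
    antisense: bool = True  # probe is revcomp of the sense transcript window

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError("probe sequence length mismatch")
        if "N" in self.sequence:
            raise ValueError("probe contains N")


@dataclass(frozen=True)
class ProbeSet:
    """All probes interrogating one exon of one gene."""

    probe_set_id: str
    gene_id: str
    exon_index: int
    probes: tuple[Probe, ...]

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValueError("probe set must be non-empty")
        starts = [p.start for p in self.probes]
        if starts != sorted(set(starts)):
            raise ValueError("probe starts must be strictly increasing")
        for p in self.probes:
            if p.gene_id != self.gene_id or p.exon_index != self.exon_index:
                raise ValueError("probe does not belong to this probe set")


@dataclass
class ArrayDesign:
    """Result of tiling a record set: probe sets, exclusions, summary."""

    probe_sets: list[ProbeSet] = field(default_factory=list)
    exclusions: list[tuple[str, ExclusionReason]] = field(default_factory=list)

    @property
    def represented_genes(self) -> list[str]:
        return sorted({ps.gene_id for ps in self.probe_sets})

    @property
    def total_probes(self) -> int:
        return sum(len(ps.probes) for ps in self.probe_sets)

    @property
    def total_probe_sets(self) -> int:
        return len(self.probe_sets)

    def summary(self) -> dict[str, int]:
        return {
            "genes_represented": len(self.represented_genes),
            "probe_sets": self.total_probe_sets,
            "probes": self.total_probes,
            "genes_excluded": len(self.exclusions),
        }


# ---------------------------------------------------------------------------
# Quality filters


def complexity_ok(window: str, params: DesignParams | None = None) -> bool:
    """Sequence-complexity screen for one probe-length window.

    Requires mononucleotide Shannon entropy >= complexity_entropy_min
    (default 1.2 bits), longest homopolymer run <= 12, and no perfect
    dinucleotide repeat covering >= 20 of the 25 bases.
    """
    params = params or DesignParams()
    n = len(window)
    entropy = 0.0
    for base in "ACGT":
        c = window.count(base)
        if c:
            p = c / n
            entropy -= p * math.log2(p)
    if entropy < params.complexity_entropy_min:
        return False
    run = best_run = 1
    for a, b in zip(window, window[1:]):
        run = run + 1 if a == b else 1
        best_run = max(best_run, run)
    if best_run > 12:
        return False
    # longest period-2 tandem stretch (positions where s[i] == s[i-2])
    di = best_di = 2
    for i in range(2, n):
        di = di + 1 if window[i] == window[i - 2] else 2
        best_di = max(best_di, di)
    if best_di >= 20:
        return False
    return True


def canonical_kmer(kmer: str) -> str:
    """Strand-canonical form: min(kmer, reverse complement)."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def build_kmer_index(
    records: Iterable[SequenceRecord], k: int
) -> dict[str, set[str]]:
    """Map every canonical k-mer to the set of gene ids containing it
    (either strand, exhaustive over all positions)."""
    index: dict[str, set[str]] = {}
    for rec in records:
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(canonical_kmer(kmer), set()).add(rec.id)
    return index


def cross_hybridizing(
    window: str,
    gene_id: str,
    index25: Mapping[str, set[str]],
    index_seed: Mapping[str, set[str]],
    seed_k: int = 18,
) -> bool:
    """True when the window risks binding another gene's transcript.

    Exact rule: its canonical 25-mer occurs in any other gene.  Seed rule
    (near-exact matches): any contiguous seed_k-mer of the window occurs
    in >= 2 genes other than its own.
    """
    owners = index25.get(canonical_kmer(window), set())
    if owners - {gene_id}:
        return True
    for i in range(len(window) - seed_k + 1):
        owners = index_seed.get(canonical_kmer(window[i : i + seed_k]), set())
        if len(owners - {gene_id}) >= 2:
            return True
    return False


# ---------------------------------------------------------------------------
# Apportionment


def allocate_probe_counts(exons: ExonStructure, n: int, probe_length: int = 25) -> list[int]:
    """Apportion n probes among exons by largest-remainder rounding.

    Weights are usable lengths (candidate offsets per exon,
    max(0, exon_length - probe_length + 1)); an exon with no usable
    length gets 0; remainder ties break toward the earlier exon.  When
    fewer candidate offsets than n exist in total, every exon gets its
    full usable length.
    """
    usable = [max(0, (end - start) - probe_length + 1) for start, end in exons.exons]
    total = sum(usable)
    if total == 0:
        return [0] * len(usable)
    if total <= n:
        return usable
    quotas = [n * u / total for u in usable]
    counts = [math.floor(q) for q in quotas]
    # cap at usable and hand out the remainder by descending fractional part
    counts = [min(c, u) for c, u in zip(counts, usable)]
    short = n - sum(counts)
    order = sorted(
        range(len(usable)), key=lambda i: (-(quotas[i] - math.floor(quotas[i])), i)
    )
    while short > 0:
        progressed = False
        for i in order:
            if short == 0:
                break
            if counts[i] < usable[i]:
                counts[i] += 1
                short -= 1
                progressed = True
        if not progressed:
            break
    return counts


# ---------------------------------------------------------------------------
# Per-gene tiling


def _probe_sequence(window: str, antisense: bool) -> str:
    return reverse_complement(window) if antisense else window


def tile_gene(
    record: SequenceRecord,
    exons: ExonStructure,
    index25: Mapping[str, set[str]],
    index_seed: Mapping[str, set[str]],
    params: DesignParams | None = None,
) -> list[ProbeSet] | ExclusionReason:
    """Select probes for one gene, or return an exclusion reason.

    Evenly spaced target offsets are placed along each exon's usable
    range (one per allocated probe); each target snaps outward to the
    nearest offset whose window passes the N, complexity and
    cross-hybridisation screens (lower offset preferred on ties).  Any
    shortfall is filled from passing candidates elsewhere in the gene,
    nearest-first to the unfilled targets.  Genes that still cannot field
    ``probes_per_gene`` clean probes are excluded (see module docstring
    for the reason-code precedence).
    """
    params = params or DesignParams()
    L = params.probe_length
    n_target = params.probes_per_gene
    seq = record.sequence
    antisense = params.probe_strand == "antisense"

    # candidate offsets per exon: window inside the exon, no N
    exon_of: dict[int, int] = {}
    candidates: list[int] = []
    for ei, (start, end) in enumerate(exons.exons):
        for off in range(start, end - L + 1):
            window = seq[off : off + L]
            if "N" in window:
                continue
            exon_of[off] = ei
            candidates.append(off)
    if len(candidates) < n_target:
        return ExclusionReason.TOO_SMALL

    complexity_pass = [off for off in candidates if complexity_ok(seq[off : off + L], params)]
    if len(complexity_pass) < n_target:
        return ExclusionReason.LOW_COMPLEXITY

    crosshyb = {
        off: cross_hybridizing(
            seq[off : off + L], record.id, index25, index_seed, params.crosshyb_seed_k
        )
        for off in complexity_pass
    }
    clean = [off for off in complexity_pass if not crosshyb[off]]

    counts = allocate_probe_counts(exons, n_target, L)
    # evenly spaced targets within each exon's usable range
    targets: list[int] = []
    for ei, (start, end) in enumerate(exons.exons):
        usable = max(0, (end - start) - L + 1)
        c = counts[ei]
        for i in range(c):
            t = start + min(usable - 1, round((i + 0.5) * usable / c))
            targets.append(t)

    clean_set = set(clean)
    selected: list[int] = []
    selected_set: set[int] = set()
    unfilled: list[int] = []
    for t in targets:
        # snap outward within the target's exon
        t_exon = None
        for ei2, (start, end) in enumerate(exons.exons):
            if start <= t < end:
                t_exon = ei2
                break
        found = None
        for delta in range(0, len(seq)):
            for off in (t - delta, t + delta) if delta else (t,):
                if off in clean_set and off not in selected_set and exon_of.get(off) == t_exon:
                    found = off
                    break
            if found is not None:
                break
        if found is None:
            unfilled.append(t)
        else:
            selected.append(found)
            selected_set.add(found)

    # fill shortfall from clean candidates anywhere, nearest to unfilled targets
    if len(selected) < n_target:
        remaining = [off for off in clean if off not in selected_set]
        pending = list(unfilled) or [t for t in targets]
        remaining.sort(key=lambda off: (min(abs(off - t) for t in pending), off))
        for off in remaining:
            if len(selected) >= n_target:
                break
            selected.append(off)
            selected_set.add(off)

    used_crosshyb = False
    if len(selected) < n_target:
        # last resort: admit cross-hybridising (complexity-passing) windows
        used_crosshyb = True
        remaining = [off for off in complexity_pass if off not in selected_set]
        pending = list(unfilled) or [t for t in targets]
        remaining.sort(key=lambda off: (min(abs(off - t) for t in pending), off))
        for off in remaining:
            if len(selected) >= n_target:
                break
            selected.append(off)
            selected_set.add(off)

    if len(selected) < n_target:
        # complexity_pass >= n_target guarantees we cannot get here, but
        # keep a safe default
        return ExclusionReason.TOO_SMALL

    if used_crosshyb:
        # gene cannot be tiled with unique probes; decide which reason
        competitor_sets = []
        for off in selected:
            window = seq[off : off + L]
            owners = set()
            owners |= index25.get(canonical_kmer(window), set()) - {record.id}
            competitor_sets.append(owners)
        common = set.intersection(*competitor_sets) if competitor_sets else set()
        if common:
            return ExclusionReason.INDISTINGUISHABLE
        return ExclusionReason.CROSS_HYBRIDISATION

    # group into per-exon probe sets
    by_exon: dict[int, list[int]] = {}
    for off in sorted(selected):
        by_exon.setdefault(exon_of[off], []).append(off)
    probe_sets: list[ProbeSet] = []
    for ei in sorted(by_exon):
        probes = tuple(
            Probe(
                gene_id=record.id,
                exon_index=ei,
                start=off,
                length=L,
                sequence=_probe_sequence(seq[off : off + L], antisense),
                antisense=antisense,
            )
            for off in by_exon[ei]
        )
        probe_sets.append(
            ProbeSet(
                probe_set_id=f"{record.id}:ps{ei}",
                gene_id=record.id,
                exon_index=ei,
                probes=probes,
            )
        )
    return probe_sets


def design_array(
    records: Sequence[SequenceRecord],
    exon_structures: Mapping[str, ExonStructure] | None = None,
    params: DesignParams | None = None,
) -> ArrayDesign:
    """Tile every record into an ArrayDesign.

    Builds the 25-mer and seed k-mer indexes once over the whole set,
    tiles each gene (uniform single-exon fallback where no structure is
    provided), and aggregates probe sets and exclusions.  Exceeding the
    array's probe capacity is a hard error.
    """
    params = params or DesignParams()
    exon_structures = exon_structures or {}
    index25 = build_kmer_index(records, params.crosshyb_exact_k)
    index_seed = build_kmer_index(records, params.crosshyb_seed_k)
    design = ArrayDesign()
    for rec in records:
        exons = exon_structures.get(rec.id) or uniform_fallback(rec)
        result = tile_gene(rec, exons, index25, index_seed, params)
        if isinstance(result, ExclusionReason):
            design.exclusions.append((rec.id, result))
        else:
            design.probe_sets.extend(result)
    if design.total_probes > params.max_probes_total:
        raise ValueError(
            f"design exceeds array capacity: {design.total_probes} probes "
            f"> {params.max_probes_total}"
        )
    return design
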