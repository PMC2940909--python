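"""Core domain types and file IO for the exon-array design pipeline.

Sequences travel as :class:`SequenceRecord`, pairwise alignment evidence as
:class:`AlignmentHit`, and tunable thresholds as :class:`DesignParams` /
:class:`AnalysisParams`.  All internal coordinates are 0-based half-open;
everything emitted as GFF3 or block TSV is 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SourceClass",
    "OrientationStatus",
    "OrientationEvidence",
    "Strand",
    "SequenceRecord",
    "AlignmentHit",
    "DesignParams",
    "AnalysisParams",
    "ExpressionMatrix",
    "reverse_complement",
    "read_sequences",
    "write_sequences",
    "parse_alignment_table",
    "write_alignment_table",
    "write_design",
    "read_expression_matrix",
    "write_expression_matrix",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# A/C/G/T plus N; U is normalised to T on read.
_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class SourceClass(str, Enum):
    UNIGENE = "unigene"
    GENE_PREDICTION = "gene_prediction"
    VELVET_CONTIG = "velvet_contig"
    AT_MODEL = "at_model"
    SCAFFOLD_MODEL = "scaffold_model"
    CONTROL = "control"


class OrientationStatus(str, Enum):
    FORWARD = "forward"
    REVERSE_COMPLEMENTED = "reverse_complemented"
    UNORIENTATED = "unorientated"


class OrientationEvidence(str, Enum):
    PROTEIN_HIT = "protein_hit"
    GENOMIC_HIT = "genomic_hit"
    ARRAY_SIGNAL = "array_signal"
    LONGEST_ORF = "longest_orf"
    POLYA_TAIL = "polya_tail"
    NONE = "none"


class Strand(str, Enum):
    PLUS = "plus"
    MINUS = "minus"


@dataclass(frozen=True)
class SequenceRecord:
    """One unigene / gene-model sequence with provenance and orientation state."""

    id: str
    sequence: str
    source_class: SourceClass = SourceClass.UNIGENE
    orientation_status: OrientationStatus = OrientationStatus.FORWARD
    orientation_evidence: OrientationEvidence = OrientationEvidence.NONE
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = next(
            ((i, c) for i, c in enumerate(self.sequence) if c not in _VALID_BASES),
            None,
        )
        if bad is not None:
            raise ValueError(
                f"non-IUPAC character {bad[1]!r} at position {bad[0] + 1} "
                f"in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complemented(self) -> "SequenceRecord":
        return replace(self, sequence=reverse_complement(self.sequence))


@dataclass(frozen=True)
class AlignmentHit:
    """One row of pairwise alignment evidence (BLAST outfmt-6 dialect).

    ``query_frame`` is an optional 13th column used by protein evidence:
    frames -3..-1 indicate the hit lies on the reverse strand of the query.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    query_aligned_fraction: float
    e_value: float
    subject_strand: Strand = Strand.PLUS
    bit_score: float = 0.0
    query_frame: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.e_value) or self.e_value < 0:
            raise ValueError(f"e_value must be finite and >= 0, got {self.e_value}")
        if not 0.0 <= self.query_aligned_fraction <= 1.0:
            raise ValueError(
                f"query_aligned_fraction out of [0,1]: {self.query_aligned_fraction}"
            )


@dataclass
class DesignParams:
    """Thresholds controlling redundancy collapse, orientation and tiling.

    Defaults follow the published array: 15 probes per gene, 25-base probes,
    2.44 M probe capacity, redundancy at >98 % identity over >75 % of the
    query with E < 1e-5, orientation alignments at E < 1e-5, exon-defining
    alignments at E < 1e-15.  The complexity / cross-hybridisation / ORF /
    poly-A parameters are this implementation's transparent stand-ins for a
    vendor-internal probe quality score.
    """

    redundancy_identity_pct: float = 98.0
    redundancy_query_fraction: float = 0.75
    redundancy_evalue: float = 1e-5
    orientation_evalue: float = 1e-5
    exon_evalue: float = 1e-15
    probes_per_gene: int = 15
    probe_length: int = 25
    max_probes_total: int = 2_440_000
    complexity_entropy_min: float = 1.2
    crosshyb_exact_k: int = 25
    crosshyb_seed_k: int = 18
    min_intron_gap: int = 50
    polya_min_run: int = 10
    polya_window: int = 25
    orf_min_codons: int = 100
    orf_margin_ratio: float = 1.5
    probe_strand: str = "antisense"  # probe = revcomp of sense transcript window

    def __post_init__(self) -> None:
        if self.probe_length < 1:
            raise ValueError("probe_length must be >= 1")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        for name in (
            "redundancy_identity_pct",
            "redundancy_query_fraction",
            "redundancy_evalue",
            "orientation_evalue",
            "exon_evalue",
            "complexity_entropy_min",
            "orf_margin_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.probe_strand not in ("antisense", "sense"):
            raise ValueError("probe_strand must be 'antisense' or 'sense'")


@dataclass
class AnalysisParams:
    """Thresholds for the expression-analysis statistics.

    ``prefilter_low``/``prefilter_high`` bound the "not changing" fold-change
    band removed before testing; differential expression requires BH-corrected
    p < ``de_alpha`` and fold change > ``de_fold_change``; a probe set is
    flagged for alternative splicing when its splicing index reaches
    ``splicing_index_min`` (linear ratio scale by default).
    """

    prefilter_low: float = 0.77
    prefilter_high: float = 1.3
    de_alpha: float = 0.01
    de_fold_change: float = 2.0
    splicing_index_min: float = 5.0
    bias_alternative: str = "greater"
    si_scale: str = "linear"

    def __post_init__(self) -> None:
        if self.bias_alternative not in ("greater", "less"):
            raise ValueError("bias_alternative must be 'greater' or 'less'")
        if self.si_scale not in ("linear", "log2"):
            raise ValueError("si_scale must be 'linear' or 'log2'")


@dataclass
class ExpressionMatrix:
    """Probe-set x sample log2 signal matrix with condition and gene maps."""

    values: pd.DataFrame  # rows = probe sets, columns = samples
    condition_of: dict[str, str]  # sample -> condition label
    gene_of: dict[str, str]  # probe set -> gene

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        orphans = [p for p in self.values.index if p not in self.gene_of]
        if orphans:
            raise ValueError(f"probe sets without gene mapping: {orphans[:5]}")

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.condition_of[s] for s in self.values.columns))

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    def gene_level(self) -> pd.DataFrame:
        """Gene-level log2 signal: unweighted mean over a gene's probe sets."""
        genes = pd.Series({p: self.gene_of[p] for p in self.values.index})
        return self.values.groupby(genes).mean()


# ---------------------------------------------------------------------------
# FASTA


def read_sequences(
    path: str | Path,
    source_class: SourceClass = SourceClass.UNIGENE,
) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Lowercase is uppercased, U is mapped to T, the description after the
    first whitespace is kept as free-text metadata.  Duplicate ids, empty
    sequences and non-IUPAC characters are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate id {entry.id}")
        seen.add(entry.id)
        seq = str(entry.seq).upper().replace("U", "T")
        desc = entry.description[len(entry.id):].strip()
        records.append(
            SequenceRecord(
                id=entry.id,
                sequence=seq,
                source_class=source_class,
                description=desc,
            )
        )
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# BLAST-style tabular alignments
#
# Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
# send evalue bitscore [qframe]


def parse_alignment_table(
    path: str | Path, query_lengths: Mapping[str, int]
) -> list[AlignmentHit]:
    """Parse a 12/13-column tab-separated alignment table.

    query_aligned_fraction = (|qend - qstart| + 1) / query length; the
    subject strand is minus when send < sstart; self hits are dropped.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (12, 13):
                raise ValueError(
                    f"malformed row at line {lineno}: expected 12 or 13 columns, "
                    f"got {len(cols)}"
                )
            try:
                qseqid, sseqid = cols[0], cols[1]
                pident = float(cols[2])
                qstart, qend = int(cols[6]), int(cols[7])
                sstart, send = int(cols[8]), int(cols[9])
                evalue = float(cols[10])
                bitscore = float(cols[11])
                qframe = int(cols[12]) if len(cols) == 13 else None
            except ValueError as exc:
                raise ValueError(f"malformed row at line {lineno}: {exc}") from None
            if qseqid == sseqid:
                continue  # self hit
            if qseqid not in query_lengths:
                raise ValueError(f"unknown qseqid {qseqid!r} at line {lineno}")
            fraction = (abs(qend - qstart) + 1) / query_lengths[qseqid]
            strand = Strand.MINUS if send < sstart else Strand.PLUS
            hits.append(
                AlignmentHit(
                    query_id=qseqid,
                    subject_id=sseqid,
                    percent_identity=pident,
                    query_aligned_fraction=fraction,
                    e_value=evalue,
                    subject_strand=strand,
                    bit_score=bitscore,
                    query_frame=qframe,
                )
            )
    return hits


def write_alignment_table(
    hits: Iterable[AlignmentHit],
    query_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write hits back to the 12/13-column tabular dialect (round-trippable)."""
    with open(path, "w", newline="\n") as fh:
        for h in hits:
            qlen = query_lengths[h.query_id]
            span = max(1, round(h.query_aligned_fraction * qlen))
            qstart, qend = 1, span
            if h.subject_strand is Strand.MINUS:
                sstart, send = span, 1
            else:
                sstart, send = 1, span
            cols = [
                h.query_id,
                h.subject_id,
                f"{h.percent_identity:g}",
                str(span),
                "0",
                "0",
                str(qstart),
                str(qend),
                str(sstart),
                str(send),
                f"{h.e_value:g}",
                f"{h.bit_score:g}",
            ]
            if h.query_frame is not None:
                cols.append(str(h.query_frame))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Design output


def write_design(design, out_dir: str | Path) -> dict[str, Path]:
    """Write an ArrayDesign as four plain-text files.

    probes.fa        probe oligos, id = geneid:probesetindex:probeindex
    probe_sets.tsv   probe_set_id, gene_id, exon_index, n_probes
    probes.gff3      probe intervals on each transcript (1-based inclusive)
    exclusions.tsv   gene_id, reason

    Output is byte-stable for identical input.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes_fasta": out / "probes.fa",
        "probe_sets": out / "probe_sets.tsv",
        "gff3": out / "probes.gff3",
        "exclusions": out / "exclusions.tsv",
    }

    with open(paths["probes_fasta"], "w", newline="\n") as fa, open(
        paths["gff3"], "w", newline="\n"
    ) as gff, open(paths["probe_sets"], "w", newline="\n") as ps:
        gff.write("##gff-version 3\n")
        ps.write("probe_set_id\tgene_id\texon_index\tn_probes\n")
        sets_by_gene: dict[str, list] = {}
        for pset in design.probe_sets:
            sets_by_gene.setdefault(pset.gene_id, []).append(pset)
        for gene_id in sorted(sets_by_gene):
            for set_index, pset in enumerate(sets_by_gene[gene_id]):
                ps.write(
                    f"{pset.probe_set_id}\t{gene_id}\t{pset.exon_index}\t"
                    f"{len(pset.probes)}\n"
                )
                for probe_index, probe in enumerate(pset.probes):
                    pid = f"{gene_id}:{set_index}:{probe_index}"
                    fa.write(f">{pid}\n{probe.sequence}\n")
                    strand = "-" if probe.antisense else "+"
                    gff.write(
                        f"{gene_id}\texontile\tprobe\t{probe.start + 1}\t"
                        f"{probe.start + probe.length}\t.\t{strand}\t.\t"
                        f"ID={pid};probe_set={pset.probe_set_id}\n"
                    )

    with open(paths["exclusions"], "w", newline="\n") as ex:
        ex.write("gene_id\treason\n")
        for gene_id, reason in sorted(design.exclusions):
            ex.write(f"{gene_id}\t{reason.value}\n")
    return paths


# ---------------------------------------------------------------------------
# Expression matrices (TSV: header row of sample ids, first column probe_set_id)


def read_expression_matrix(
    matrix_path: str | Path,
    condition_path: str | Path,
    gene_map_path: str | Path,
) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    cond = pd.read_csv(condition_path, sep="\t")
    genes = pd.read_csv(gene_map_path, sep="\t")
    condition_of = dict(zip(cond.iloc[:, 0].astype(str), cond.iloc[:, 1].astype(str)))
    gene_of = dict(zip(genes.iloc[:, 0].astype(str), genes.iloc[:, 1].astype(str)))
    return ExpressionMatrix(values=values, condition_of=condition_of, gene_of=gene_of)


def write_expression_matrix(matrix: ExpressionMatrix, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "conditions": out / "conditions.tsv",
        "genes": out / "gene_map.tsv",
    }
    matrix.values.to_csv(paths["matrix"], sep="\t", index_label="probe_set_id")
    pd.DataFrame(
        {"sample": list(matrix.values.columns),
         "condition": [matrix.condition_of[s] for s in matrix.values.columns]}
    ).to_csv(paths["conditions"], sep="\t", index=False)
    pd.DataFrame(
        {"probe_set": list(matrix.values.index),
         "gene": [matrix.gene_of[p] for p in matrix.values.index]}
    ).to_csv(paths["genes"], sep="\t", index=False)
    return paths
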