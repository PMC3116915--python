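"""Genome records, gene features, and extragenic space.

Coordinates are 0-based, half-open throughout the package; positions are
converted to 1-based only when formatting human-readable reports. Circular
genomes are treated as linear (no origin-spanning windows).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "GenomeRecord",
    "ExtragenicSpace",
    "read_genome",
    "extragenic_space",
    "reverse_complement",
    "write_genome",
    "write_bed",
]

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)

DNA_ALPHABET = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement.

    IUPAC ambiguity codes are complemented; any other character raises
    ``ValueError``.
    """
    s = seq.upper()
    out = s.translate(_COMPLEMENT)[::-1]
    if len(out) != len(s) or not set(s) <= _IUPAC:
        bad = sorted(set(s) - _IUPAC)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return out


_IUPAC = frozenset("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene-class feature on the forward coordinate system."""

    start: int
    end: int
    strand: str = "+"
    kind: str = "gene"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid feature interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class GenomeRecord:
    """A named DNA sequence with gene-feature annotations."""

    id: str
    sequence: str
    circular: bool = False
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError("empty genome sequence")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature [{f.start}, {f.end}) outside genome of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ExtragenicSpace:
    """Sorted, disjoint non-coding intervals of one genome."""

    intervals: list[tuple[int, int]]
    source_genome: str = ""

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, start: int, end: int) -> bool:
        """True iff [start, end) lies wholly within one extragenic interval."""
        import bisect

        i = bisect.bisect_right(self._starts(), start) - 1
        if i < 0:
            return False
        s, e = self.intervals[i]
        return s <= start and end <= e

    def _starts(self) -> list[int]:
        if not hasattr(self, "_starts_cache") or len(self._starts_cache) != len(self.intervals):
            self._starts_cache = [s for s, _ in self.intervals]
        return self._starts_cache


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def extragenic_space(
    genome: GenomeRecord, feature_kinds: Sequence[str] | None = None
) -> ExtragenicSpace:
    """Complement of the union of gene-class features.

    ``feature_kinds`` selects which feature classes count as "genic"; by
    default ``gene`` features are used if any are annotated, else ``CDS``.
    A genome with no features yields a single interval covering it.
    """
    if feature_kinds is None:
        kinds = {f.kind for f in genome.features}
        feature_kinds = ("gene",) if "gene" in kinds else ("CDS",)
    genic = _merge_intervals(
        (f.start, f.end) for f in genome.features if f.kind in feature_kinds
    )
    out: list[tuple[int, int]] = []
    prev = 0
    for s, e in genic:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < len(genome):
        out.append((prev, len(genome)))
    return ExtragenicSpace(intervals=out, source_genome=genome.id)


def _features_from_gff3(path: str, seq_ids: set[str]) -> dict[str, list[GeneFeature]]:
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: dict[str, list[GeneFeature]] = {sid: [] for sid in seq_ids}
    seen_ids = set()
    for f in db.all_features():
        seen_ids.add(f.seqid)
        if f.seqid not in out:
            continue
        if f.featuretype not in ("gene", "CDS"):
            continue
        out[f.seqid].append(
            GeneFeature(
                start=f.start - 1,  # GFF3 is 1-based inclusive
                end=f.end,
                strand=f.strand if f.strand in ("+", "-") else "+",
                kind=f.featuretype,
            )
        )
    if seen_ids and not (seen_ids & seq_ids):
        raise ValueError(
            f"annotation sequence ids {sorted(seen_ids)} do not match FASTA ids"
        )
    return out


def _features_from_genbank(path: str) -> dict[str, tuple[str, list[GeneFeature]]]:
    out = {}
    for rec in SeqIO.parse(path, "genbank"):
        feats = []
        for f in rec.features:
            if f.type not in ("gene", "CDS"):
                continue
            feats.append(
                GeneFeature(
                    start=int(f.location.start),
                    end=int(f.location.end),
                    strand="+" if f.location.strand != -1 else "-",
                    kind=f.type,
                )
            )
        out[rec.id] = (str(rec.seq).upper(), feats)
    return out


def read_genome(
    fasta_path: str | None = None, annotation_path: str | None = None
) -> GenomeRecord | list[GenomeRecord]:
    """Read a genome (FASTA) plus optional annotation (GFF3 or GenBank).

    A GenBank file may be given as the sole argument (sequence and features
    both come from it). A multi-record FASTA yields a list of records.
    """
    if fasta_path is None and annotation_path is None:
        raise ValueError("at least one input path is required")
    if fasta_path is None:
        fasta_path = annotation_path
        annotation_path = None
    if not os.path.exists(fasta_path):
        raise FileNotFoundError(fasta_path)
    if annotation_path is not None and not os.path.exists(annotation_path):
        raise FileNotFoundError(annotation_path)

    if fasta_path.endswith((".gb", ".gbk", ".gbff", ".genbank")):
        recs = [
            GenomeRecord(id=rid, sequence=seq, features=feats)
            for rid, (seq, feats) in _features_from_genbank(fasta_path).items()
        ]
    else:
        seqs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(fasta_path, "fasta")]
        if not seqs:
            raise ValueError(f"no FASTA records in {fasta_path}")
        feats: dict[str, list[GeneFeature]] = {rid: [] for rid, _ in seqs}
        if annotation_path is not None:
            if annotation_path.endswith((".gb", ".gbk", ".gbff", ".genbank")):
                gb = _features_from_genbank(annotation_path)
                for rid in feats:
                    if rid in gb:
                        feats[rid] = gb[rid][1]
            else:
                feats = _features_from_gff3(annotation_path, set(feats))
        recs = [GenomeRecord(id=rid, sequence=s, features=feats[rid]) for rid, s in seqs]
    return recs[0] if len(recs) == 1 else recs


def write_genome(genome: GenomeRecord, fasta_path: str, gff3_path: str | None = None) -> None:
    """Write a genome as FASTA and, optionally, its features as GFF3."""
    SeqIO.write(
        SeqRecord(Seq(genome.sequence), id=genome.id, description=""),
        fasta_path,
        "fasta",
    )
    if gff3_path is not None:
        with open(gff3_path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
            for i, f in enumerate(genome.features):
                fh.write(
                    f"{genome.id}\trepinscan\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\tID={f.kind}{i + 1}\n"
                )


def write_bed(space: ExtragenicSpace, path: str) -> None:
    """Write extragenic intervals as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for s, e in space.intervals:
            fh.write(f"{space.source_genome}\t{s}\t{e}\n")
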