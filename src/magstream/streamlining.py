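"""Per-genome streamlining traits and clade-level summaries.

Genome streamlining in oligotrophic marine bacteria manifests as a coherent
set of genomic traits: a small (completeness-corrected) genome, low %G+C,
high coding density, an elevated proteome carbon-to-nitrogen ratio and few
or no gene duplication events.  This module computes the first three traits
directly from assemblies and CDS coordinates and aggregates any trait into
clade means with normal-approximation 95% confidence intervals; the C:N
ratio and duplication counts come from :mod:`magstream.proteome` and
:mod:`magstream.paralogs`.

Coordinates are 1-based inclusive (GFF3 convention).  Coding density is a
genomic-space fraction: overlapping CDS intervals are merged across strands
before measuring covered bases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import InputError

CLADES = ("hydrothermal", "organic_carbon", "marine_I", "marine_II", "other")

_UNAMBIGUOUS = frozenset("ACGTacgt")
_GC = frozenset("GCgc")


@dataclass
class GenomeRecord:
    """One metagenome-assembled genome with its quality estimates.

    ``completeness`` and ``contamination`` are CheckM-style percentages;
    completeness may exceed 100 (it is used as given, with a warning at the
    point of use).  ``clade`` is a free label, conventionally one of
    :data:`CLADES`.
    """

    genome_id: str
    contigs: list[tuple[str, str]]
    completeness: float
    contamination: float
    clade: str = "other"

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            raise InputError(f"duplicate contig ids in genome {self.genome_id!r}")
        if self.completeness <= 0:
            raise InputError(
                f"genome {self.genome_id!r}: completeness must be > 0, "
                f"got {self.completeness}"
            )
        if self.contamination < 0:
            raise InputError(
                f"genome {self.genome_id!r}: contamination must be >= 0"
            )

    @property
    def assembly_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def contig_lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs}


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature, 1-based inclusive on its contig."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise InputError(
                f"CDS {self.genome_id}/{self.contig_id}:{self.start}-{self.end}: "
                "require 1 <= start <= end"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class StreamliningProfile:
    """The five streamlining traits of one genome."""

    genome_id: str
    gc_percent: float
    coding_density_percent: float
    estimated_genome_size: float  # Mbp
    proteome_cn_ratio: float | None = None
    duplication_events: int | None = None
    clade: str = "other"


@dataclass(frozen=True)
class CladeSummary:
    """Mean / sd / 95% CI half-width of one metric over one clade."""

    clade: str
    metric: str
    n: int
    mean: float
    sd: float
    ci95_half_width: float


def gc_content(contigs: str | Iterable[str]) -> float:
    """Percent G+C over unambiguous bases, case-insensitive.

    Ambiguity codes (including N) are excluded from both numerator and
    denominator.  Accepts a single sequence or an iterable of sequences.
    """
    if isinstance(contigs, str):
        contigs = [contigs]
    gc = total = 0
    for seq in contigs:
        for ch in seq:
            if ch in _UNAMBIGUOUS:
                total += 1
                if ch in _GC:
                    gc += 1
    if total == 0:
        raise InputError("no countable bases (sequence empty or all ambiguous)")
    return 100.0 * gc / total


def coding_density(genome: GenomeRecord, cds: Sequence[CdsFeature]) -> float:
    """Percent of the assembly covered by the union of CDS intervals.

    Strands are merged; overlapping features are never counted twice.
    """
    lengths = genome.contig_lengths()
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for f in cds:
        if f.contig_id not in lengths:
            raise InputError(
                f"CDS {f.contig_id}:{f.start}-{f.end} references a contig "
                f"absent from genome {genome.genome_id!r}"
            )
        if f.end > lengths[f.contig_id]:
            raise InputError(
                f"CDS {f.contig_id}:{f.start}-{f.end} extends beyond contig "
                f"length {lengths[f.contig_id]}"
            )
        by_contig.setdefault(f.contig_id, []).append((f.start, f.end))
    covered = 0
    for intervals in by_contig.values():
        intervals.sort()
        cur_s, cur_e = intervals[0]
        for s, e in intervals[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        covered += cur_e - cur_s + 1
    length = genome.assembly_length
    if length == 0:
        raise InputError(f"genome {genome.genome_id!r} has zero length")
    return 100.0 * covered / length


def estimated_genome_size(assembly_length: int, completeness: float) -> float:
    """Completeness-corrected genome size in Mbp.

    ``assembly_length / (completeness/100) / 1e6``.  Completeness above 100
    (possible from marker-based estimators) shrinks the estimate; it is used
    as given with a warning rather than capped, so clade means are not
    silently biased.
    """
    if completeness <= 0:
        raise InputError(f"completeness must be > 0, got {completeness}")
    if completeness > 100:
        warnings.warn(
            f"completeness {completeness} > 100%; estimate will be smaller "
            "than the assembly",
            stacklevel=2,
        )
    return assembly_length / (completeness / 100.0) / 1e6


def summarize_clade(
    values: Sequence[float], clade: str, metric: str
) -> CladeSummary:
    """Sample mean, sd (n-1 denominator) and 1.96*sd/sqrt(n) CI half-width."""
    n = len(values)
    if n == 0:
        raise InputError(f"no values to summarize for {clade}/{metric}")
    mean = sum(values) / n
    if n == 1:
        sd = 0.0
    else:
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return CladeSummary(
        clade=clade,
        metric=metric,
        n=n,
        mean=mean,
        sd=sd,
        ci95_half_width=1.96 * sd / math.sqrt(n),
    )


def build_profile(
    genome: GenomeRecord,
    cds: Sequence[CdsFeature],
    proteome_cn_ratio: float | None = None,
    duplication_events: int | None = None,
) -> StreamliningProfile:
    """Assemble the streamlining trait vector for one genome."""
    return StreamliningProfile(
        genome_id=genome.genome_id,
        gc_percent=gc_content(seq for _, seq in genome.contigs),
        coding_density_percent=coding_density(genome, cds),
        estimated_genome_size=estimated_genome_size(
            genome.assembly_length, genome.completeness
        ),
        proteome_cn_ratio=proteome_cn_ratio,
        duplication_events=duplication_events,
        clade=genome.clade,
    )


def summarize_profiles(
    profiles: Sequence[StreamliningProfile],
    metrics: Sequence[str] = (
        "gc_percent",
        "coding_density_percent",
        "estimated_genome_size",
        "proteome_cn_ratio",
        "duplication_events",
    ),
) -> list[CladeSummary]:
    """Clade-by-metric summaries over a set of profiles (None values skipped)."""
    out: list[CladeSummary] = []
    clades = sorted({p.clade for p in profiles})
    for clade in clades:
        members = [p for p in profiles if p.clade == clade]
        for metric in metrics:
            vals = [
                float(v)
                for p in members
                if (v := getattr(p, metric)) is not None
            ]
            if vals:
                out.append(summarize_clade(vals, clade, metric))
    return out
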