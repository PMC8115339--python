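"""Readers and writers for the tabular and sequence formats the pipeline
consumes: FASTA (Biopython), GFF3 / 4-column CDS tables, CheckM-style
quality tables, BLAST outfmt-6 hit tables, count/sample/ANI TSVs and wide
environmental CSVs."""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ecology import AniPair, GenomeQuality
from .errors import InputError
from .paralogs import PairwiseHit
from .streamlining import CdsFeature, CladeSummary, GenomeRecord, StreamliningProfile

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path: str) -> dict[str, str]:
    try:
        records = {r.id: str(r.seq) for r in SeqIO.parse(path, "fasta")}
    except (ValueError, FileNotFoundError) as exc:
        raise InputError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise InputError(f"FASTA {path} contains no records")
    return records


def write_fasta(path: str, sequences: Mapping[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="")
         for name, seq in sequences.items()),
        path, "fasta",
    )


def read_cds_gff3(path: str, genome_id: str) -> list[CdsFeature]:
    """CDS rows of a GFF3 file (other feature types ignored)."""
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise InputError(f"{path}:{lineno}: not a GFF3 row")
            if parts[2] != "CDS":
                continue
            features.append(CdsFeature(
                genome_id=genome_id, contig_id=parts[0],
                start=int(parts[3]), end=int(parts[4]), strand=parts[6],
            ))
    return features


def write_cds_gff3(path: str, cds: Sequence[CdsFeature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(cds, key=lambda x: (x.contig_id, x.start)):
            fh.write(
                f"{f.contig_id}\tmagstream\tCDS\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t0\tID={f.genome_id}_{f.contig_id}_{f.start}\n"
            )


def read_cds_tsv(path: str, genome_id: str) -> list[CdsFeature]:
    """4-column CDS table: contig, start, end, strand."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig_id", "start", "end", "strand"])
    return [
        CdsFeature(genome_id, r.contig_id, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]


def read_quality_table(path: str) -> pd.DataFrame:
    """TSV with header genome_id, completeness, contamination, clade
    (extra columns such as assembly_length pass through)."""
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "completeness", "contamination"}
    if not required <= set(df.columns):
        raise InputError(
            f"{path}: quality table must have columns {sorted(required)}"
        )
    return df.set_index("genome_id")


def read_blast_tab(path: str) -> list[PairwiseHit]:
    """BLAST/DIAMOND tabular hits (outfmt-6 column order)."""
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    return [
        PairwiseHit(str(r.qseqid), str(r.sseqid), float(r.bitscore),
                    float(r.evalue))
        for r in df.itertuples(index=False)
    ]


def write_blast_tab(path: str, hits: Iterable[PairwiseHit]) -> None:
    """Hits from the built-in scorer as outfmt-6 rows (alignment-detail
    columns not computed by the scorer are written as 0)."""
    with open(path, "w") as fh:
        for h in hits:
            ev = h.evalue if h.evalue is not None else 0.0
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{ev:g}\t{h.bitscore:.1f}\n"
            )


def read_counts_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"genome_id", "sample_id", "reads"} <= set(df.columns):
        raise InputError(f"{path}: need columns genome_id, sample_id, reads")
    return df


def read_sample_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "station", "depth", "total_reads", "total_bp"}
    if not need <= set(df.columns):
        raise InputError(f"{path}: need columns {sorted(need)}")
    return df.set_index("sample_id")


def read_env_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"station", "depth"} <= set(df.columns):
        raise InputError(f"{path}: env table needs station and depth columns")
    return df


def read_ani_tsv(path: str) -> list[AniPair]:
    """Directional ANI rows (query, ref, ani); the two directions of a pair
    are merged into one :class:`AniPair`."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["query", "ref", "ani"], usecols=[0, 1, 2])
    directional: dict[tuple[str, str], float] = {}
    for r in df.itertuples(index=False):
        if r.query == r.ref:
            continue
        directional[(str(r.query), str(r.ref))] = float(r.ani)
    pairs, seen = [], set()
    for (a, b), ani in sorted(directional.items()):
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(AniPair(a, b, ani, directional.get((b, a))))
    return pairs


def quality_from_genomes(genomes: Sequence[GenomeRecord]) -> dict[str, GenomeQuality]:
    return {
        g.genome_id: GenomeQuality(
            g.completeness, g.contamination, g.assembly_length
        )
        for g in genomes
    }


def write_profiles_tsv(path: str, profiles: Sequence[StreamliningProfile]) -> None:
    pd.DataFrame([vars(p) for p in profiles]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_clade_summaries_tsv(path: str, summaries: Sequence[CladeSummary]) -> None:
    pd.DataFrame([vars(s) for s in summaries]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
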