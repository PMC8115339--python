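"""Synthetic MAG collections with the statistical structure the analysis
assumes.

The generator emulates the contrasts a streamlining analysis exploits:

* clades of genomes with contrasting GC, coding density, genome size,
  proteome composition and paralog content — streamlined marine-type
  clades (small, AT-rich, dense, no duplications, nitrogen-poor proteome)
  versus organic-carbon/hydrothermal-type clades (the converse);
* completeness simulated by truncating contigs to a drawn fraction, so
  ``assembly_length / completeness`` recovers the true genome size exactly
  and size-estimation tests are sharp;
* protein families with known duplication counts, scored into self- and
  cross-hits by the built-in aligner;
* a two-clade depth-partitioned niche with depth-correlated environmental
  gradients, read counts drawn from a multinomial per sample;
* rhodopsin sequences built on the synthetic reference scaffold with known
  residues at the diagnostic sites.

Not emulated: realistic sequence evolution, codon structure linking
nucleotide and protein composition, read-level sequencing error, assembly
artifacts.  All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawns, so outputs are deterministic and
platform-independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import SYNTHETIC_PR_REFERENCE, TUNING_SITE
from .errors import InputError
from .paralogs import PairwiseHit, self_and_cross_hits
from .streamlining import CdsFeature, GenomeRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
_N_RICH = frozenset("RKHNQW")  # nitrogen-rich side chains
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CladeSpec:
    """Target genomic traits for one synthetic clade."""

    clade: str
    n_genomes: int
    true_genome_size: int          # bp, before completeness truncation
    gc_target: float               # percent
    coding_density_target: float   # percent
    n_paralog_families: int
    paralog_copies: int = 3
    paralog_identity: float = 95.0  # percent within-family identity
    completeness_range: tuple[float, float] = (50.0, 100.0)
    cn_bias: str = "low_N"          # low_N (streamlined) or high_N
    n_contigs: int = 5
    n_singleton_proteins: int = 25
    protein_length: int = 100

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise InputError("n_genomes must be >= 1")
        if not 0 < self.gc_target < 100:
            raise InputError("gc_target must be in (0, 100)")
        if not 0 < self.coding_density_target <= 100:
            raise InputError("coding_density_target must be in (0, 100]")
        if self.cn_bias not in ("low_N", "high_N"):
            raise InputError(f"unknown cn_bias {self.cn_bias!r}")
        lo, hi = self.completeness_range
        if not 0 < lo <= hi <= 100:
            raise InputError("completeness_range must satisfy 0 < lo <= hi <= 100")
        # rough feasibility: CDS laid at the density target must fit
        if self.true_genome_size < self.n_contigs * 2000:
            raise InputError("true_genome_size too small for the contig count")


@dataclass
class NicheSpec:
    """Depth-partitioned two-clade niche with environmental gradients.

    ``env_gradients`` maps a parameter name to (intercept, slope_per_m,
    noise_sd); values follow ``intercept + slope*depth + N(0, sd)``.
    """

    boundary_depth: float = 100.0
    clade_above: str = "marine_I"
    clade_below: str = "marine_II"
    n_stations: int = 6
    depths: tuple[float, ...] = (
        20.0, 40.0, 60.0, 80.0, 120.0, 150.0, 200.0, 250.0,
    )
    dominance: float = 0.9          # asymptotic share of clade reads on its own side
    transition_width_m: float = 12.0  # logistic width of the niche boundary
    sample_total_reads: int = 1_000_000
    recruited_fraction: float = 0.02
    read_length: int = 100          # bp, sets sample_total_bp
    duplicate_cast_prob: float = 0.3
    env_gradients: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "depth_m": (0.0, 1.0, 0.0),
            "temperature_C": (25.0, -0.05, 2.0),
            "nitrate_uM": (0.5, 0.08, 2.0),
            "oxygen_uM": (250.0, -0.3, 15.0),
        }
    )
    patchy_param: str | None = "chlorophyll_ug_L"
    patchy_coverage: float = 0.5

    def __post_init__(self) -> None:
        if not min(self.depths) <= self.boundary_depth <= max(self.depths):
            raise InputError("boundary_depth outside the sampled depth range")
        if not 0.5 < self.dominance <= 1:
            raise InputError("dominance must be in (0.5, 1]")


@dataclass
class GenomeBundle:
    """Everything generated for one clade."""

    genomes: list[GenomeRecord]
    cds: dict[str, list[CdsFeature]]
    proteins: dict[str, dict[str, str]]
    hits: dict[str, list[PairwiseHit]]
    truth: dict[str, dict]


def default_clade_specs() -> list[CladeSpec]:
    """The default study conditions: two streamlined marine pelagic clades
    (~1.22 Mbp, 30% GC, ~96.5% coding density, no paralog families,
    nitrogen-poor proteomes) contrasted with larger, GC-rich, paralog-
    bearing organic-carbon and hydrothermal clades."""
    return [
        CladeSpec("marine_I", 8, 1_220_000, 30.0, 96.5, 0, cn_bias="low_N"),
        CladeSpec("marine_II", 8, 1_220_000, 30.0, 96.5, 0, cn_bias="low_N"),
        CladeSpec(
            "organic_carbon", 6, 3_000_000, 55.0, 88.0, 5,
            paralog_copies=3, cn_bias="high_N",
        ),
        CladeSpec(
            "hydrothermal", 6, 2_500_000, 45.0, 90.0, 3,
            paralog_copies=3, cn_bias="high_N",
        ),
    ]


def aa_frequencies(cn_bias: str) -> np.ndarray:
    """Residue sampling weights over :data:`AA` for a composition bias.

    ``low_N`` down-weights nitrogen-rich side chains (streamlined,
    nitrogen-limited proteome, higher C:N); ``high_N`` up-weights them.
    """
    w = np.ones(len(AA))
    for i, aa in enumerate(AA):
        if aa in _N_RICH:
            w[i] = 0.35 if cn_bias == "low_N" else 2.2
    return w / w.sum()


def _random_protein(rng: np.random.Generator, length: int, freqs: np.ndarray) -> str:
    return "".join(np.array(list(AA))[rng.choice(len(AA), size=length, p=freqs)])


def _mutate(rng: np.random.Generator, seq: str, identity: float,
            freqs: np.ndarray) -> str:
    out = list(seq)
    p = 1 - identity / 100.0
    for i in range(len(out)):
        if rng.random() < p:
            out[i] = AA[rng.choice(len(AA), p=freqs)]
    return "".join(out)


def generate_paralog_proteome(
    n_families: int,
    copies: int,
    n_singletons: int,
    identity: float = 95.0,
    length: int = 100,
    seed: int | np.random.Generator = 0,
    cn_bias: str = "high_N",
    prefix: str = "p",
) -> tuple[dict[str, str], list[set[str]], list[PairwiseHit]]:
    """A proteome with planted paralog families plus singletons, scored into
    self- and within-family cross-hits (plus a few decoy cross pairs)."""
    rng = seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed)
    )
    freqs = aa_frequencies(cn_bias)
    proteins: dict[str, str] = {}
    families: list[set[str]] = []
    pairs: list[tuple[str, str]] = []
    for f in range(n_families):
        seed_seq = _random_protein(rng, length, freqs)
        members = set()
        for k in range(copies):
            pid = f"{prefix}_fam{f}_{k}"
            proteins[pid] = _mutate(rng, seed_seq, identity, freqs)
            members.add(pid)
        families.append(members)
        ms = sorted(members)
        pairs.extend((ms[i], ms[j]) for i in range(len(ms))
                     for j in range(i + 1, len(ms)))
    singles = []
    for s in range(n_singletons):
        pid = f"{prefix}_sgl{s}"
        proteins[pid] = _random_protein(rng, length, freqs)
        singles.append(pid)
    # decoy unrelated pairs exercise the minbit retention filter
    for _ in range(min(5, len(singles) // 2)):
        a, b = rng.choice(len(singles), size=2, replace=False)
        pairs.append((singles[a], singles[b]))
    return proteins, families, self_and_cross_hits(proteins, pairs)


def _random_genome_sequence(
    rng: np.random.Generator, length: int, gc_percent: float
) -> str:
    g = gc_percent / 100.0
    p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    codes = _BASES[rng.choice(4, size=length, p=p)]
    return codes.tobytes().decode("ascii")


def _lay_cds(
    rng: np.random.Generator, genome_id: str, contig_id: str,
    contig_len: int, density: float,
) -> list[CdsFeature]:
    features = []
    d = density / 100.0
    pos = 1 + int(rng.integers(10, 60))
    while True:
        gene = int(rng.integers(600, 1200))
        if pos + gene - 1 > contig_len:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(CdsFeature(genome_id, contig_id, pos, pos + gene - 1, strand))
        mean_gap = gene * (1 - d) / d
        gap = max(1, int(rng.uniform(0.5, 1.5) * mean_gap)) if mean_gap > 1 else 1
        pos += gene + gap
    return features


def generate_genomes(spec: CladeSpec, seed: int = 0) -> GenomeBundle:
    """Genomes, CDS, proteomes and alignment hits for one clade.

    Completeness is simulated by truncating the full genome to a fraction
    drawn from ``completeness_range``: contigs are kept in order and the
    last retained contig is cut, CDS not fully inside the retained part
    are dropped, and the reported completeness is the exact retained
    fraction.
    """
    bundle = GenomeBundle([], {}, {}, {}, {})
    for i in range(spec.n_genomes):
        clade_tag = zlib.crc32(spec.clade.encode()) % (2**31)
        rng = np.random.default_rng(np.random.SeedSequence([seed, clade_tag, i]))
        gid = f"{spec.clade}_{i:02d}"
        # full genome, then truncate
        base = spec.true_genome_size // spec.n_contigs
        lengths = [base] * (spec.n_contigs - 1)
        lengths.append(spec.true_genome_size - sum(lengths))
        contigs_full = []
        cds_full: list[CdsFeature] = []
        for ci, clen in enumerate(lengths):
            cid = f"{gid}_c{ci}"
            contigs_full.append((cid, _random_genome_sequence(rng, clen, spec.gc_target)))
            cds_full.extend(
                _lay_cds(rng, gid, cid, clen, spec.coding_density_target)
            )
        frac = rng.uniform(*spec.completeness_range) / 100.0
        keep = int(round(spec.true_genome_size * frac))
        contigs, kept_len = [], 0
        for cid, seq in contigs_full:
            if kept_len + len(seq) <= keep:
                contigs.append((cid, seq))
                kept_len += len(seq)
            else:
                cut = keep - kept_len
                if cut > 0:
                    contigs.append((cid, seq[:cut]))
                    kept_len += cut
                break
        completeness = 100.0 * kept_len / spec.true_genome_size
        retained = {cid: len(seq) for cid, seq in contigs}
        cds = [
            f for f in cds_full
            if f.contig_id in retained and f.end <= retained[f.contig_id]
        ]
        genome = GenomeRecord(
            genome_id=gid,
            contigs=contigs,
            completeness=completeness,
            contamination=float(np.round(rng.uniform(0.0, 4.0), 2)),
            clade=spec.clade,
        )
        proteins, families, hits = generate_paralog_proteome(
            spec.n_paralog_families,
            spec.paralog_copies,
            spec.n_singleton_proteins,
            identity=spec.paralog_identity,
            length=spec.protein_length,
            seed=rng,
            cn_bias=spec.cn_bias,
            prefix=gid,
        )
        bundle.genomes.append(genome)
        bundle.cds[gid] = cds
        bundle.proteins[gid] = proteins
        bundle.hits[gid] = hits
        bundle.truth[gid] = {
            "true_size_bp": spec.true_genome_size,
            "completeness": completeness,
            "n_families": spec.n_paralog_families,
            "families": families,
        }
    return bundle


def generate_ani_table(
    genomes: Sequence[GenomeRecord], seed: int = 0
) -> list[tuple[str, str, float]]:
    """Directional ANI rows: within-clade pairs near 99%, cross-clade ~78%."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    rows = []
    for i, a in enumerate(genomes):
        for b in genomes[i + 1:]:
            if a.clade == b.clade:
                mu = 99.2
                sd = 0.25
            else:
                mu = 78.0
                sd = 1.5
            for q, r in ((a, b), (b, a)):
                rows.append((
                    q.genome_id, r.genome_id,
                    float(np.clip(rng.normal(mu, sd), 70.0, 100.0)),
                ))
    return rows


def generate_ecology(
    niche: NicheSpec,
    genomes: Sequence[GenomeRecord],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Count table, sample table and environmental cast table.

    Above-boundary samples recruit ``dominance`` of the clade reads to
    ``clade_above`` genomes and vice versa.  Environmental casts sit within
    +-0.4 m of the metagenome depth; a station-depth pair occasionally gets
    a duplicate cast to exercise the mean rule.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 417]))
    above = [g.genome_id for g in genomes if g.clade == niche.clade_above]
    below = [g.genome_id for g in genomes if g.clade == niche.clade_below]
    if not above or not below:
        raise InputError("need genomes in both niche clades")
    count_rows, sample_rows, env_rows = [], [], []
    for s in range(niche.n_stations):
        station = f"ST{s:02d}"
        for depth in niche.depths:
            sid = f"{station}_{int(depth)}m"
            # sharp but monotone niche transition centred on the boundary
            sig = 1.0 / (1.0 + np.exp(
                (depth - niche.boundary_depth) / niche.transition_width_m
            ))
            w_above = (2 * niche.dominance - 1) * sig + (1 - niche.dominance)
            weights = np.concatenate([
                rng.uniform(0.5, 1.5, len(above)) * w_above,
                rng.uniform(0.5, 1.5, len(below)) * (1 - w_above),
            ])
            weights /= weights.sum()
            recruited = int(niche.sample_total_reads * niche.recruited_fraction
                            * rng.uniform(0.7, 1.3))
            reads = rng.multinomial(recruited, weights)
            for gid, n in zip(above + below, reads):
                count_rows.append(
                    {"genome_id": gid, "sample_id": sid, "reads": int(n)}
                )
            sample_rows.append({
                "sample_id": sid, "station": station, "depth": depth,
                "total_reads": niche.sample_total_reads,
                "total_bp": niche.sample_total_reads * niche.read_length,
            })
            n_casts = 2 if rng.random() < niche.duplicate_cast_prob else 1
            for _ in range(n_casts):
                cast_depth = depth + float(rng.uniform(-0.4, 0.4))
                row = {"station": station, "depth": cast_depth}
                for name, (b0, b1, sd) in niche.env_gradients.items():
                    noise = rng.normal(0, sd) if sd > 0 else 0.0
                    row[name] = b0 + b1 * cast_depth + noise
                if niche.patchy_param:
                    row[niche.patchy_param] = (
                        float(rng.uniform(0.05, 1.5))
                        if rng.random() < niche.patchy_coverage else np.nan
                    )
                env_rows.append(row)
    counts = pd.DataFrame(count_rows)
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    env = pd.DataFrame(env_rows)
    return counts, samples, env


def generate_rhodopsins(
    n: int = 8,
    label_mix: Sequence[str] = ("blue",) * 7 + ("green",),
    seed: int = 0,
    background_mutation_rate: float = 0.05,
    delete_site: int | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Rhodopsin sequences on the synthetic scaffold with known tuning.

    ``label_mix`` is cycled over the ``n`` sequences: ``blue`` sets Q at
    site 105, ``green`` sets L or M.  Sites 97/108 carry the D/E proton
    pump pair.  Background positions outside the diagnostic window mutate
    at ``background_mutation_rate``.  ``delete_site`` removes that
    reference position from every sequence (for gap-handling tests).
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 105]))
    seqs: dict[str, str] = {}
    truth_rows = []
    protected = set(range(93, 110))  # window positions 94-110, 0-based
    for i in range(n):
        label = label_mix[i % len(label_mix)]
        chars = list(SYNTHETIC_PR_REFERENCE)
        for j in range(len(chars)):
            if j not in protected and rng.random() < background_mutation_rate:
                chars[j] = AA[rng.choice(len(AA))]
        chars[96] = "D"
        chars[104] = "Q" if label == "blue" else ("L" if rng.random() < 0.7 else "M")
        chars[107] = "E"
        r105 = chars[104]
        if delete_site is not None:
            del chars[delete_site - 1]
        pid = f"rhod_{i:02d}"
        seqs[pid] = "".join(chars)
        truth_rows.append(
            {"protein_id": pid, "tuning": label, "residue_105": r105}
        )
    return seqs, pd.DataFrame(truth_rows)


def load_config(path: str) -> dict:
    """Parse a YAML simulation config into specs and a seed.

    Keys: ``seed`` (int), ``clades`` (list of CladeSpec fields), ``niche``
    (NicheSpec fields, optional).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InputError(f"config {path!r} is not a mapping")
    clades = [CladeSpec(**c) for c in raw.get("clades", [])]
    for c in clades:
        if isinstance(c.completeness_range, list):
            c.completeness_range = tuple(c.completeness_range)
    niche_raw = raw.get("niche")
    niche = NicheSpec(**_niche_kwargs(niche_raw)) if niche_raw else NicheSpec()
    return {"seed": int(raw.get("seed", 0)), "clades": clades, "niche": niche}


def _niche_kwargs(raw: Mapping) -> dict:
    kw = dict(raw)
    if "depths" in kw:
        kw["depths"] = tuple(float(d) for d in kw["depths"])
    if "env_gradients" in kw:
        kw["env_gradients"] = {
            k: tuple(v) for k, v in kw["env_gradients"].items()
        }
    return kw
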