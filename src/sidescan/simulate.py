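"""Synthetic inputs with known ground truth for every pipeline stage.

This module emulates, at reduced scale, the data classes the pipeline
was designed for: bacterial genome assemblies carrying a planted
petrobactin-like biosynthetic gene cluster (two NIS synthase genes,
pfam04183, plus a 3-dehydroshikimate dehydratase gene, pfam01261),
point-mutated genome copies and shotgun reads for ANI / read-recruitment
work, LC-MS feature tables with siderophore peaks among decoys, and
logistic OD600 growth curves.  Every generator is deterministic given a
seed and returns a machine-readable truth record so downstream recovery
can be scored exactly.

Substitution-only mutation is the default (an optional flag adds
indels): it keeps nucleotide identity on mutated copies an exact
bookkeeping quantity, so the ANI stage can be checked against a
position-by-position oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DomtblRow, GffGene
from .mass_screen import SiderophoreRecord, adduct_mz

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

# Gene layout mimicking the asb-like operon of known petrobactin
# producers: two NIS synthases (asbA/asbB analogs), a dehydratase (asbF
# analog), accessory genes without diagnostic domains, and a TBDT-like
# transporter next door.
DEFAULT_CLUSTER_SPEC: tuple[tuple[str, str | None], ...] = (
    ("asbA", "pfam04183"),
    ("asbB", "pfam04183"),
    ("asbC", None),
    ("asbD", None),
    ("asbE", None),
    ("asbF", "pfam01261"),
    ("tbdt", "pfam00593"),
)


class SizingError(ValueError):
    """Genome too short for the requested gene layout."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated genome / sample.

    Defaults are kept modest so a full multi-genome screen runs in
    seconds while leaving room for a realistic gene layout.
    """

    seed: int = 0
    genome_length: int = 60_000
    n_genes: int = 40
    cluster_spec: tuple[tuple[str, str | None], ...] = DEFAULT_CLUSTER_SPEC
    substitution_rate: float = 0.02
    read_length: int = 100
    depth: float = 10.0
    ms_noise_peaks: int = 100
    od_noise_sd: float = 0.01
    completeness: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness must be in (0, 1]")


@dataclass(frozen=True)
class ClusterTruth:
    """Ground-truth record of the planted locus."""

    contig_id: str
    gene_ids: tuple[str, ...]
    pfam_labels: tuple[str | None, ...]
    start: int  # 1-based inclusive, span of the whole locus
    end: int


@dataclass(frozen=True)
class SimGenome:
    genome_id: str
    sequence: str
    genes: tuple[GffGene, ...]
    domain_hits: tuple[DomtblRow, ...]
    truth: ClusterTruth | None


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def gen_genome(config: SimConfig, genome_id: str = "sim") -> SimGenome:
    """Simulate a single-contig genome with a planted gene cluster.

    Genes are laid out left to right with intergenic gaps drawn from
    [20, 200] bp; the cluster genes occupy a consecutive run of gene
    slots at a random position in gene order, mimicking an operon.
    Domain hits are emitted in HMMER domtblout shape for every gene
    whose spec carries a pfam label.  Coordinates are 1-based inclusive.
    """
    rng = np.random.default_rng(config.seed)
    spec = list(config.cluster_spec)
    if config.n_genes < len(spec):
        raise SizingError(
            f"n_genes={config.n_genes} < cluster size {len(spec)}"
        )
    gene_lengths = rng.integers(600, 1201, size=config.n_genes)
    gaps = rng.integers(20, 201, size=config.n_genes)  # gap before each gene
    span = int(gene_lengths.sum() + gaps.sum())
    if config.genome_length < span:
        raise SizingError(
            f"genome_length={config.genome_length} bp cannot hold "
            f"{config.n_genes} genes spanning {span} bp"
        )
    contig = f"{genome_id}_c1"
    sequence = _random_sequence(rng, config.genome_length)

    # Which gene slots belong to the cluster (consecutive in gene order).
    if spec:
        cluster_at = int(rng.integers(0, config.n_genes - len(spec) + 1))
        cluster_slots = set(range(cluster_at, cluster_at + len(spec)))
    else:
        cluster_at, cluster_slots = -1, set()

    genes: list[GffGene] = []
    hits: list[DomtblRow] = []
    truth_genes: list[str] = []
    truth_pfams: list[str | None] = []
    pos = 0
    for i in range(config.n_genes):
        pos += int(gaps[i])
        start, end = pos + 1, pos + int(gene_lengths[i])
        pos = end
        strand = "+" if rng.random() < 0.5 else "-"
        if i in cluster_slots:
            role, pfam = spec[i - cluster_at]
            gene_id = f"{genome_id}_g{i + 1:04d}_{role}"
            truth_genes.append(gene_id)
            truth_pfams.append(pfam)
        else:
            gene_id = f"{genome_id}_g{i + 1:04d}"
            pfam = None
        genes.append(GffGene(gene_id, contig, start, end, strand))
        if pfam is not None:
            evalue = 10.0 ** -float(rng.uniform(20, 60))
            hits.append(
                DomtblRow(
                    target_name=gene_id,
                    query_name=pfam,
                    query_accession=pfam.replace("pfam", "PF") + ".1",
                    full_evalue=evalue,
                    full_score=float(rng.uniform(80, 400)),
                )
            )

    truth = None
    if spec:
        members = [genes[i] for i in sorted(cluster_slots)]
        truth = ClusterTruth(
            contig_id=contig,
            gene_ids=tuple(truth_genes),
            pfam_labels=tuple(truth_pfams),
            start=members[0].start,
            end=members[-1].end,
        )
    return SimGenome(genome_id, sequence, tuple(genes), tuple(hits), truth)


def mutate_genome(
    sequence: str,
    rate: float,
    seed: int,
    indels: bool = False,
    indel_rate: float = 0.001,
) -> str:
    """Return a point-mutated copy of ``sequence``.

    Each position is substituted independently with probability ``rate``;
    the replacement is drawn uniformly from the three alternative bases,
    so ``rate=1`` changes every position.  With ``indels=True``, short
    (1-3 bp) insertions and deletions are additionally introduced at
    ``indel_rate`` per position.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if not sequence:
        warnings.warn("mutate_genome called on an empty genome", stacklevel=2)
        return ""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    idx = _BASE_INDEX[arr].astype(np.int64)
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n:
        idx[hit] = (idx[hit] + rng.integers(1, 4, size=n)) % 4
        arr = _BASES[idx]
    out = arr.tobytes().decode("ascii")
    if indels:
        chars = list(out)
        i = 0
        result: list[str] = []
        while i < len(chars):
            if rng.random() < indel_rate:
                size = int(rng.integers(1, 4))
                if rng.random() < 0.5:  # deletion
                    i += size
                    continue
                result.extend(
                    rng.choice(_BASES, size=size).tobytes().decode("ascii")
                )
            result.append(chars[i])
            i += 1
        out = "".join(result)
    return out


@dataclass(frozen=True)
class SimRead:
    read_id: str
    contig_id: str
    pos: int  # 1-based leftmost position on the source genome
    seq: str
    n_errors: int

    @property
    def cigar(self) -> str:
        return f"{len(self.seq)}M"


def gen_reads(
    sequence: str,
    read_length: int,
    depth: float,
    error_rate: float = 0.0,
    seed: int = 0,
    contig_id: str = "sim_c1",
) -> list[SimRead]:
    """Draw uniform shotgun reads with per-base substitution errors.

    The read count is Poisson with mean depth * L / read_length, the
    sequencing analog of fold-coverage.  Truth SAM records (1-based POS,
    all-match CIGAR, NM = injected error count) can be written with
    :func:`reads_to_sam_records` + ``io.write_sam``.
    """
    if read_length > len(sequence):
        raise ValueError("read_length exceeds genome length")
    if depth <= 0:
        return []
    rng = np.random.default_rng(seed)
    n_reads = int(rng.poisson(depth * len(sequence) / read_length))
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    starts = rng.integers(0, len(sequence) - read_length + 1, size=n_reads)
    reads = []
    for i, s in enumerate(starts):
        sub = arr[s : s + read_length].copy()
        errs = rng.random(read_length) < error_rate
        n_err = int(errs.sum())
        if n_err:
            idx = _BASE_INDEX[sub[errs]].astype(np.int64)
            sub[errs] = _BASES[(idx + rng.integers(1, 4, size=n_err)) % 4]
        reads.append(
            SimRead(
                read_id=f"read_{i:07d}",
                contig_id=contig_id,
                pos=int(s) + 1,
                seq=sub.tobytes().decode("ascii"),
                n_errors=n_err,
            )
        )
    return reads


def reads_to_sam_records(reads: Sequence[SimRead]) -> list[dict]:
    return [
        {
            "read_id": r.read_id,
            "contig_id": r.contig_id,
            "pos": r.pos,
            "seq": r.seq,
            "cigar": r.cigar,
            "nm": r.n_errors,
        }
        for r in reads
    ]


def gen_ms_features(
    references: Sequence[SiderophoreRecord],
    adducts: Sequence[str] = ("[M+H]+",),
    n_noise: int = 100,
    mz_range: tuple[float, float] = (150.0, 1200.0),
    seed: int = 0,
    jitter_ppm: float = 0.0,
    sample_id: str = "sim",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an LC-MS feature table containing known siderophores.

    One feature is generated per (compound, adduct) at the theoretical
    m/z, offset by Gaussian mass error of ``jitter_ppm`` ppm sd.  Decoy
    features are uniform over ``mz_range`` but resampled until at least
    10 ppm away from every true m/z, so truth labels are unambiguous.

    Returns (features, truth); ``features`` has the on-disk TSV shape
    (sample_id, mz, rt_min, intensity, ms2) and ``truth`` maps feature
    rows to compound/adduct labels.
    """
    rng = np.random.default_rng(seed)
    lo, hi = mz_range
    true_mz = []
    rows = []
    truth_rows = []
    for ref in references:
        for adduct in adducts:
            mz = adduct_mz(ref.neutral_monoisotopic_mass, adduct)
            if not lo <= mz <= hi:
                raise ValueError(
                    f"mz_range {mz_range} does not span {ref.name} {adduct} ({mz:.3f})"
                )
            true_mz.append(mz)
            observed = mz * (1.0 + rng.normal(0.0, jitter_ppm) * 1e-6)
            rows.append(
                {
                    "sample_id": sample_id,
                    "mz": observed,
                    "rt_min": float(rng.uniform(1, 20)),
                    "intensity": float(rng.lognormal(10, 1)),
                    "ms2": "",
                }
            )
            truth_rows.append(
                {"compound": ref.name, "adduct": adduct, "theoretical_mz": mz}
            )
    n_decoys = 0
    while n_decoys < n_noise:
        mz = float(rng.uniform(lo, hi))
        if any(abs(mz - t) / t * 1e6 < 10.0 for t in true_mz):
            continue  # too close to a real compound: truth would be ambiguous
        rows.append(
            {
                "sample_id": sample_id,
                "mz": mz,
                "rt_min": float(rng.uniform(1, 20)),
                "intensity": float(rng.lognormal(8, 1)),
                "ms2": "",
            }
        )
        truth_rows.append({"compound": None, "adduct": None, "theoretical_mz": np.nan})
        n_decoys += 1
    features = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    truth["is_decoy"] = truth["compound"].isna()
    return features, truth


def logistic(t: np.ndarray | float, mu: float, K: float, N0: float):
    """Logistic growth N(t) = K / (1 + ((K - N0)/N0) e^(-mu t))."""
    return K / (1.0 + ((K - N0) / N0) * np.exp(-mu * np.asarray(t, dtype=float)))


def gen_growth_curves(
    mu: float,
    K: float,
    N0: float,
    times: Sequence[float],
    noise_sd: float = 0.01,
    n_rep: int = 3,
    seed: int = 0,
    condition: str = "sim",
    strain: str = "WT",
) -> pd.DataFrame:
    """Simulate replicate OD600 logistic growth curves.

    Gaussian noise of sd ``noise_sd`` (OD600 units) is added and values
    truncated at 0, emulating blank-subtracted plate-reader output.
    Returns the long-format table (condition, strain, replicate, time_h,
    od600) the growth module reads.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a strictly increasing vector")
    if not (mu > 0 and K > N0 > 0):
        raise ValueError("require mu > 0 and K > N0 > 0")
    rng = np.random.default_rng(seed)
    clean = logistic(t, mu, K, N0)
    frames = []
    for rep in range(1, n_rep + 1):
        od = clean + rng.normal(0.0, noise_sd, size=len(t)) if noise_sd > 0 else clean
        od = np.maximum(od, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "condition": condition,
                    "strain": strain,
                    "replicate": rep,
                    "time_h": t,
                    "od600": od,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
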