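"""Read-recruitment filtering, counting and RPKM normalization.

Competitive mapping assigns each metagenomic read to its best genome;
this module takes the resulting SAM, applies the standard recruitment
filter — drop alignments below 95% identity or below 75% of the read
aligned — counts primary alignments per contig, rolls counts up to MAGs
via a contig→MAG map, and normalizes to RPKM:

    RPKM = count / ((genome_length / 1e3) * (metagenome_size / 1e9))

i.e. reads per kbp of genome per Gbp of sequenced metagenome.  For MAGs
grouped into one species, member read counts are pooled and normalized
by the species' estimated complete genome length, so overlapping
assemblies that split reads between them do not dilute the species
signal.

Identity is gap-compensated: 1 - NM / aligned_length, with
aligned_length the read-consuming alignment columns excluding clips.
Thresholds are inclusive (records *below* a threshold are removed).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .ani import SpeciesGroup

DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MIN_ALIGNED_FRACTION = 0.75

# CIGAR ops that consume the read, excluding soft clips: M, I, =, X
_READ_CONSUMING = {0, 1, 7, 8}


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    contig_id: str | None
    read_length: int
    aligned_length: int  # alignment columns on the read (clips excluded)
    edit_distance: int | None  # NM; None when the tag is absent
    mapped: bool
    primary: bool = True

    @property
    def identity(self) -> float | None:
        if not self.mapped or self.edit_distance is None or self.aligned_length == 0:
            return None
        return 1.0 - self.edit_distance / self.aligned_length

    @property
    def aligned_fraction(self) -> float | None:
        if not self.mapped or self.read_length == 0:
            return None
        return self.aligned_length / self.read_length


def read_sam(path: str) -> list[AlignmentRecord]:
    """Load alignment records from a SAM file (NM tag expected)."""
    records = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped:
                records.append(
                    AlignmentRecord(
                        seg.query_name, None,
                        seg.query_length or len(seg.query_sequence or ""),
                        0, None, mapped=False,
                    )
                )
                continue
            aligned = sum(
                length for op, length in (seg.cigartuples or [])
                if op in _READ_CONSUMING
            )
            read_len = seg.infer_read_length() or aligned
            nm = seg.get_tag("NM") if seg.has_tag("NM") else None
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    contig_id=seg.reference_name,
                    read_length=read_len,
                    aligned_length=aligned,
                    edit_distance=None if nm is None else int(nm),
                    mapped=True,
                    primary=not (seg.is_secondary or seg.is_supplementary),
                )
            )
    return records


def filter_alignments(
    records: Iterable[AlignmentRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aligned_fraction: float = DEFAULT_MIN_ALIGNED_FRACTION,
    on_missing_nm: str = "drop",
) -> list[AlignmentRecord]:
    """Keep mapped records meeting both identity and aligned-fraction cuts.

    Boundary values are retained: a record at exactly 95% identity
    passes a 0.95 cut.  Records lacking the NM tag are dropped with a
    warning by default (``on_missing_nm="error"`` raises instead).
    """
    for name, value in (
        ("min_identity", min_identity),
        ("min_aligned_fraction", min_aligned_fraction),
    ):
        if not 0.0 < value <= 1.0:
            raise ValueError(f"{name} must be in (0, 1]")
    kept = []
    n_missing = 0
    for rec in records:
        if not rec.mapped:
            continue
        if rec.edit_distance is None:
            if on_missing_nm == "error":
                raise ValueError(f"record {rec.read_id} lacks an edit distance (NM)")
            n_missing += 1
            continue
        if (
            rec.identity >= min_identity
            and rec.aligned_fraction >= min_aligned_fraction
        ):
            kept.append(rec)
    if n_missing:
        warnings.warn(
            f"dropped {n_missing} record(s) lacking the NM tag", stacklevel=2
        )
    return kept


def count_per_contig(
    records: Iterable[AlignmentRecord],
    contig_to_mag: Mapping[str, str],
) -> tuple[Counter, Counter, int]:
    """Primary-alignment read counts per contig and per MAG.

    Secondary/supplementary alignments are excluded — competitive
    mapping assigns each read once.  Contigs absent from the map are
    pooled under an "unassigned" total, with a warning.
    """
    per_contig: Counter = Counter()
    per_mag: Counter = Counter()
    unassigned = 0
    unknown_contigs = set()
    for rec in records:
        if not (rec.mapped and rec.primary):
            continue
        per_contig[rec.contig_id] += 1
        mag = contig_to_mag.get(rec.contig_id)
        if mag is None:
            unassigned += 1
            unknown_contigs.add(rec.contig_id)
        else:
            per_mag[mag] += 1
    if unknown_contigs:
        warnings.warn(
            f"{len(unknown_contigs)} contig(s) not in the MAG map; "
            f"{unassigned} read(s) counted as unassigned",
            stacklevel=2,
        )
    return per_contig, per_mag, unassigned


def rpkm(count: float, genome_length: float, metagenome_size: float) -> float:
    """Reads per kbp of genome per Gbp of metagenome."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if metagenome_size <= 0:
        raise ValueError("metagenome_size must be positive")
    return count / ((genome_length / 1e3) * (metagenome_size / 1e9))


def pooled_species_rpkm(
    species: SpeciesGroup,
    per_mag_counts: Mapping[str, float],
    metagenome_size: float,
) -> float:
    """Species-level RPKM from pooled member counts.

    Member counts are summed and normalized by the species' estimated
    complete genome length, so reads split between overlapping MAG
    assemblies of the same species are recovered into one number.
    """
    missing = [m for m in species.member_mag_ids if m not in per_mag_counts]
    if missing:
        raise ValueError(
            f"missing read counts for species members: {', '.join(missing)}"
        )
    total = sum(per_mag_counts[m] for m in species.member_mag_ids)
    return rpkm(total, species.estimated_complete_genome_length, metagenome_size)


@dataclass(frozen=True)
class AbundanceProfile:
    sample_id: str
    metagenome_size: float
    per_contig_counts: Mapping[str, int]
    per_mag_counts: Mapping[str, int]
    per_mag_rpkm: Mapping[str, float]
    per_species_counts: Mapping[str, int]
    per_species_rpkm: Mapping[str, float]
    unassigned: int


def profile_sample(
    records: Sequence[AlignmentRecord],
    contig_to_mag: Mapping[str, str],
    mag_lengths: Mapping[str, float],
    metagenome_size: float,
    sample_id: str = "sample",
    species: Sequence[SpeciesGroup] = (),
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aligned_fraction: float = DEFAULT_MIN_ALIGNED_FRACTION,
) -> AbundanceProfile:
    """Filter, count and normalize one sample end to end."""
    kept = filter_alignments(records, min_identity, min_aligned_fraction)
    per_contig, per_mag, unassigned = count_per_contig(kept, contig_to_mag)
    mag_rpkm = {
        mag: rpkm(per_mag.get(mag, 0), length, metagenome_size)
        for mag, length in mag_lengths.items()
    }
    sp_counts = {}
    sp_rpkm = {}
    for sp in species:
        counts = {m: per_mag.get(m, 0) for m in sp.member_mag_ids}
        sp_counts[sp.species_id] = sum(counts.values())
        sp_rpkm[sp.species_id] = pooled_species_rpkm(sp, counts, metagenome_size)
    return AbundanceProfile(
        sample_id=sample_id,
        metagenome_size=metagenome_size,
        per_contig_counts=dict(per_contig),
        per_mag_counts=dict(per_mag),
        per_mag_rpkm=mag_rpkm,
        per_species_counts=sp_counts,
        per_species_rpkm=sp_rpkm,
        unassigned=unassigned,
    )


def profile_to_frame(profile: AbundanceProfile) -> pd.DataFrame:
    """Long-format abundance table (sample, unit, unit_id, count, rpkm)."""
    rows = []
    for mag, count in sorted(profile.per_mag_counts.items()):
        rows.append(
            {
                "sample": profile.sample_id,
                "unit": "mag",
                "unit_id": mag,
                "count": count,
                "rpkm": profile.per_mag_rpkm.get(mag),
            }
        )
    for sp, count in sorted(profile.per_species_counts.items()):
        rows.append(
            {
                "sample": profile.sample_id,
                "unit": "species",
                "unit_id": sp,
                "count": count,
                "rpkm": profile.per_species_rpkm[sp],
            }
        )
    if profile.unassigned:
        rows.append(
            {
                "sample": profile.sample_id,
                "unit": "unassigned",
                "unit_id": "unassigned",
                "count": profile.unassigned,
                "rpkm": None,
            }
        )
    return pd.DataFrame(rows, columns=["sample", "unit", "unit_id", "count", "rpkm"])
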