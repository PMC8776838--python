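"""Detection of petrobactin-like biosynthetic gene clusters.

Petrobactin biosynthesis is diagnosed by the genomic co-location of
NRPS-independent (NIS) siderophore synthase genes (Pfam PF04183, the
asbA/asbB analogs) with a 3-dehydroshikimate dehydratase gene (PF01261,
the asbF analog).  Inputs are ordinary annotation artifacts — GFF3 gene
calls and HMMER domtblout domain hits — so the module slots in after
any gene caller / profile search.  Co-localization is codified as a
gene-count gap rule: carrier genes on the same contig belong to one
locus when at most ``max_gene_gap`` non-carrier genes intervene.
Strand is recorded but ignored for grouping, since known clusters mix
operon orientations across taxa.

Completeness classes:

``complete``
    at least two distinct synthase genes plus a dehydratase — the
    two-NIS-synthase architecture of authentic petrobactin pathways;
``partial``
    one synthase plus a dehydratase;
``synthase_only``
    synthase carrier(s) without a co-localized dehydratase.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import DomtblRow, GffGene, read_domtblout, read_gff3_genes

DEFAULT_SYNTHASE_PFAM = "PF04183"
DEFAULT_DEHYDRATASE_PFAM = "PF01261"
DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_MAX_GENE_GAP = 3


def normalize_pfam(label: str) -> str:
    """Canonicalize Pfam labels: 'pfam04183', 'PF04183.14' -> 'PF04183'."""
    m = re.match(r"(?i)^(?:pf(?:am)?)(\d+)(?:\.\d+)?$", label.strip())
    if not m:
        raise ValueError(f"unrecognized pfam label {label!r}")
    return f"PF{int(m.group(1)):05d}"


@dataclass(frozen=True)
class Gene:
    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    ordinal: int  # index along the contig in start order

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    pfam_accession: str  # normalized, e.g. PF04183
    full_sequence_evalue: float
    bitscore: float


@dataclass(frozen=True)
class Locus:
    """A run of domain-carrier genes plus the genes between them."""

    contig_id: str
    carrier_gene_ids: tuple[str, ...]
    all_gene_ids: tuple[str, ...]  # carriers plus intervening genes, in order
    start: int
    end: int
    is_candidate: bool  # has >=1 synthase AND >=1 dehydratase


@dataclass(frozen=True)
class GeneCluster:
    contig_id: str
    gene_ids: tuple[str, ...]
    n_synthase: int
    has_dehydratase: bool
    accessory_labels: Mapping[str, str]  # gene_id -> other pfam on the locus
    completeness_class: str  # complete | partial | synthase_only
    start: int
    end: int


class OrphanHitError(ValueError):
    """Domain hits referencing gene ids absent from the gene calls."""


def _index_genes(raw: Iterable[GffGene]) -> list[Gene]:
    by_contig: dict[str, list[GffGene]] = defaultdict(list)
    for g in raw:
        by_contig[g.contig_id].append(g)
    out: list[Gene] = []
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=lambda g: (g.start, g.end, g.gene_id))
        out.extend(
            Gene(g.gene_id, g.contig_id, g.start, g.end, g.strand, i)
            for i, g in enumerate(ordered)
        )
    return out


def load_annotations(
    gff3_path: str,
    domtblout_path: str,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> tuple[list[Gene], list[DomainHit]]:
    """Load gene calls and significance-filtered domain hits.

    Hits with full-sequence E-value above ``evalue_max`` are discarded
    (boundary inclusive); of the survivors, only the lowest-E-value hit
    per (gene, pfam) is kept.  Hits naming genes absent from the GFF3
    raise ``OrphanHitError`` listing the orphans.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    genes = _index_genes(read_gff3_genes(gff3_path))
    hits = filter_domain_hits(read_domtblout(domtblout_path), evalue_max)
    known = {g.gene_id for g in genes}
    orphans = sorted({h.gene_id for h in hits} - known)
    if orphans:
        raise OrphanHitError(
            f"domain hits reference genes absent from GFF3: {', '.join(orphans)}"
        )
    return genes, hits


def filter_domain_hits(
    rows: Iterable[DomtblRow], evalue_max: float = DEFAULT_EVALUE_MAX
) -> list[DomainHit]:
    """Apply the E-value cutoff, then keep the best hit per (gene, pfam)."""
    best: dict[tuple[str, str], DomainHit] = {}
    for r in rows:
        if r.full_evalue > evalue_max:
            continue
        pfam = normalize_pfam(r.query_accession if r.query_accession != "-" else r.query_name)
        key = (r.target_name, pfam)
        hit = DomainHit(r.target_name, pfam, r.full_evalue, r.full_score)
        if key not in best or hit.full_sequence_evalue < best[key].full_sequence_evalue:
            best[key] = hit
    return sorted(
        best.values(), key=lambda h: (h.gene_id, h.pfam_accession)
    )


def find_loci(
    genes: Sequence[Gene],
    hits: Sequence[DomainHit],
    synthase_pfam: str = DEFAULT_SYNTHASE_PFAM,
    dehydratase_pfam: str = DEFAULT_DEHYDRATASE_PFAM,
    max_gene_gap: int = DEFAULT_MAX_GENE_GAP,
) -> list[Locus]:
    """Group synthase/dehydratase carrier genes into loci by gene-gap rule.

    Consecutive carriers on one contig join a locus when separated by at
    most ``max_gene_gap`` intervening genes.  Every locus is returned;
    ``is_candidate`` marks those carrying both diagnostic domains.
    """
    if max_gene_gap < 0:
        raise ValueError("max_gene_gap must be >= 0")
    synthase = normalize_pfam(synthase_pfam)
    dehydratase = normalize_pfam(dehydratase_pfam)
    pfams_by_gene: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        pfams_by_gene[h.gene_id].add(h.pfam_accession)

    by_contig: dict[str, list[Gene]] = defaultdict(list)
    for g in genes:
        by_contig[g.contig_id].append(g)

    loci: list[Locus] = []
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=lambda g: g.ordinal)
        carriers = [
            g for g in ordered
            if pfams_by_gene[g.gene_id] & {synthase, dehydratase}
        ]
        if not carriers:
            continue
        run: list[Gene] = [carriers[0]]
        for g in carriers[1:]:
            if g.ordinal - run[-1].ordinal - 1 <= max_gene_gap:
                run.append(g)
            else:
                loci.append(_make_locus(run, ordered, pfams_by_gene, synthase, dehydratase))
                run = [g]
        loci.append(_make_locus(run, ordered, pfams_by_gene, synthase, dehydratase))
    return loci


def _make_locus(
    run: list[Gene],
    contig_genes: list[Gene],
    pfams_by_gene: Mapping[str, set],
    synthase: str,
    dehydratase: str,
) -> Locus:
    lo, hi = run[0].ordinal, run[-1].ordinal
    members = [g for g in contig_genes if lo <= g.ordinal <= hi]
    has_syn = any(synthase in pfams_by_gene[g.gene_id] for g in run)
    has_deh = any(dehydratase in pfams_by_gene[g.gene_id] for g in run)
    return Locus(
        contig_id=run[0].contig_id,
        carrier_gene_ids=tuple(g.gene_id for g in run),
        all_gene_ids=tuple(g.gene_id for g in members),
        start=min(g.start for g in members),
        end=max(g.end for g in members),
        is_candidate=has_syn and has_deh,
    )


def find_colocalized(
    genes: Sequence[Gene],
    hits: Sequence[DomainHit],
    synthase_pfam: str = DEFAULT_SYNTHASE_PFAM,
    dehydratase_pfam: str = DEFAULT_DEHYDRATASE_PFAM,
    max_gene_gap: int = DEFAULT_MAX_GENE_GAP,
) -> list[Locus]:
    """Candidate loci only: both diagnostic domains co-localized."""
    return [
        l for l in find_loci(genes, hits, synthase_pfam, dehydratase_pfam, max_gene_gap)
        if l.is_candidate
    ]


def classify_cluster(
    locus: Locus,
    genes: Sequence[Gene],
    hits: Sequence[DomainHit],
    synthase_pfam: str = DEFAULT_SYNTHASE_PFAM,
    dehydratase_pfam: str = DEFAULT_DEHYDRATASE_PFAM,
    neighborhood: int = DEFAULT_MAX_GENE_GAP,
) -> GeneCluster:
    """Assign a pathway-completeness class to a locus.

    A gene with several synthase domain hits still counts once; the
    two-synthase requirement is about distinct genes.  Any other pfam
    labels supplied in ``hits`` (e.g. transporters) on locus members or
    on genes within ``neighborhood`` positions of the locus edges are
    reported as accessory annotations but never required.
    """
    synthase = normalize_pfam(synthase_pfam)
    dehydratase = normalize_pfam(dehydratase_pfam)
    member = set(locus.all_gene_ids)
    ordinals = [
        g.ordinal for g in genes
        if g.contig_id == locus.contig_id and g.gene_id in member
    ]
    lo, hi = min(ordinals) - neighborhood, max(ordinals) + neighborhood
    neighbors = {
        g.gene_id for g in genes
        if g.contig_id == locus.contig_id and lo <= g.ordinal <= hi
    }
    pfams_by_gene: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        if h.gene_id in neighbors:
            pfams_by_gene[h.gene_id].add(h.pfam_accession)
    n_synthase = sum(1 for g in locus.all_gene_ids if synthase in pfams_by_gene[g])
    has_dehydratase = any(
        dehydratase in pfams_by_gene[g] for g in locus.all_gene_ids
    )
    accessory = {
        g: ",".join(sorted(pfams_by_gene[g] - {synthase, dehydratase}))
        for g in sorted(neighbors)
        if pfams_by_gene[g] - {synthase, dehydratase}
    }
    if n_synthase < 1:
        raise ValueError("a cluster must contain at least one synthase gene")
    if n_synthase >= 2 and has_dehydratase:
        cls = "complete"
    elif n_synthase == 1 and has_dehydratase:
        cls = "partial"
    else:
        cls = "synthase_only"
    return GeneCluster(
        contig_id=locus.contig_id,
        gene_ids=locus.all_gene_ids,
        n_synthase=n_synthase,
        has_dehydratase=has_dehydratase,
        accessory_labels=accessory,
        completeness_class=cls,
        start=locus.start,
        end=locus.end,
    )


@dataclass(frozen=True)
class ScreenSummary:
    n_genomes: int
    n_with_synthase: int
    n_with_colocalization: int
    n_complete: int
    failures: tuple[str, ...] = ()


def screen_genes(
    genes: Sequence[Gene],
    hits: Sequence[DomainHit],
    synthase_pfam: str = DEFAULT_SYNTHASE_PFAM,
    dehydratase_pfam: str = DEFAULT_DEHYDRATASE_PFAM,
    max_gene_gap: int = DEFAULT_MAX_GENE_GAP,
) -> list[GeneCluster]:
    """Classify every locus with at least one synthase gene."""
    synthase = normalize_pfam(synthase_pfam)
    clusters = []
    for locus in find_loci(genes, hits, synthase_pfam, dehydratase_pfam, max_gene_gap):
        carrier_pfams = {
            h.pfam_accession for h in hits if h.gene_id in set(locus.carrier_gene_ids)
        }
        if synthase not in carrier_pfams:
            continue  # dehydratase-only locus: not a siderophore synthase locus
        clusters.append(
            classify_cluster(locus, genes, hits, synthase_pfam, dehydratase_pfam)
        )
    return clusters


def screen_genome_set(
    annotation_pairs: Mapping[str, tuple[str, str]],
    synthase_pfam: str = DEFAULT_SYNTHASE_PFAM,
    dehydratase_pfam: str = DEFAULT_DEHYDRATASE_PFAM,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    max_gene_gap: int = DEFAULT_MAX_GENE_GAP,
) -> tuple[ScreenSummary, pd.DataFrame]:
    """Screen many genomes given {genome_id: (gff3_path, domtblout_path)}.

    Returns a summary — genomes with any synthase hit, genomes with a
    co-localized candidate locus, genomes with a complete pathway — and
    a per-cluster report table.  A genome that fails to parse is skipped
    and reported in ``summary.failures`` so one bad assembly does not
    abort the screen.
    """
    if not annotation_pairs:
        raise ValueError("need at least one genome to screen")
    synthase = normalize_pfam(synthase_pfam)
    n_syn = n_coloc = n_complete = 0
    rows = []
    failures = []
    for genome_id in sorted(annotation_pairs):
        gff3, domtbl = annotation_pairs[genome_id]
        try:
            genes, hits = load_annotations(gff3, domtbl, evalue_max)
        except Exception as exc:  # propagate per-genome failures in summary
            failures.append(f"{genome_id}: {exc}")
            continue
        if any(h.pfam_accession == synthase for h in hits):
            n_syn += 1
        clusters = screen_genes(genes, hits, synthase_pfam, dehydratase_pfam, max_gene_gap)
        if any(c.has_dehydratase for c in clusters):
            n_coloc += 1
        if any(c.completeness_class == "complete" for c in clusters):
            n_complete += 1
        for c in clusters:
            rows.append(
                {
                    "genome": genome_id,
                    "contig": c.contig_id,
                    "start": c.start,
                    "end": c.end,
                    "n_synthase": c.n_synthase,
                    "has_dehydratase": c.has_dehydratase,
                    "completeness_class": c.completeness_class,
                    "gene_ids": ",".join(c.gene_ids),
                    "accessory": ";".join(
                        f"{g}:{p}" for g, p in sorted(c.accessory_labels.items())
                    ),
                }
            )
    summary = ScreenSummary(
        n_genomes=len(annotation_pairs),
        n_with_synthase=n_syn,
        n_with_colocalization=n_coloc,
        n_complete=n_complete,
        failures=tuple(failures),
    )
    report = pd.DataFrame(
        rows,
        columns=[
            "genome", "contig", "start", "end", "n_synthase",
            "has_dehydratase", "completeness_class", "gene_ids", "accessory",
        ],
    )
    return summary, report
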