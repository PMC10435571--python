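"""Consensus-peak analysis: replicate merging, reference selection,
cross-dataset overlap counting, gene annotation and candidate ranking.

The consensus construction mirrors a BEDtools-style workflow: replicate peak
sets sharing a dataset id are coalesced (>=1 bp overlap, maximum member
score), the dataset with the most peaks becomes the reference, and each
reference peak becomes a consensus site whose overlap count k is one plus the
number of non-reference datasets contributing at least one intersecting peak.
Sites are annotated to genes (gene body, then an upstream promoter window,
then nearest TSS), filtered to blood-group genes minus excluded transcription
factors, and ranked by (k, reference peak score, best motif relative score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import pandas as pd
from intervaltree import IntervalTree

if TYPE_CHECKING:  # pragma: no cover
    from .io import GeneAnnotation
    from .pwm import MotifHit

logger = logging.getLogger("bgregulome.peaks")


@dataclass(frozen=True)
class Peak:
    contig: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal_value: float | None = None
    p_value: float | None = None
    q_value: float | None = None
    summit: int | None = None  # absolute coordinate of the summit

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"invalid peak interval [{self.start}, {self.end})")


@dataclass
class PeakSet:
    """Peaks of one dataset, kept sorted by (contig, start, end)."""

    dataset_id: str
    peaks: list[Peak]
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.contig, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)


def merge_replicates(peaksets: Sequence[PeakSet]) -> PeakSet:
    """Union of replicate peak sets with overlapping peaks (>=1 bp) coalesced
    into their spanning interval; coalesced score is the maximum member score.
    Book-touching intervals ([a,b) and [b,c)) are not merged."""
    if not peaksets:
        raise ValueError("need at least one peak set")
    ids = {ps.dataset_id for ps in peaksets}
    if len(ids) != 1:
        raise ValueError(f"replicates must share a dataset_id, got {sorted(ids)}")
    dataset_id = peaksets[0].dataset_id
    all_peaks = sorted(
        (p for ps in peaksets for p in ps.peaks),
        key=lambda p: (p.contig, p.start, p.end),
    )
    merged: list[Peak] = []
    cur: Peak | None = None
    n_members = 0
    for p in all_peaks:
        if cur is not None and p.contig == cur.contig and p.start < cur.end:
            cur = replace(
                cur,
                end=max(cur.end, p.end),
                score=max(cur.score, p.score),
                summit=None,
            )
            n_members += 1
        else:
            if cur is not None:
                merged.append(cur)
            cur = p
            n_members = 1
    if cur is not None:
        merged.append(cur)
    return PeakSet(dataset_id=dataset_id, peaks=merged,
                   n_rejected=sum(ps.n_rejected for ps in peaksets))


def select_reference(peaksets: Sequence[PeakSet]) -> str:
    """Dataset with the most peaks; ties broken by lexicographically smallest
    dataset id."""
    if len(peaksets) < 2:
        raise ValueError("reference selection needs at least two datasets")
    return min(peaksets, key=lambda ps: (-len(ps.peaks), ps.dataset_id)).dataset_id


@dataclass
class ConsensusSite:
    """A reference peak with its cross-dataset overlap count k."""

    contig: str
    start: int
    end: int
    overlap_count: int
    contributing_datasets: tuple[str, ...]
    reference_score: float
    assigned_gene: str | None = None
    assignment_category: str | None = None  # body / promoter / nearest
    motif_hits: list["MotifHit"] = field(default_factory=list)

    @property
    def best_hit(self) -> "MotifHit | None":
        if not self.motif_hits:
            return None
        return max(self.motif_hits, key=lambda h: h.relative_score)


def count_overlaps(reference: PeakSet, others: Sequence[PeakSet]) -> list[ConsensusSite]:
    """One consensus site per reference peak; k = 1 + number of non-reference
    datasets with >=1 bp intersection."""
    trees: dict[str, dict[str, IntervalTree]] = {}
    for ps in others:
        per_contig = trees.setdefault(ps.dataset_id, {})
        for p in ps.peaks:
            per_contig.setdefault(p.contig, IntervalTree()).addi(p.start, p.end)
    sites = []
    for p in reference.peaks:
        contributing = [reference.dataset_id]
        for ds_id in sorted(trees):
            tree = trees[ds_id].get(p.contig)
            if tree is not None and tree.overlaps(p.start, p.end):
                contributing.append(ds_id)
        sites.append(
            ConsensusSite(
                contig=p.contig,
                start=p.start,
                end=p.end,
                overlap_count=len(contributing),
                contributing_datasets=tuple(contributing),
                reference_score=p.score,
            )
        )
    return sites


def _tss(gene: "GeneAnnotation") -> int:
    return gene.start if gene.strand == "+" else gene.end - 1


def _gene_order(gene: "GeneAnnotation"):
    return (gene.contig, gene.start, gene.end, gene.symbol)


def annotate_to_genes(
    sites: Sequence[ConsensusSite],
    annotation: Sequence["GeneAnnotation"],
    upstream_window: int = 2000,
) -> list[ConsensusSite]:
    """Assign each site to a gene: gene-body overlap first, then a
    strand-aware upstream promoter window, then nearest TSS.  Ties within a
    category go to the gene earliest in coordinate order."""
    if not annotation:
        raise ValueError("annotation must be non-empty")
    genes = sorted(annotation, key=_gene_order)
    for site in sites:
        same_contig = [g for g in genes if g.contig == site.contig]
        body = [g for g in same_contig if site.start < g.end and g.start < site.end]
        if body:
            site.assigned_gene, site.assignment_category = body[0].symbol, "body"
            continue
        promoter = []
        for g in same_contig:
            tss = _tss(g)
            if g.strand == "+":
                lo, hi = tss - upstream_window, tss
            else:
                lo, hi = tss + 1, tss + 1 + upstream_window
            if site.start < hi and lo < site.end:
                promoter.append(g)
        if promoter:
            site.assigned_gene, site.assignment_category = promoter[0].symbol, "promoter"
            continue
        candidates = same_contig or genes

        def tss_distance(g):
            tss = _tss(g)
            if site.start <= tss < site.end:
                return 0
            return min(abs(tss - site.start), abs(tss - (site.end - 1)))

        nearest = min(candidates, key=lambda g: (tss_distance(g),) + _gene_order(g))
        site.assigned_gene, site.assignment_category = nearest.symbol, "nearest"
    return list(sites)


def filter_candidates(
    sites: Sequence[ConsensusSite], annotation: Sequence["GeneAnnotation"]
) -> list[ConsensusSite]:
    """Keep sites assigned to blood-group genes; drop excluded transcription
    factors (e.g. KLF1, GATA1).  Every removal is logged with its reason."""
    by_symbol = {g.symbol: g for g in annotation}
    kept = []
    for site in sites:
        gene = by_symbol.get(site.assigned_gene) if site.assigned_gene else None
        if gene is None:
            reason = "unassigned"
        elif gene.is_excluded_tf:
            reason = "excluded_tf"
        elif not gene.is_blood_group:
            reason = "not_blood_group"
        else:
            kept.append(site)
            continue
        logger.info(
            "filtered site %s:%d-%d (gene=%s): %s",
            site.contig, site.start, site.end, site.assigned_gene, reason,
        )
    return kept


def rank_candidates(sites: Sequence[ConsensusSite]) -> pd.DataFrame:
    """Total, stable ordering: overlap count desc, reference peak score desc,
    best motif relative score desc, then (contig, start)."""
    def best_rel(site: ConsensusSite) -> float:
        hit = site.best_hit
        return hit.relative_score if hit is not None else float("-inf")

    ordered = sorted(
        sites,
        key=lambda s: (-s.overlap_count, -s.reference_score, -best_rel(s), s.contig, s.start),
    )
    rows = []
    for s in ordered:
        hit = s.best_hit
        rows.append(
            {
                "contig": s.contig,
                "start": s.start,
                "end": s.end,
                "overlap_count": s.overlap_count,
                "datasets": ",".join(s.contributing_datasets),
                "reference_score": s.reference_score,
                "gene": s.assigned_gene,
                "category": s.assignment_category,
                "n_motif_hits": len(s.motif_hits),
                "best_motif_start": hit.start if hit else pd.NA,
                "best_motif_strand": hit.strand if hit else pd.NA,
                "best_relative_score": hit.relative_score if hit else pd.NA,
                "best_p_value": hit.p_value if hit else pd.NA,
            }
        )
    return pd.DataFrame(rows)
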