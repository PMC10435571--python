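"""Variant-in-motif intersection and motif-disruption scoring.

A single-nucleotide variant falling inside a scored motif occurrence is
re-scored with the alternate allele substituted into the window and the
disruption is quantified as delta = rel_wt - rel_mut, the change in JASPAR
relative score.  A Hardy-Weinberg frequency triage compares the expected
homozygote frequency AF^2 against a phenotype prevalence.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence

from .pwm import (
    MotifHit,
    PositionWeightMatrix,
    relative_score,
    reverse_complement,
    score_window,
)

logger = logging.getLogger("bgregulome.variants")

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV at a 0-based position."""

    contig: str
    position: int
    ref: str
    alt: str
    identifier: str | None = None
    allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.ref not in _COMPLEMENT_BASE or self.alt not in _COMPLEMENT_BASE:
            raise ValueError(f"ref/alt must be single bases in ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.allele_frequency is not None and not 0 <= self.allele_frequency <= 1:
            raise ValueError("allele frequency must lie in [0, 1]")


@dataclass
class ImpactRecord:
    """Motif-disruption record for one (hit, variant) pair."""

    hit: MotifHit
    variant: Variant
    rel_wt: float
    rel_mut: float
    delta: float
    core_disrupted: bool


def variants_in_motif(
    hits: Sequence[MotifHit], variants: Sequence[Variant]
) -> list[tuple[MotifHit, Variant]]:
    """Pairs (hit, variant) with hit.start <= variant.position < hit.end,
    on the same contig (half-open interval containment)."""
    by_contig: dict[str, list[Variant]] = {}
    for v in variants:
        by_contig.setdefault(v.contig, []).append(v)
    for vs in by_contig.values():
        vs.sort(key=lambda v: v.position)
    pairs = []
    for hit in hits:
        vs = by_contig.get(hit.contig, [])
        positions = [v.position for v in vs]
        lo = bisect_left(positions, hit.start)
        hi = bisect_right(positions, hit.end - 1)
        for v in vs[lo:hi]:
            pairs.append((hit, v))
    return pairs


def _window_offset(hit: MotifHit, variant: Variant) -> int:
    """Offset of the variant within the scanned-strand window."""
    forward_offset = variant.position - hit.start
    if not 0 <= forward_offset < len(hit.window):
        raise ValueError("variant does not fall inside the motif window")
    if hit.strand == "-":
        return len(hit.window) - 1 - forward_offset
    return forward_offset


def apply_variant(window: str, hit: MotifHit, variant: Variant) -> str:
    """Substitute the alternate allele into the scanned-strand window.

    For "-"-strand hits the window holds the reverse complement of the
    forward strand, so ref/alt are complemented before the substitution.  A
    mismatch between the window base and the expected reference base raises,
    guarding against assembly or coordinate slips.
    """
    offset = _window_offset(hit, variant)
    if hit.strand == "-":
        expected_ref = _COMPLEMENT_BASE[variant.ref]
        new_base = _COMPLEMENT_BASE[variant.alt]
    else:
        expected_ref, new_base = variant.ref, variant.alt
    if window[offset] != expected_ref:
        raise ValueError(
            f"reference mismatch at {variant.contig}:{variant.position}: window has "
            f"{window[offset]!r} but variant.ref implies {expected_ref!r} on strand {hit.strand}"
        )
    return window[:offset] + new_base + window[offset + 1 :]


def delta_relative_score(
    pwm: PositionWeightMatrix,
    hit: MotifHit,
    variant: Variant,
    n_core_columns: int = 4,
) -> ImpactRecord:
    """Change in relative score when the alternate allele replaces the
    reference allele in the hit window.

    ``core_disrupted`` flags variants landing on one of the matrix's
    ``n_core_columns`` highest-information columns (the WGATAR core for a
    GATA-type matrix).
    """
    rel_wt = hit.relative_score
    mutated = apply_variant(hit.window, hit, variant)
    rel_mut = relative_score(pwm, score_window(pwm, mutated))
    column = _window_offset(hit, variant)
    core = bool(column in set(pwm.core_columns(n_core_columns).tolist()))
    return ImpactRecord(
        hit=hit,
        variant=variant,
        rel_wt=rel_wt,
        rel_mut=rel_mut,
        delta=rel_wt - rel_mut,
        core_disrupted=core,
    )


@dataclass
class TriagedImpact:
    """An impact annotated with its Hardy-Weinberg frequency assessment."""

    impact: ImpactRecord
    allele_frequency: float | None
    homozygote_frequency: float | None  # AF^2 under HWE
    flag: str  # candidate_fit / poor_fit / too_rare / no_af


def frequency_triage(
    impacts: Sequence[ImpactRecord],
    prevalence: float,
    af_floor: float = 1e-3,
    fit_factor: float = 10.0,
) -> list[TriagedImpact]:
    """Compare each variant's expected homozygote frequency AF^2 with a
    phenotype prevalence.

    Flags: "too_rare" when AF < af_floor; "candidate_fit" when AF^2 lies
    within a factor ``fit_factor`` of the prevalence; "poor_fit" otherwise;
    "no_af" when the allele frequency is unknown.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    out = []
    for impact in impacts:
        af = impact.variant.allele_frequency
        if af is None:
            out.append(TriagedImpact(impact, None, None, "no_af"))
            continue
        hom = af * af
        if af < af_floor:
            flag = "too_rare"
        elif hom > 0 and abs(math.log10(hom / prevalence)) <= math.log10(fit_factor):
            flag = "candidate_fit"
        else:
            flag = "poor_fit"
        out.append(TriagedImpact(impact, af, hom, flag))
    return out
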