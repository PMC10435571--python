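"""Synthetic input bundles with recorded ground truth.

The generator emits everything the mining and cohort pipelines read — a
genome with planted transcription-factor motifs inside gene intervals,
multi-dataset ChIP-seq-like peak sets, a VCF of motif-disrupting SNVs, a
JASPAR-format count matrix, and a cohort table with a dose-dependent
expression effect — plus a JSON manifest of the planted truth.

The default manifest mirrors the shape of a GATA1 blood-group regulome
study: four datasets, two planted motifs 710 bp apart inside one
"CR1-like" blood-group gene, one decoy motif in an excluded transcription
factor gene and one in a non-blood-group gene, a core-disrupting SNV at
minor allele frequency 0.157 plus a very rare one (1.31e-5), and a cohort
of n = 396 drawn from two-locus haplotype frequencies whose locus-1 minor
allele frequency is 0.157.  Expression noise is lognormal for the
flow-cytometry-like MFI readout and Gaussian for the qPCR ddCt readout;
haplotypes are drawn under Hardy-Weinberg random mating.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GeneAnnotation, GenomeSequence, write_fasta, write_gene_bed, \
    write_narrowpeak, write_table, write_vcf_lite
from .peaks import Peak, PeakSet
from .pwm import PositionFrequencyMatrix, build_pwm, reverse_complement, \
    scan_sequence, write_jaspar_pfm
from .variants import Variant

BASES = "ACGT"


def default_pfm() -> PositionFrequencyMatrix:
    """Synthetic GATA-type count matrix (consensus AAGATAAA, WGATAR core).

    This is a synthetic stand-in constructed for simulation and testing; it
    is not a JASPAR database profile.
    """
    counts = np.array(
        [
            #  A    C    G    T
            [110.0, 40.0, 30.0, 20.0],  # weak flank
            [150.0, 5.0, 5.0, 40.0],    # W
            [4.0, 3.0, 190.0, 3.0],     # G
            [194.0, 2.0, 2.0, 2.0],     # A
            [2.0, 2.0, 2.0, 194.0],     # T
            [190.0, 3.0, 4.0, 3.0],     # A
            [140.0, 5.0, 50.0, 5.0],    # R
            [100.0, 30.0, 30.0, 40.0],  # weak flank
        ]
    )
    return PositionFrequencyMatrix(identifier="GATA1SYN.1", counts=counts)


@dataclass(frozen=True)
class GeneSpec:
    symbol: str
    start: int
    end: int
    strand: str
    is_blood_group: bool
    is_excluded_tf: bool


@dataclass(frozen=True)
class PlantedSite:
    """A motif instance written into the genome at a recorded location."""

    position: int  # forward-strand start of the motif interval
    strand: str
    gene: str
    role: str  # candidate / decoy_excluded_tf / decoy_not_blood_group


@dataclass(frozen=True)
class SimulatedSnv:
    position: int
    ref: str
    alt: str
    allele_frequency: float
    identifier: str


def _default_genes() -> list[GeneSpec]:
    return [
        GeneSpec("KLF1L", 5000, 12000, "+", True, True),
        GeneSpec("CR1L", 20000, 45000, "+", True, False),
        GeneSpec("OR4XL", 50000, 55000, "+", False, False),
    ]


def _default_planted() -> list[PlantedSite]:
    # the two candidate motifs sit 710 bp apart inside the CR1-like gene
    return [
        PlantedSite(30000, "+", "CR1L", "candidate"),
        PlantedSite(30710, "-", "CR1L", "candidate"),
        PlantedSite(8000, "+", "KLF1L", "decoy_excluded_tf"),
        PlantedSite(52000, "+", "OR4XL", "decoy_not_blood_group"),
    ]


def _default_snvs() -> list[SimulatedSnv]:
    # simsnv_m2 hits the G of the WGATAR core of the "-"-strand motif
    # (forward base C -> G); simsnv_m1 hits the weak W column of motif 1.
    return [
        SimulatedSnv(30001, "A", "T", 1.31e-5, "simsnv_m1"),
        SimulatedSnv(30715, "C", "G", 0.157, "simsnv_m2"),
    ]


@dataclass
class SimulationManifest:
    """Every tunable of the generator, recorded as ground truth."""

    seed: int = 0
    contig: str = "chrS"
    genome_length: int = 60000
    gc_content: float = 0.41
    genes: list = field(default_factory=_default_genes)
    planted_sites: list = field(default_factory=_default_planted)
    snvs: list = field(default_factory=_default_snvs)
    n_datasets: int = 4
    peak_halfwidth: int = 150
    jitter_sd: float = 20.0
    miss_rate: float = 0.0
    false_peak_counts: tuple = (40, 25, 25, 25)
    scrub_threshold: float = 0.90
    cohort_n: int = 396
    # haplotype frequencies (AB, Ab, aB, ab); locus-1 MAF = p_aB + p_ab =
    # 0.157 and roughly 2.8% of samples are expected to separate the loci
    haplotype_frequencies: tuple = (0.833, 0.010, 0.004, 0.153)
    mfi_log_mean: float = math.log(1000.0)
    mfi_beta: float = 0.5       # log-scale decrease per dose at locus 1
    mfi_sigma: float = 0.3
    ct_beta: float = 1.0        # ddCt cycles per dose at locus 1
    ct_sigma: float = 0.3
    calibrator_delta_ct: float = 4.0
    reference_ct_mean: float = 20.0
    ct_tech_spread: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.miss_rate < 1:
            raise ValueError("miss_rate must lie in [0, 1)")
        if len(self.false_peak_counts) != self.n_datasets:
            raise ValueError("false_peak_counts must have one entry per dataset")
        hf = np.asarray(self.haplotype_frequencies, dtype=float)
        if hf.shape != (4,) or np.any(hf < 0) or abs(hf.sum() - 1) > 1e-9:
            raise ValueError("haplotype frequencies must be 4 non-negatives summing to 1")
        for site in self.planted_sites:
            if not 0 <= site.position < self.genome_length:
                raise ValueError(f"planted site at {site.position} outside the genome")
        if self.cohort_n < 10:
            raise ValueError("cohort_n must be at least 10")

    @property
    def locus1_maf(self) -> float:
        return self.haplotype_frequencies[2] + self.haplotype_frequencies[3]

    def dataset_ids(self) -> list[str]:
        return [f"d{i + 1}" for i in range(self.n_datasets)]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationManifest":
        data = json.loads(text)
        data["genes"] = [GeneSpec(**g) for g in data["genes"]]
        data["planted_sites"] = [PlantedSite(**s) for s in data["planted_sites"]]
        data["snvs"] = [SimulatedSnv(**v) for v in data["snvs"]]
        data["false_peak_counts"] = tuple(data["false_peak_counts"])
        data["haplotype_frequencies"] = tuple(data["haplotype_frequencies"])
        return cls(**data)


def _child_rngs(manifest: SimulationManifest) -> dict:
    children = np.random.SeedSequence(manifest.seed).spawn(3)
    return {
        "genome": np.random.default_rng(children[0]),
        "peaks": np.random.default_rng(children[1]),
        "cohort": np.random.default_rng(children[2]),
    }


def _motif_intervals(manifest: SimulationManifest, motif_length: int):
    return [(s.position, s.position + motif_length) for s in manifest.planted_sites]


def simulate_genome(
    manifest: SimulationManifest, pfm: PositionFrequencyMatrix | None = None
):
    """Background sequence at the stated GC content with consensus motif
    instances written at the recorded positions and strands.

    Non-planted windows that would scan above ``scrub_threshold`` are
    disrupted so the planted sites are the only strong matches, keeping the
    truth table unambiguous.  Overlapping planted motifs are an error.
    """
    pfm = pfm or default_pfm()
    L = pfm.length
    intervals = sorted(_motif_intervals(manifest, L))
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError(f"planted motifs overlap: [{s1},{e1}) and [{s2},{e2})")
    gene_by_symbol = {g.symbol: g for g in manifest.genes}
    for site in manifest.planted_sites:
        g = gene_by_symbol[site.gene]
        if not (g.start <= site.position and site.position + L <= g.end):
            raise ValueError(f"planted site {site} outside gene {g.symbol}")

    rng = _child_rngs(manifest)["genome"]
    gc = manifest.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = list(rng.choice(list(BASES), size=manifest.genome_length, p=probs))
    consensus = pfm.consensus()
    for site in manifest.planted_sites:
        motif = consensus if site.strand == "+" else reverse_complement(consensus)
        seq[site.position : site.position + L] = list(motif)

    pwm = build_pwm(pfm)
    planted = _motif_intervals(manifest, L)

    def spurious(hits):
        return [
            h for h in hits
            if not any(h.start < e and s < h.end for s, e in planted)
        ]

    for _ in range(50):
        genome = GenomeSequence(name=manifest.contig, sequence="".join(seq))
        offenders = spurious(
            scan_sequence(pwm, genome, threshold=manifest.scrub_threshold,
                          with_pvalues=False)
        )
        if not offenders:
            break
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for h in offenders:
            # break the match at a base that lies outside every planted
            # motif, switching it to the scanned column's worst base
            free = [p for p in range(h.start, h.end)
                    if not any(s <= p < e for s, e in planted)]
            pos = min(free, key=lambda p: abs(p - (h.start + L // 2)))
            col = pos - h.start if h.strand == "+" else L - 1 - (pos - h.start)
            worst = BASES[int(np.argmin(pwm.weights[col]))]
            seq[pos] = worst if h.strand == "+" else comp[worst]
    else:  # pragma: no cover
        raise RuntimeError("could not scrub spurious motif matches")

    annotation = [
        GeneAnnotation(symbol=g.symbol, contig=manifest.contig, start=g.start,
                       end=g.end, strand=g.strand, is_blood_group=g.is_blood_group,
                       is_excluded_tf=g.is_excluded_tf)
        for g in manifest.genes
    ]
    return genome, annotation, list(manifest.planted_sites)


def simulate_peaksets(
    manifest: SimulationManifest,
    planted: list[PlantedSite] | None = None,
    motif_length: int | None = None,
) -> list[PeakSet]:
    """K peak sets: every planted site yields a jittered peak per dataset
    (guaranteed to cover the motif; the first dataset never drops a site, the
    others drop with the miss rate), plus false peaks in motif-free regions
    that never overlap a planted motif.  True-site scores are stochastically
    higher than false-peak scores."""
    planted = planted if planted is not None else manifest.planted_sites
    L = motif_length or default_pfm().length
    rng = _child_rngs(manifest)["peaks"]
    motif_iv = [(s.position, s.position + L) for s in planted]
    half = manifest.peak_halfwidth
    peaksets = []
    for i, ds in enumerate(manifest.dataset_ids()):
        peaks = []
        for j, site in enumerate(planted):
            missed = rng.random() < manifest.miss_rate
            if i > 0 and missed:
                continue
            center = site.position + L // 2
            start = center - half + int(round(rng.normal(0, manifest.jitter_sd)))
            end = center + half + int(round(rng.normal(0, manifest.jitter_sd)))
            start = max(0, min(start, site.position - 1))
            end = min(manifest.genome_length, max(end, site.position + L + 1))
            peaks.append(
                Peak(contig=manifest.contig, start=start, end=end,
                     name=f"{ds}_true_{j}", score=float(rng.uniform(600, 1000)),
                     summit=center)
            )
        for j in range(manifest.false_peak_counts[i]):
            for _ in range(1000):
                width = int(rng.integers(200, 401))
                start = int(rng.integers(0, manifest.genome_length - width))
                end = start + width
                if not any(start < e and s < end for s, e in motif_iv):
                    break
            else:  # pragma: no cover
                raise RuntimeError("no motif-free region for a false peak")
            peaks.append(
                Peak(contig=manifest.contig, start=start, end=end,
                     name=f"{ds}_false_{j}", score=float(rng.uniform(100, 400)))
            )
        peaksets.append(PeakSet(dataset_id=ds, peaks=peaks))
    return peaksets


def simulate_cohort(manifest: SimulationManifest) -> pd.DataFrame:
    """Cohort table drawn under Hardy-Weinberg random mating.

    Two haplotypes per sample are drawn i.i.d. from the manifest
    frequencies; geometric MFI decreases lognormally with the locus-1 dose
    and ddCt increases by ``ct_beta`` cycles per locus-1 dose.  The locus-2
    dose has no direct effect — any association it shows arises only through
    linkage with locus 1.  Ct triplicates are constructed so that the
    standard ddCt normalization recovers the sampled ddCt value exactly.
    """
    rng = _child_rngs(manifest)["cohort"]
    n = manifest.cohort_n
    haps = rng.choice(4, size=(n, 2), p=np.asarray(manifest.haplotype_frequencies))
    # haplotype codes: 0=AB 1=Ab 2=aB 3=ab (minor alleles: a at locus 1, b at locus 2)
    dose1 = np.isin(haps, (2, 3)).sum(axis=1)
    dose2 = np.isin(haps, (1, 3)).sum(axis=1)
    mfi = np.exp(
        manifest.mfi_log_mean - manifest.mfi_beta * dose1
        + rng.normal(0, manifest.mfi_sigma, n)
    )
    ddct = manifest.ct_beta * dose1 + rng.normal(0, manifest.ct_sigma, n)
    ref_mean = manifest.reference_ct_mean + rng.normal(0, 0.3, n)
    target_mean = ref_mean + manifest.calibrator_delta_ct + ddct
    spread = manifest.ct_tech_spread * np.array([-1.0, 0.0, 1.0])
    rows = {
        "sample_id": [f"S{i + 1:04d}" for i in range(n)],
        "dose_locus1": dose1,
        "dose_locus2": dose2,
        "mfi_geometric": mfi,
    }
    for k in range(3):
        rows[f"ct_target_{k + 1}"] = target_mean + spread[k]
    for k in range(3):
        rows[f"ct_ref_{k + 1}"] = ref_mean + spread[k]
    return pd.DataFrame(rows)


def write_bundle(manifest: SimulationManifest, outdir) -> dict:
    """Write the complete synthetic input bundle; returns the path map.

    Identical manifests produce byte-identical bundles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pfm = default_pfm()
    genome, annotation, planted = simulate_genome(manifest, pfm)
    peaksets = simulate_peaksets(manifest, planted, pfm.length)
    cohort = simulate_cohort(manifest)

    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.bed",
        "pwm": outdir / "motif.jaspar",
        "vcf": outdir / "variants.vcf",
        "cohort": outdir / "cohort.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_fasta([genome], paths["genome"])
    write_gene_bed(annotation, paths["genes"])
    write_jaspar_pfm(pfm, paths["pwm"])
    variants = [
        Variant(contig=manifest.contig, position=v.position, ref=v.ref, alt=v.alt,
                identifier=v.identifier, allele_frequency=v.allele_frequency)
        for v in manifest.snvs
    ]
    write_vcf_lite(variants, paths["vcf"],
                   contigs={manifest.contig: manifest.genome_length})
    write_table(
        cohort, paths["cohort"],
        meta={"seed": manifest.seed,
              "calibrator_delta_ct": manifest.calibrator_delta_ct},
    )
    paths["peaks"] = {}
    for ps in peaksets:
        p = outdir / f"peaks_{ps.dataset_id}.narrowPeak"
        write_narrowpeak(ps, p)
        paths["peaks"][ps.dataset_id] = p
    paths["manifest"].write_text(manifest.to_json() + "\n")
    return paths
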