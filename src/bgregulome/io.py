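"""File-format readers and writers, run configuration and logging.

Formats covered: FASTA (via Bio.SeqIO), ENCODE narrowPeak / BED6 peak files,
a BED6+2 gene annotation with blood-group and excluded-transcription-factor
flags, a single-sample-free VCF 4.x subset (via cyvcf2, SNVs only) and
tab-separated report tables with a commented ``# key=value`` header.

All internal coordinates are 0-based half-open; BED/narrowPeak are native
and VCF positions are converted on read/write.  Malformed records are
skipped and counted rather than fatal, except for structural corruption.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peaks import Peak, PeakSet
from .variants import Variant

logger = logging.getLogger("bgregulome.io")

_DNA_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """A file is structurally malformed."""


@dataclass
class GenomeSequence:
    """One contig: a name and an uppercase DNA string over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.name:
            raise ValueError("contig name must be non-empty")
        if not self.sequence:
            raise ValueError(f"contig {self.name!r} has an empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ParseError(
                f"illegal character(s) {sorted(bad)} in sequence {self.name!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval with blood-group / excluded-TF flags (BED6+2)."""

    symbol: str
    contig: str
    start: int
    end: int
    strand: str
    is_blood_group: bool = False
    is_excluded_tf: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.symbol}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.symbol}: strand must be '+' or '-'")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[GenomeSequence]:
    """Read all records; lowercase input is accepted and uppercased."""
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(GenomeSequence(name=rec.id, sequence=str(rec.seq)))
    except (ValueError, FileNotFoundError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise ParseError(f"malformed FASTA {path}: {exc}") from exc
    return records


def write_fasta(sequences, path) -> None:
    recs = [
        SeqRecord(Seq(s.sequence), id=s.name, description="") for s in sequences
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# narrowPeak / BED6 peak files

def _fmt(value, default="-1") -> str:
    if value is None:
        return default
    return f"{value:g}"


def read_narrowpeak(path, dataset_id: str) -> PeakSet:
    """Read a 6-column BED or 10-column narrowPeak file.

    Records with start >= end are rejected with a counted warning; a
    non-numeric score is a parse error naming the line.
    """
    peaks = []
    n_rejected = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) not in (6, 10):
                raise ParseError(
                    f"{path} line {lineno}: expected 6 or 10 columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ParseError(f"{path} line {lineno}: non-integer coordinates") from None
            try:
                score = float(cols[4])
            except ValueError:
                raise ParseError(f"{path} line {lineno}: non-numeric score {cols[4]!r}") from None
            if start >= end:
                n_rejected += 1
                logger.warning(
                    "%s line %d: rejected inverted interval [%d, %d)", path, lineno, start, end
                )
                continue
            kwargs = {}
            if len(cols) == 10:
                kwargs["signal_value"] = float(cols[6])
                kwargs["p_value"] = float(cols[7])
                kwargs["q_value"] = float(cols[8])
                offset = int(cols[9])
                kwargs["summit"] = start + offset if offset >= 0 else None
            peaks.append(
                Peak(contig=cols[0], start=start, end=end, name=cols[3],
                     score=score, strand=cols[5], **kwargs)
            )
    return PeakSet(dataset_id=dataset_id, peaks=peaks, n_rejected=n_rejected)


def write_narrowpeak(peakset: PeakSet, path) -> None:
    """Write 10-column narrowPeak (summit offset -1 when unknown)."""
    with open(path, "w") as out:
        for p in peakset.peaks:
            offset = p.summit - p.start if p.summit is not None else -1
            out.write(
                "\t".join(
                    [
                        p.contig, str(p.start), str(p.end), p.name, f"{p.score:g}",
                        p.strand, _fmt(p.signal_value), _fmt(p.p_value),
                        _fmt(p.q_value), str(offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene annotation (BED6 + is_blood_group + is_excluded_tf)

def read_gene_bed(path) -> list[GeneAnnotation]:
    genes = []
    seen = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) != 8:
                raise ParseError(f"{path} line {lineno}: expected 8 columns, got {len(cols)}")
            symbol = cols[3]
            if symbol in seen:
                raise ParseError(f"{path} line {lineno}: duplicate gene symbol {symbol!r}")
            seen.add(symbol)
            genes.append(
                GeneAnnotation(
                    symbol=symbol, contig=cols[0], start=int(cols[1]), end=int(cols[2]),
                    strand=cols[5], is_blood_group=cols[6] == "1",
                    is_excluded_tf=cols[7] == "1",
                )
            )
    return genes


def write_gene_bed(genes, path) -> None:
    with open(path, "w") as out:
        for g in genes:
            out.write(
                "\t".join(
                    [g.contig, str(g.start), str(g.end), g.symbol, "0", g.strand,
                     "1" if g.is_blood_group else "0",
                     "1" if g.is_excluded_tf else "0"]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF (read-only SNV subset via cyvcf2, plus a minimal writer)

class VariantList(list):
    """Variants read from a VCF, with skip/reject counters."""

    def __init__(self, items=(), n_skipped_indels: int = 0, n_rejected: int = 0):
        super().__init__(items)
        self.n_skipped_indels = n_skipped_indels
        self.n_rejected = n_rejected


def read_vcf_lite(path) -> VariantList:
    """Read single-nucleotide variants from a VCF 4.x file.

    Positions become 0-based, multi-allelic records are split, indels are
    skipped with a counted warning, and REF = ALT records are rejected.
    The gnomAD-style AF INFO field is carried when present.
    """
    from cyvcf2 import VCF

    if not Path(path).exists():
        raise FileNotFoundError(path)
    out = VariantList()
    for rec in VCF(str(path)):
        af = rec.INFO.get("AF")
        afs = af if isinstance(af, tuple) else (af,) * max(1, len(rec.ALT))
        for i, alt in enumerate(rec.ALT):
            if len(rec.REF) != 1 or len(alt) != 1 or {rec.REF, alt} - set("ACGT"):
                out.n_skipped_indels += 1
                continue
            if rec.REF == alt:
                out.n_rejected += 1
                logger.warning("%s: rejected REF=ALT record at %s:%d", path, rec.CHROM, rec.POS)
                continue
            this_af = afs[i] if i < len(afs) else None
            out.append(
                Variant(
                    contig=rec.CHROM,
                    position=rec.POS - 1,
                    ref=rec.REF,
                    alt=alt,
                    identifier=rec.ID,
                    allele_frequency=float(this_af) if this_af is not None else None,
                )
            )
    if out.n_skipped_indels:
        logger.info("%s: skipped %d non-SNV allele(s)", path, out.n_skipped_indels)
    return out


def write_vcf_lite(variants, path, contigs=None) -> None:
    """Write SNVs as a minimal VCF 4.2 file (AF in INFO when known)."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        for name, length in (contigs or {}).items():
            out.write(f"##contig=<ID={name},length={length}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.contig, v.position)):
            info = f"AF={v.allele_frequency:g}" if v.allele_frequency is not None else "."
            out.write(
                f"{v.contig}\t{v.position + 1}\t{v.identifier or '.'}\t"
                f"{v.ref}\t{v.alt}\t.\t.\t{info}\n"
            )


# ---------------------------------------------------------------------------
# commented-header report tables

def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a TSV preceded by ``# key=value`` comment lines."""
    with open(path, "w") as out:
        for key, value in (meta or {}).items():
            out.write(f"# {key}={value}\n")
        df.to_csv(out, sep="\t", index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    lines = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("# ") and "=" in line:
                key, _, value = line[2:].rstrip("\n").partition("=")
                meta[key] = value
            else:
                lines.append(line)
    df = pd.read_csv(_stdio.StringIO("".join(lines)), sep="\t")
    return df, meta


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Resolved parameters of a mining run; hashed into every output header."""

    peaks: dict = field(default_factory=dict)  # dataset_id -> path
    genome: str | None = None
    genes: str | None = None
    pwm: str | None = None
    vcf: str | None = None
    pseudocount: float = 0.8
    background: tuple = (0.25, 0.25, 0.25, 0.25)
    rel_threshold: float = 0.8
    min_overlap: int = 2
    upstream_window: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if not 0 <= self.rel_threshold <= 1:
            raise ValueError("rel_threshold must lie in [0, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be at least 1")
        if self.upstream_window < 0:
            raise ValueError("upstream_window must be non-negative")
        if len(self.background) != 4 or abs(sum(self.background) - 1) > 1e-9:
            raise ValueError("background must be 4 probabilities summing to 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "background" in data:
            data["background"] = tuple(data["background"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["background"] = list(self.background)
        return d

    @property
    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def header_meta(self) -> dict:
        from . import __version__

        return {"config_hash": self.hash, "seed": self.seed, "bgregulome_version": __version__}
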