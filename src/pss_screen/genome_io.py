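"""Locus/interval/variant data model and readers/writers for the formats the pipeline touches.

Coordinate convention: 0-based, half-open everywhere in memory. BEDPE anchors
are written as single-base intervals at the first rearranged base (left) and
last rearranged base (right), so ``left_bp = anchor1.start`` and
``right_bp = anchor2.start + 1``. Small-variant tables carry a 1-based POS on
disk and are converted on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
SV_TYPES = frozenset({"DEL", "INV", "DUP", "TRA"})
SMALL_VARIANT_CLASSES = frozenset({"SNV", "INS", "DEL"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeIOError(ValueError):
    """Raised on malformed inputs or contract violations."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class LocusReference:
    """Single-locus reference sequence plus its interval annotations.

    ``partners`` holds auxiliary contig sequences (translocation partners)
    keyed by contig name; the main locus is addressed by ``name``.
    """

    name: str
    sequence: str
    exons: list[GenomicInterval] = field(default_factory=list)
    amplicons: list[GenomicInterval] = field(default_factory=list)
    annotations: list[GenomicInterval] = field(default_factory=list)
    partners: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = _validate_sequence(self.sequence)
        for ex in self.exons:
            if ex.end > len(self.sequence):
                raise GenomeIOError(f"exon {ex.label} outside locus")
        srt = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(srt, srt[1:]):
            if a.end > b.start:
                raise GenomeIOError(f"overlapping exons {a.label}/{b.label}")
        self.exons = srt

    def contig_sequence(self, contig: str) -> str:
        if contig == self.name:
            return self.sequence
        try:
            return self.partners[contig]
        except KeyError:
            raise GenomeIOError(f"unknown contig {contig!r}") from None


@dataclass(frozen=True)
class StructuralVariant:
    """One rearrangement call: two breakpoints delimiting the rearranged segment.

    ``left_bp`` is the first rearranged base, ``right_bp`` one past the last
    (half-open). For TRA, ``right_bp`` lives on ``partner_contig``.
    """

    id: str
    svtype: str
    left_bp: int
    right_bp: int
    partner_contig: str = ""
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise GenomeIOError(f"unknown svtype {self.svtype!r}")
        if self.svtype != "TRA" and not self.left_bp < self.right_bp:
            raise GenomeIOError(
                f"{self.id}: left_bp must precede right_bp for {self.svtype}"
            )


@dataclass(frozen=True)
class SmallVariant:
    pos: int  # 0-based
    ref: str
    alt: str
    supporting_reads: int
    total_reads: int
    vclass: str

    def __post_init__(self) -> None:
        if not (0 <= self.supporting_reads <= self.total_reads):
            raise GenomeIOError("supporting_reads must be within [0, total_reads]")
        if self.ref == self.alt:
            raise GenomeIOError("ref == alt")
        if self.vclass not in SMALL_VARIANT_CLASSES:
            raise GenomeIOError(f"unknown variant class {self.vclass!r}")


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise GenomeIOError(f"illegal sequence characters: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; involution by construction."""
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise GenomeIOError(f"illegal sequence characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> LocusReference:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise GenomeIOError(f"{path}: no FASTA records (empty file?)")
    if len(records) > 1:
        raise GenomeIOError(f"{path}: {len(records)} records; ambiguous locus")
    rec = records[0]
    return LocusReference(name=rec.id, sequence=str(rec.seq))


def write_fasta(locus: LocusReference, path: str | Path) -> None:
    records = [SeqRecord(Seq(locus.sequence), id=locus.name, description="")]
    for name in sorted(locus.partners):
        records.append(SeqRecord(Seq(locus.partners[name]), id=name, description=""))
    # partners, when present, are written to a sibling file so the locus FASTA
    # stays single-record
    if locus.partners:
        SeqIO.write(records[:1], str(path), "fasta")
        SeqIO.write(records[1:], str(Path(path).with_suffix(".partners.fa")), "fasta")
    else:
        SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise GenomeIOError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise GenomeIOError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise GenomeIOError(f"{path}:{lineno}: invalid interval {start}-{end}")
            label = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "+"
            intervals.append(GenomicInterval(cols[0], start, end, strand, label))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# BEDPE


def read_bedpe(path: str | Path, default_contig: str | None = None) -> list[StructuralVariant]:
    """Read SV calls from BEDPE (anchor1 cols 1-3, anchor2 cols 4-6, name col 7,
    svtype col 9, cohort col 10 when present)."""
    svs: list[StructuralVariant] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise GenomeIOError(f"{path}:{lineno}: expected >=9 BEDPE columns")
            contig1, contig2 = cols[0], cols[3]
            try:
                a1_start = int(cols[1])
                a2_start = int(cols[4])
            except ValueError:
                raise GenomeIOError(f"{path}:{lineno}: non-integer coordinates") from None
            svtype = cols[8]
            if svtype not in SV_TYPES:
                raise GenomeIOError(f"{path}:{lineno}: unknown svtype {svtype!r}")
            left_bp = a1_start
            right_bp = a2_start + 1
            partner = contig2 if contig2 != contig1 else ""
            if svtype != "TRA" and partner:
                raise GenomeIOError(
                    f"{path}:{lineno}: intra-locus svtype {svtype} with two contigs"
                )
            if svtype != "TRA" and left_bp >= right_bp:
                raise GenomeIOError(
                    f"{path}:{lineno}: anchors out of order for intra-locus SV"
                )
            cohort = cols[9] if len(cols) > 9 else ""
            svs.append(
                StructuralVariant(
                    id=cols[6],
                    svtype=svtype,
                    left_bp=left_bp,
                    right_bp=right_bp,
                    partner_contig=partner,
                    cohort=cohort,
                )
            )
    return svs


def write_bedpe(svs: Iterable[StructuralVariant], path: str | Path, contig: str) -> None:
    with open(path, "w") as fh:
        for sv in svs:
            c2 = sv.partner_contig or contig
            fh.write(
                "\t".join(
                    [
                        contig,
                        str(sv.left_bp),
                        str(sv.left_bp + 1),
                        c2,
                        str(sv.right_bp - 1),
                        str(sv.right_bp),
                        sv.id,
                        "0",
                        sv.svtype,
                        sv.cohort,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Small variants: TSV dialect and minimal VCF 4.2 body with AD in FORMAT


def _classify_small(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNV"
    return "INS" if len(alt) > len(ref) else "DEL"


def read_small_variants(path: str | Path) -> list[SmallVariant]:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return _read_small_variants_vcf(path)
    return _read_small_variants_tsv(path)


def _read_small_variants_tsv(path: str | Path) -> list[SmallVariant]:
    out: list[SmallVariant] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = ("pos", "ref", "alt", "supporting_reads", "total_reads")
        missing = [c for c in required if c not in idx]
        if missing:
            raise GenomeIOError(f"{path}: missing columns {missing}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            pos1 = int(cols[idx["pos"]])
            if pos1 < 1:
                raise GenomeIOError(f"{path}:{lineno}: POS must be 1-based positive")
            ref, alt = cols[idx["ref"]], cols[idx["alt"]]
            out.append(
                SmallVariant(
                    pos=pos1 - 1,
                    ref=ref,
                    alt=alt,
                    supporting_reads=int(cols[idx["supporting_reads"]]),
                    total_reads=int(cols[idx["total_reads"]]),
                    vclass=cols[idx["vclass"]] if "vclass" in idx else _classify_small(ref, alt),
                )
            )
    return out


def _read_small_variants_vcf(path: str | Path) -> list[SmallVariant]:
    out: list[SmallVariant] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise GenomeIOError(f"{path}:{lineno}: VCF body needs FORMAT+sample")
            pos1 = int(cols[1])
            ref, alt = cols[3], cols[4]
            fmt = cols[8].split(":")
            if "AD" not in fmt:
                raise GenomeIOError(f"{path}:{lineno}: AD missing from FORMAT")
            sample = cols[9].split(":")
            ad = sample[fmt.index("AD")].split(",")
            ref_depth, alt_depth = int(ad[0]), int(ad[1])
            out.append(
                SmallVariant(
                    pos=pos1 - 1,
                    ref=ref,
                    alt=alt,
                    supporting_reads=alt_depth,
                    total_reads=ref_depth + alt_depth,
                    vclass=_classify_small(ref, alt),
                )
            )
    return out


def write_small_variants(variants: Iterable[SmallVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tref\talt\tsupporting_reads\ttotal_reads\tvclass\n")
        for v in variants:
            fh.write(
                f"{v.pos + 1}\t{v.ref}\t{v.alt}\t{v.supporting_reads}\t"
                f"{v.total_reads}\t{v.vclass}\n"
            )


# ---------------------------------------------------------------------------
# Amplicon tiling


def tile_amplicons(
    locus: LocusReference,
    min_span: int,
    max_span: int,
    overlap: int = 200,
) -> list[GenomicInterval]:
    """Tile the locus with overlapping amplicons of span within [min_span, max_span].

    Spans are equalized so every amplicon except possibly the last lies in the
    requested range; adjacent amplicons overlap by ``overlap`` bases; the union
    covers every base.
    """
    n = len(locus.sequence)
    if not (0 < min_span <= max_span):
        raise GenomeIOError("need 0 < min_span <= max_span")
    if min_span > n:
        raise GenomeIOError("locus shorter than min_span")
    if overlap >= min_span:
        raise GenomeIOError("overlap must be smaller than min_span")
    if n <= max_span:
        return [GenomicInterval(locus.name, 0, n, "+", "amplicon_1")]
    step = max_span - overlap
    k = -(-(n - overlap) // step)  # ceil
    span = -(-(n + (k - 1) * overlap) // k)
    span = max(span, min_span)
    out: list[GenomicInterval] = []
    for i in range(k):
        start = i * (span - overlap)
        end = min(start + span, n)
        if end <= start:
            break
        out.append(GenomicInterval(locus.name, start, end, "+", f"amplicon_{i + 1}"))
        if end == n:
            break
    return out
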