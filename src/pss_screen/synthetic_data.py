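"""Synthetic single-gene locus, SV cohorts with planted inverted-repeat elements,
and windowed small-variant counts.

Everything is driven by a seeded ``numpy.random.Generator`` so that runs are
bit-deterministic given the config. Elements are planted by overwriting
reference bases (not inserting), keeping SV coordinates valid: the element copy
is written at the left breakpoint reading inward, and its reverse complement
ends at the right breakpoint, so the inward flanks of a planted SV both begin
with the element sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .genome_io import (
    GenomicInterval,
    LocusReference,
    SmallVariant,
    StructuralVariant,
    reverse_complement,
)
from .pss_detection import has_disqualifying_repeat

BASES = np.array(["A", "C", "G", "T"])

WINDOW_LEN = 40  # non-overlapping tiling used for small-variant counts


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    seed: int
    locus_len: int = 43_000
    n_exons: int = 9
    gc: float = 0.41
    n_sv_case: int = 20
    n_sv_control: int = 20
    sv_type_weights: dict[str, float] = field(
        default_factory=lambda: {"DEL": 0.4, "INV": 0.3, "DUP": 0.2, "TRA": 0.1}
    )
    planted_fraction: float = 1.0
    motif_len: int = 13
    motif_terminal: str = "GGG"
    motif_t_free: bool = True
    motif_noise: float = 0.0
    flank_window: int = 20
    snv_rate_exon: float = 0.5
    snv_rate_intron: float = 0.5
    selected_exon_boost: float = 5.0
    min_segment: int = 500
    max_segment: int = 10_000
    partner_len: int = 5_000
    read_depth: int = 1_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        for p in (self.planted_fraction, self.motif_noise, self.gc):
            if not (0.0 <= p <= 1.0):
                raise SimulationError("probabilities must lie in [0, 1]")
        total = sum(self.sv_type_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError("sv_type_weights must sum to 1")
        if self.motif_len >= self.flank_window:
            raise SimulationError("motif_len must be smaller than flank_window")
        if self.motif_len < 6:
            raise SimulationError("motif_len must be >= 6")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise SimulationError("config missing mandatory seed")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass(frozen=True)
class PlantedTruth:
    sv_id: str
    planted: bool
    motif_seq: str = ""
    left_copy_interval: GenomicInterval | None = None
    right_copy_interval: GenomicInterval | None = None


# ---------------------------------------------------------------------------
# Locus


def simulate_locus(config: SimulationConfig) -> LocusReference:
    """Random locus with the target GC content and disjoint exon intervals.

    Exons are 60-300 bp, separated by at least 500 bp, and kept at least 500 bp
    from the locus ends.
    """
    rng = np.random.default_rng(config.seed)
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    seq = "".join(rng.choice(BASES, size=config.locus_len, p=p))

    margin, min_gap = 500, 500
    lengths = rng.integers(60, 301, size=config.n_exons)
    slack = (
        config.locus_len
        - 2 * margin
        - int(lengths.sum())
        - (config.n_exons - 1) * min_gap
    )
    if slack < 0:
        raise SimulationError("locus too short to place exons")
    extra = rng.multinomial(slack, np.full(config.n_exons + 1, 1 / (config.n_exons + 1)))
    exons: list[GenomicInterval] = []
    pos = margin
    for i, length in enumerate(lengths):
        pos += int(extra[i])
        exons.append(
            GenomicInterval("locus", pos, pos + int(length), "+", f"exon_{i + 1}")
        )
        pos += int(length) + min_gap
    return LocusReference(name="locus", sequence=seq, exons=exons)


# ---------------------------------------------------------------------------
# Planted elements


def make_pss_element(config: SimulationConfig, rng: np.random.Generator) -> str:
    """One element sequence in inward (breakpoint-anchored) orientation.

    The first bases are the reverse complement of ``motif_terminal`` so that,
    after reporting-orientation conversion, the terminal trinucleotide lands at
    the breakpoint-proximal (3') end. T is excluded when ``motif_t_free`` and
    the result never contains a disqualifying repeat.
    """
    prefix = reverse_complement(config.motif_terminal)
    alphabet = np.array(["A", "C", "G"]) if config.motif_t_free else BASES
    body_len = config.motif_len - len(prefix)
    for _ in range(10_000):
        body = "".join(rng.choice(alphabet, size=body_len))
        elem = prefix + body
        if config.motif_t_free and "T" in elem:
            continue
        if not has_disqualifying_repeat(elem, 5):
            return elem
    raise SimulationError("could not generate a repeat-free element")


def _apply_noise(seq: str, noise: float, rng: np.random.Generator) -> str:
    if noise <= 0:
        return seq
    chars = list(seq)
    hits = rng.random(len(chars)) < noise
    for i in np.flatnonzero(hits):
        others = [b for b in "ACGT" if b != chars[i]]
        chars[i] = others[int(rng.integers(0, 3))]
    return "".join(chars)


def _straddles_exon_boundary(
    start: int, end: int, exons: Sequence[GenomicInterval]
) -> bool:
    for ex in exons:
        if ex.overlaps(start, end) and not (ex.start <= start and end <= ex.end):
            return True
    return False


def plant_structural_variants(
    locus: LocusReference, config: SimulationConfig
) -> tuple[LocusReference, list[StructuralVariant], list[PlantedTruth]]:
    """Draw case and control SV cohorts and plant elements into the case cohort.

    Rearranged segments are 500-10,000 bp and breakpoints stay clear of locus
    ends. Breakpoint neighborhoods (one flank window to each side) are mutually
    disjoint across both cohorts so that planted copies never collide; whole
    segments may overlap, as real call sets do. Planted element copies never
    straddle an exon boundary.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_total = config.n_sv_case + config.n_sv_control
    w = config.flank_window
    types = list(config.sv_type_weights)
    weights = np.array([config.sv_type_weights[t] for t in types])

    seq = list(locus.sequence)
    partners: dict[str, str] = {}
    occupied: list[tuple[int, int]] = []
    svs: list[StructuralVariant] = []
    truths: list[PlantedTruth] = []

    def collides(left: int, right: int) -> bool:
        for bp in (left, right):
            for obp in occupied:
                if abs(bp - obp) < 2 * w:
                    return True
        return False

    planted_flags = rng.random(config.n_sv_case) < config.planted_fraction

    for k in range(n_total):
        cohort = "case" if k < config.n_sv_case else "control"
        sv_id = f"{cohort}_sv_{(k if cohort == 'case' else k - config.n_sv_case) + 1}"
        svtype = str(rng.choice(types, p=weights))
        placed = False
        for _ in range(10_000):
            seg_len = int(rng.integers(config.min_segment, config.max_segment + 1))
            hi = config.locus_len - seg_len - w
            if hi <= w:
                continue
            left = int(rng.integers(w, hi))
            right = left + seg_len
            if collides(left, right):
                continue
            if _straddles_exon_boundary(left, left + config.motif_len, locus.exons):
                continue
            if _straddles_exon_boundary(right - config.motif_len, right, locus.exons):
                continue
            placed = True
            break
        if not placed:
            raise SimulationError("cannot place SVs with disjoint breakpoint windows")
        occupied.extend((left, right))

        partner = ""
        if svtype == "TRA":
            partner = f"partner_{sv_id}"
            p_gc = np.array(
                [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
            )
            partners[partner] = "".join(
                rng.choice(BASES, size=config.partner_len, p=p_gc)
            )
            # right anchor sits mid-partner; left anchor keeps its locus position
            right = config.partner_len // 2

        sv = StructuralVariant(
            id=sv_id,
            svtype=svtype,
            left_bp=left,
            right_bp=right,
            partner_contig=partner,
            cohort=cohort,
        )
        svs.append(sv)

        planted = cohort == "case" and bool(planted_flags[k]) if k < config.n_sv_case else False
        if planted:
            m = config.motif_len
            # inward flank context beyond the element; a chance-matched prefix
            # of these would extend a perfect-identity alignment, so redraw the
            # element if element+matched-context carries a disqualifying repeat
            left_ctx = "".join(seq[left + m : left + w])
            if partner:
                right_ctx = reverse_complement(partners[partner][right - w : right - m])
            else:
                right_ctx = reverse_complement("".join(seq[right - w : right - m]))
            lcp = 0
            while (
                lcp < len(left_ctx)
                and lcp < len(right_ctx)
                and left_ctx[lcp] == right_ctx[lcp]
            ):
                lcp += 1
            for _ in range(1_000):
                elem = make_pss_element(config, rng)
                if not has_disqualifying_repeat(elem + left_ctx[:lcp], 5):
                    break
            else:
                raise SimulationError("could not plant a repeat-safe element")
            left_copy = _apply_noise(elem, config.motif_noise, rng)
            right_copy = _apply_noise(elem, config.motif_noise, rng)
            seq[left : left + m] = left_copy
            rc = reverse_complement(right_copy)
            if partner:
                ps = list(partners[partner])
                ps[right - m : right] = rc
                partners[partner] = "".join(ps)
                right_iv = GenomicInterval(partner, right - m, right, "-", sv_id)
            else:
                seq[right - m : right] = rc
                right_iv = GenomicInterval(locus.name, right - m, right, "-", sv_id)
            truths.append(
                PlantedTruth(
                    sv_id=sv_id,
                    planted=True,
                    motif_seq=elem,
                    left_copy_interval=GenomicInterval(
                        locus.name, left, left + m, "+", sv_id
                    ),
                    right_copy_interval=right_iv,
                )
            )
        else:
            truths.append(PlantedTruth(sv_id=sv_id, planted=False))

    out = LocusReference(
        name=locus.name,
        sequence="".join(seq),
        exons=list(locus.exons),
        amplicons=list(locus.amplicons),
        annotations=list(locus.annotations),
        partners=partners,
    )
    return out, svs, truths


# ---------------------------------------------------------------------------
# Small variants


def simulate_small_variants(
    locus: LocusReference, config: SimulationConfig, condition: str
) -> list[SmallVariant]:
    """Per-40-bp-window Poisson event counts with an exonic boost under selection."""
    if condition not in ("unselected", "selected"):
        raise SimulationError(f"unknown condition {condition!r}")
    offset = 1_000 if condition == "unselected" else 2_000
    rng = np.random.default_rng(config.seed + offset)
    n = len(locus.sequence)
    variants: list[SmallVariant] = []
    for start in range(0, n, WINDOW_LEN):
        end = min(start + WINDOW_LEN, n)
        exonic = any(ex.overlaps(start, end) for ex in locus.exons)
        rate = config.snv_rate_exon if exonic else config.snv_rate_intron
        if exonic and condition == "selected":
            rate *= config.selected_exon_boost
        count = int(rng.poisson(rate))
        for _ in range(count):
            pos = int(rng.integers(start, end))
            ref = locus.sequence[pos]
            if ref == "N":
                ref = "A"
            vclass = str(rng.choice(["SNV", "INS", "DEL"], p=[0.7, 0.15, 0.15]))
            if vclass == "SNV":
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            elif vclass == "INS":
                alt = ref + "".join(rng.choice(BASES, size=int(rng.integers(1, 4))))
            else:
                extra = "".join(rng.choice(BASES, size=int(rng.integers(1, 4))))
                ref, alt = ref + extra, ref
            support = int(rng.integers(1, max(2, config.read_depth // 20)))
            variants.append(
                SmallVariant(
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    supporting_reads=min(support, config.read_depth),
                    total_reads=config.read_depth,
                    vclass=vclass,
                )
            )
    return variants


# ---------------------------------------------------------------------------
# Truth table I/O


def write_truth_tsv(truths: Sequence[PlantedTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sv_id\tplanted\tmotif_seq\tleft_copy_start\tleft_copy_end\t"
            "right_copy_contig\tright_copy_start\tright_copy_end\n"
        )
        for t in truths:
            if t.planted:
                li, ri = t.left_copy_interval, t.right_copy_interval
                fh.write(
                    f"{t.sv_id}\ttrue\t{t.motif_seq}\t{li.start}\t{li.end}\t"
                    f"{ri.contig}\t{ri.start}\t{ri.end}\n"
                )
            else:
                fh.write(f"{t.sv_id}\tfalse\t\t\t\t\t\t\n")


def read_truth_tsv(path: str | Path) -> list[PlantedTruth]:
    out: list[PlantedTruth] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                continue
            if cols[1] == "true":
                out.append(
                    PlantedTruth(
                        sv_id=cols[0],
                        planted=True,
                        motif_seq=cols[2],
                        left_copy_interval=GenomicInterval(
                            "locus", int(cols[3]), int(cols[4]), "+", cols[0]
                        ),
                        right_copy_interval=GenomicInterval(
                            cols[5], int(cols[6]), int(cols[7]), "-", cols[0]
                        ),
                    )
                )
            else:
                out.append(PlantedTruth(sv_id=cols[0], planted=False))
    return out
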