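"""Signal-sequence detection at structural-variant breakpoints.

A breakpoint flank is taken in "inward" orientation: read from the breakpoint
into the rearranged segment, 5'->3' on the plus strand at the left breakpoint,
and the reverse complement of the plus-strand window ending at the right
breakpoint. Under this convention an inverted-orientation comparison of the two
flanks is a plain forward identity comparison. Candidates are converted to
reporting orientation (5'->3' with the breakpoint at the 3' terminus) on emit.

Detection applies three filters in order:

i.   best ungapped inverted alignment of the two flanks with start offsets
     at most ``max_offset`` bases from the breakpoints and identity at least
     ``min_identity``;
ii.  neither aligned flank segment contains a homopolymer or tandem repeat
     tract longer than ``max_repeat_len``;
iii. no similar passing alignment exists among the control-cohort flanks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .genome_io import (
    GenomicInterval,
    LocusReference,
    StructuralVariant,
    reverse_complement,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PssConfig:
    flank_window: int = 20
    min_identity: float = 0.50
    max_offset: int = 3  # "less than 4 bp" from the breakpoint
    min_aligned_len: int = 10
    max_repeat_len: int = 5
    control_identity: float = 0.80
    flank_mode: str = "inner"  # or "outer"
    identity_denominator: str = "aligned"  # or "window"
    strict_control: bool = False  # discard entire run if any control pair passes

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.max_offset < 0:
            raise ValueError("max_offset must be >= 0")
        if self.min_aligned_len > self.flank_window - self.max_offset:
            raise ValueError("min_aligned_len too large for flank_window/max_offset")
        if self.flank_mode not in ("inner", "outer"):
            raise ValueError("flank_mode must be 'inner' or 'outer'")
        if self.identity_denominator not in ("aligned", "window"):
            raise ValueError("identity_denominator must be 'aligned' or 'window'")


@dataclass(frozen=True)
class FlankPair:
    sv_id: str
    flank_left: str
    flank_right: str


@dataclass(frozen=True)
class InvertedAlignmentResult:
    offset_left: int
    offset_right: int
    aligned_len: int
    matches: int
    identity: float
    passed: bool


@dataclass(frozen=True)
class PssCandidate:
    """A passing breakpoint flank, reported 5'->3' with the breakpoint at the 3' end."""

    sv_id: str
    side: str  # "left" or "right"
    sequence: str
    alignment: InvertedAlignmentResult
    inward_segment: str = ""  # aligned segment in inward orientation (internal)


def _match(a: str, b: str) -> bool:
    # N never counts as a match
    return a == b and a != "N"


def extract_flanks(
    sv: StructuralVariant, locus: LocusReference, config: PssConfig
) -> FlankPair | None:
    """Inward flank pair for an SV; None (with a logged reason) if a breakpoint
    sits closer than ``flank_window`` to its contig end."""
    w = config.flank_window
    left_seq = locus.sequence
    right_seq = (
        locus.contig_sequence(sv.partner_contig) if sv.partner_contig else locus.sequence
    )
    if config.flank_mode == "inner":
        l_start, l_end = sv.left_bp, sv.left_bp + w
        r_start, r_end = sv.right_bp - w, sv.right_bp
        if l_start < 0 or l_end > len(left_seq) or r_start < 0 or r_end > len(right_seq):
            logger.info("skip %s: reason=flank_out_of_bounds", sv.id)
            return None
        flank_left = left_seq[l_start:l_end]
        flank_right = reverse_complement(right_seq[r_start:r_end])
    else:  # outer: windows outside the rearranged segment
        l_start, l_end = sv.left_bp - w, sv.left_bp
        r_start, r_end = sv.right_bp, sv.right_bp + w
        if l_start < 0 or l_end > len(left_seq) or r_start < 0 or r_end > len(right_seq):
            logger.info("skip %s: reason=flank_out_of_bounds", sv.id)
            return None
        flank_left = reverse_complement(left_seq[l_start:l_end])
        flank_right = right_seq[r_start:r_end]
    return FlankPair(sv_id=sv.id, flank_left=flank_left, flank_right=flank_right)


def best_inverted_alignment(pair: FlankPair, config: PssConfig) -> InvertedAlignmentResult:
    """Exhaustive ungapped search over (offset_left, offset_right, aligned_len).

    Maximizes identity; ties broken by larger aligned_len, then smaller
    offset_left+offset_right, then smaller offset_left.
    """
    w = len(pair.flank_left)
    best: tuple[float, int, int, int] | None = None  # (identity, len, -(ol+or), -ol)
    best_res: InvertedAlignmentResult | None = None
    for ol in range(config.max_offset + 1):
        for orr in range(config.max_offset + 1):
            max_len = w - max(ol, orr)
            for length in range(config.min_aligned_len, max_len + 1):
                a = pair.flank_left[ol : ol + length]
                b = pair.flank_right[orr : orr + length]
                matches = sum(_match(x, y) for x, y in zip(a, b))
                denom = w if config.identity_denominator == "window" else length
                identity = matches / denom
                key = (identity, length, -(ol + orr), -ol)
                if best is None or key > best:
                    best = key
                    best_res = InvertedAlignmentResult(
                        offset_left=ol,
                        offset_right=orr,
                        aligned_len=length,
                        matches=matches,
                        identity=identity,
                        passed=identity >= config.min_identity,
                    )
    assert best_res is not None
    return best_res


def has_disqualifying_repeat(seq: str, max_repeat_len: int = 5) -> bool:
    """True iff ``seq`` contains a homopolymer run longer than ``max_repeat_len``
    or a tandem tract (>=2 full consecutive copies of a unit of period 2..max_repeat_len)
    with total tract length > ``max_repeat_len``."""
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    # homopolymer runs
    run = 1
    for i in range(1, n):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        if run > max_repeat_len:
            return True
    # tandem tracts of period 2..max_repeat_len
    for p in range(2, max_repeat_len + 1):
        i = 0
        while i + p < n:
            if seq[i + p] == seq[i]:
                j = i + p
                while j + 1 < n and seq[j + 1] == seq[j + 1 - p]:
                    j += 1
                tract_len = j - i + 1
                if tract_len >= 2 * p and tract_len > max_repeat_len:
                    return True
                i = j - p + 1
            i += 1
    return False


def _best_shifted_identity(a: str, b: str, max_shift: int) -> float:
    """Best ungapped identity of ``b`` to ``a`` over relative shifts <= max_shift.

    The denominator is len(a): positions of ``a`` left uncovered by the shifted
    ``b`` count as mismatches, so a short chance overlap cannot score high.
    """
    if not a:
        return 0.0
    best = 0.0
    for shift in range(-max_shift, max_shift + 1):
        if shift >= 0:
            aa, bb = a[shift:], b
        else:
            aa, bb = a, b[-shift:]
        matches = sum(_match(x, y) for x, y in zip(aa, bb))
        best = max(best, matches / len(a))
    return best


def subtract_control(
    candidates: Sequence[PssCandidate],
    control_pairs: Sequence[FlankPair],
    config: PssConfig,
) -> list[PssCandidate]:
    """Drop candidates resembling any passing control alignment (criterion iii).

    A candidate is removed when a control flank pair yields a passing inverted
    alignment whose aligned left-flank segment has >= ``control_identity``
    ungapped identity (best over shifts <= ``max_offset``) with the candidate's
    aligned segment. In ``strict_control`` mode any passing control alignment
    voids all candidates.
    """
    control_segments: list[tuple[str, str]] = []
    for pair in control_pairs:
        res = best_inverted_alignment(pair, config)
        if res.passed:
            seg = pair.flank_left[res.offset_left : res.offset_left + res.aligned_len]
            control_segments.append((pair.sv_id, seg))
    if not control_segments:
        return list(candidates)
    if config.strict_control:
        logger.warning(
            "strict control mode: %d passing control alignments; all candidates dropped",
            len(control_segments),
        )
        return []
    kept: list[PssCandidate] = []
    for cand in candidates:
        cand_seg = cand.inward_segment or reverse_complement(cand.sequence)
        hit = None
        for ctrl_id, seg in control_segments:
            if _best_shifted_identity(cand_seg, seg, config.max_offset) >= config.control_identity:
                hit = ctrl_id
                break
        if hit is None:
            kept.append(cand)
        else:
            logger.info(
                "drop %s/%s: reason=control_hit control_id=%s", cand.sv_id, cand.side, hit
            )
    return kept


def _to_candidate(
    pair: FlankPair, side: str, res: InvertedAlignmentResult, config: PssConfig
) -> PssCandidate:
    offset = res.offset_left if side == "left" else res.offset_right
    flank = pair.flank_left if side == "left" else pair.flank_right
    span = min(offset + res.aligned_len, len(flank))
    inward = flank[:span]
    return PssCandidate(
        sv_id=pair.sv_id,
        side=side,
        sequence=reverse_complement(inward),
        alignment=res,
        inward_segment=flank[offset : offset + res.aligned_len],
    )


def detect_pss(
    case_svs: Sequence[StructuralVariant],
    control_svs: Sequence[StructuralVariant],
    locus: LocusReference,
    config: PssConfig | None = None,
) -> list[PssCandidate]:
    """Full detection: flank extraction, inverted alignment (criterion i),
    repeat filter (criterion ii), control subtraction (criterion iii).

    Emits two candidates (left and right side) per passing SV, in reporting
    orientation with the breakpoint at the 3' terminus.
    """
    config = config or PssConfig()
    candidates: list[PssCandidate] = []
    for sv in case_svs:
        pair = extract_flanks(sv, locus, config)
        if pair is None:
            continue
        res = best_inverted_alignment(pair, config)
        if not res.passed:
            continue
        seg_l = pair.flank_left[res.offset_left : res.offset_left + res.aligned_len]
        seg_r = pair.flank_right[res.offset_right : res.offset_right + res.aligned_len]
        if has_disqualifying_repeat(seg_l, config.max_repeat_len) or has_disqualifying_repeat(
            seg_r, config.max_repeat_len
        ):
            logger.info("drop %s: reason=disqualifying_repeat", sv.id)
            continue
        candidates.append(_to_candidate(pair, "left", res, config))
        candidates.append(_to_candidate(pair, "right", res, config))
    control_pairs = [
        p for sv in control_svs if (p := extract_flanks(sv, locus, config)) is not None
    ]
    return subtract_control(candidates, control_pairs, config)


# ---------------------------------------------------------------------------
# Inactivation classification


def _overlaps_exon(start: int, end: int, exons: Sequence[GenomicInterval]) -> bool:
    return any(ex.overlaps(start, end) for ex in exons)


def classify_inactivating(sv: StructuralVariant, exons: Sequence[GenomicInterval]) -> bool:
    """True iff the rearrangement is predicted to disrupt exonic sequence."""
    if not exons:
        return False
    if sv.svtype in ("DEL", "DUP"):
        return _overlaps_exon(sv.left_bp, sv.right_bp, exons)
    if sv.svtype == "INV":
        gene_start = min(ex.start for ex in exons)
        gene_end = max(ex.end for ex in exons)
        inside = any(gene_start < bp < gene_end for bp in (sv.left_bp, sv.right_bp))
        return inside and _overlaps_exon(sv.left_bp, sv.right_bp, exons)
    # TRA: an anchor within an exon disrupts it; the partner anchor is on
    # another contig and cannot hit a locus exon
    anchors = [sv.left_bp] if sv.partner_contig else [sv.left_bp, sv.right_bp - 1]
    return any(ex.contains(bp) for bp in anchors for ex in exons)


def summarize_cohort(
    svs: Sequence[StructuralVariant], exons: Sequence[GenomicInterval]
) -> dict[str, int]:
    """Inactivating/total tallies for one cohort."""
    inact = sum(classify_inactivating(sv, exons) for sv in svs)
    return {"inactivating": int(inact), "total": len(svs)}


# ---------------------------------------------------------------------------
# Output


def write_candidates_tsv(candidates: Sequence[PssCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sv_id\tside\tsequence\toffset_left\toffset_right\taligned_len\t"
            "matches\tidentity\n"
        )
        for c in candidates:
            a = c.alignment
            fh.write(
                f"{c.sv_id}\t{c.side}\t{c.sequence}\t{a.offset_left}\t{a.offset_right}\t"
                f"{a.aligned_len}\t{a.matches}\t{a.identity:.6f}\n"
            )


def write_candidates_fasta(candidates: Sequence[PssCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.sv_id}|{c.side}\n{c.sequence}\n")


def read_candidates_tsv(path: str | Path) -> list[PssCandidate]:
    out: list[PssCandidate] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            res = InvertedAlignmentResult(
                offset_left=int(cols[idx["offset_left"]]),
                offset_right=int(cols[idx["offset_right"]]),
                aligned_len=int(cols[idx["aligned_len"]]),
                matches=int(cols[idx["matches"]]),
                identity=float(cols[idx["identity"]]),
                passed=True,
            )
            out.append(
                PssCandidate(
                    sv_id=cols[idx["sv_id"]],
                    side=cols[idx["side"]],
                    sequence=cols[idx["sequence"]],
                    alignment=res,
                )
            )
    return out
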