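"""Breakpoint-anchored alignment of candidate sequences, position-frequency
matrices, per-column information content, and terminal-composition summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import reverse_complement

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE_ORDER = "ACGT"


@dataclass
class AnchoredAlignment:
    """Right-justified stack of candidate sequences.

    The anchor (breakpoint) is the final column; column j holds bases at
    distance depth - 1 - j from the breakpoint. Shorter sequences contribute
    nothing to leading columns.
    """

    sequences: list[str]
    depth: int


@dataclass
class PositionFrequencyMatrix:
    counts: np.ndarray  # (depth, 4) ints ordered A, C, G, T
    n_effective: np.ndarray  # (depth,) contributing sequences per column
    pseudocount: float = 0.0

    @property
    def depth(self) -> int:
        return self.counts.shape[0]

    def probabilities(self) -> np.ndarray:
        denom = self.n_effective[:, None] + 4.0 * self.pseudocount
        with np.errstate(invalid="ignore"):
            probs = (self.counts + self.pseudocount) / denom
        return np.nan_to_num(probs)


def anchor_align(candidates: Sequence[str], depth: int | None = None) -> AnchoredAlignment:
    """Stack sequences with their 3' (breakpoint-proximal) ends in the last column."""
    if not candidates:
        raise ValueError("no candidate sequences to align")
    depth = depth or max(len(s) for s in candidates)
    return AnchoredAlignment(sequences=[s.upper() for s in candidates], depth=depth)


def build_pfm(alignment: AnchoredAlignment, pseudocount: float = 0.0) -> PositionFrequencyMatrix:
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    depth = alignment.depth
    counts = np.zeros((depth, 4), dtype=np.int64)
    n_eff = np.zeros(depth, dtype=np.int64)
    for seq in alignment.sequences:
        tail = seq[-depth:]
        start = depth - len(tail)
        for j, base in enumerate(tail, start=start):
            idx = _BASE_INDEX.get(base)
            if idx is None:  # N contributes nothing
                continue
            counts[j, idx] += 1
            n_eff[j] += 1
    return PositionFrequencyMatrix(counts=counts, n_effective=n_eff, pseudocount=pseudocount)


def information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Bits per column: 2 + sum_b p_b log2 p_b, with 0 log 0 = 0."""
    probs = pfm.probabilities()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log2(probs), 0.0)
    ic = 2.0 + terms.sum(axis=1)
    ic[pfm.n_effective == 0] = 0.0
    return np.clip(ic, 0.0, 2.0)


def terminal_composition(candidates: Sequence[str], k: int = 3) -> dict:
    """Counts of terminal (breakpoint-proximal) k-mers, the fraction ending in
    GGG, and the overall T fraction across all candidate bases."""
    kept = []
    for seq in candidates:
        if len(seq) < k:
            logger.info("exclude short candidate %r from terminal composition", seq)
            continue
        kept.append(seq.upper())
    kmer_counts: dict[str, int] = {}
    for seq in kept:
        kmer = seq[-k:]
        kmer_counts[kmer] = kmer_counts.get(kmer, 0) + 1
    total_bases = sum(len(s) for s in kept)
    t_count = sum(s.count("T") for s in kept)
    n = len(kept)
    ggg = sum(1 for s in kept if s.endswith("GGG"))
    return {
        "n_candidates": n,
        "terminal_kmer_counts": dict(sorted(kmer_counts.items())),
        "ggg_fraction": ggg / n if n else 0.0,
        "t_fraction": t_count / total_bases if total_bases else 0.0,
    }


def scan_occurrences(consensus: str, sequence: str, max_mismatches: int = 0) -> int:
    """Sliding-window occurrence count of the consensus on both strands with at
    most ``max_mismatches`` mismatches; overlapping matches all count. N never
    matches."""
    consensus = consensus.upper()
    sequence = sequence.upper()
    m, n = len(consensus), len(sequence)
    if m > n:
        raise ValueError("consensus longer than sequence")

    def _count(pattern: str) -> int:
        hits = 0
        for i in range(n - m + 1):
            window = sequence[i : i + m]
            mismatches = sum(
                1 for a, b in zip(pattern, window) if a != b or a == "N" or b == "N"
            )
            if mismatches <= max_mismatches:
                hits += 1
        return hits

    return _count(consensus) + _count(reverse_complement(consensus))


def consensus_sequence(pfm: PositionFrequencyMatrix) -> str:
    """Majority base per column (ties broken alphabetically), skipping empty columns."""
    probs = pfm.probabilities()
    out = []
    for j in range(pfm.depth):
        if pfm.n_effective[j] == 0:
            continue
        out.append(_BASE_ORDER[int(np.argmax(probs[j]))])
    return "".join(out)


def write_logo_tsv(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    """Numeric logo: per column, base heights in bits (p_b * IC_j)."""
    ic = information_content(pfm)
    probs = pfm.probabilities()
    with open(path, "w") as fh:
        fh.write("column\tA\tC\tG\tT\tinformation_bits\tn_effective\n")
        for j in range(pfm.depth):
            heights = probs[j] * ic[j]
            fh.write(
                f"{j}\t"
                + "\t".join(f"{h:.6f}" for h in heights)
                + f"\t{ic[j]:.6f}\t{int(pfm.n_effective[j])}\n"
            )
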