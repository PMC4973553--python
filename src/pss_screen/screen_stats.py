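"""Screen statistics: mutational frequency, clonogenic efficiency, the exact
Poisson rate-ratio test (conditional binomial), exact binomial enrichment test,
and 40-bp windowed variant profiles.

Two-sided p-values default to the minlike convention (sum of point
probabilities not exceeding the observed one), matching the behavior of the
reference exact-test implementations; the central (doubling) convention is
available via ``method="central"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome_io import LocusReference, SmallVariant

WINDOW_LEN = 40

# relative slack when comparing point probabilities, mirroring R's binom.test
_REL_EPS = 1.0 + 1e-7


@dataclass(frozen=True)
class MutationAssayCounts:
    X_S: int  # colonies with selection
    N_S: int  # cells seeded with selection
    X_0: int  # colonies without selection
    N_0: int  # cells seeded without selection


@dataclass(frozen=True)
class RateRatioResult:
    rate_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    conf_level: float


@dataclass(frozen=True)
class WindowProfile:
    window_start: int
    window_len: int
    event_reads: int
    total_reads: int
    region: str  # "exonic" or "intronic"

    @property
    def frequency(self) -> float:
        return self.event_reads / self.total_reads if self.total_reads else 0.0


def mutational_frequency(counts: MutationAssayCounts) -> float:
    """ln(X_S/N_S) / ln(X_0/N_0); the two leading minus signs cancel."""
    for v in (counts.X_S, counts.N_S, counts.X_0, counts.N_0):
        if v <= 0:
            raise ValueError("all assay counts must be positive")
    return math.log(counts.X_S / counts.N_S) / math.log(counts.X_0 / counts.N_0)


def clonogenic_efficiency(colonies: int, seeded: int) -> float:
    if seeded <= 0:
        raise ValueError("seeded must be positive")
    if not (0 <= colonies <= seeded):
        raise ValueError("colonies must lie in [0, seeded]")
    return colonies / seeded


def clopper_pearson(x: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if not (0 <= x <= n) or n < 1:
        raise ValueError("need 0 <= x <= n, n >= 1")
    if not (0 < conf_level < 1):
        raise ValueError("conf_level must be in (0, 1)")
    alpha = 1.0 - conf_level
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def _binom_two_sided_p(k: int, n: int, p0: float, method: str = "minlike") -> float:
    if method == "central":
        lower = float(stats.binom.cdf(k, n, p0))
        upper = float(stats.binom.sf(k - 1, n, p0))
        return min(1.0, 2.0 * min(lower, upper))
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    observed = pmf[k]
    return float(min(1.0, pmf[pmf <= observed * _REL_EPS].sum()))


def binomial_enrichment_test(
    k: int, n_trials: int, p0: float, method: str = "minlike"
) -> float:
    """Two-sided exact binomial test of k successes in n_trials against p0."""
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    if not (0 <= k <= n_trials):
        raise ValueError("need 0 <= k <= n_trials")
    return _binom_two_sided_p(k, n_trials, p0, method=method)


def exact_poisson_rate_ratio_test(
    c1: int,
    t1: float,
    c2: int,
    t2: float,
    conf_level: float = 0.95,
    method: str = "minlike",
) -> RateRatioResult:
    """Exact comparison of two Poisson rates.

    Conditional on n = c1 + c2, c1 is binomial(n, pi) with pi = t1/(t1+t2).
    The two-sided p-value follows the chosen convention; the confidence
    interval is the Clopper-Pearson interval for pi mapped to the rate-ratio
    scale by (pi/(1-pi)) * (t2/t1).
    """
    if c1 < 0 or c2 < 0:
        raise ValueError("counts must be non-negative")
    if t1 <= 0 or t2 <= 0:
        raise ValueError("exposures must be positive")
    n = c1 + c2
    if n < 1:
        raise ValueError("both counts zero")
    pi0 = t1 / (t1 + t2)
    p_value = _binom_two_sided_p(c1, n, pi0, method=method)
    lo_pi, hi_pi = clopper_pearson(c1, n, conf_level)
    scale = t2 / t1
    ci_low = (lo_pi / (1 - lo_pi)) * scale if lo_pi < 1 else math.inf
    ci_high = (hi_pi / (1 - hi_pi)) * scale if hi_pi < 1 else math.inf
    if c2 == 0:
        rate_ratio = math.inf
        ci_high = math.inf
    else:
        rate_ratio = (c1 / t1) / (c2 / t2)
    return RateRatioResult(
        rate_ratio=rate_ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        conf_level=conf_level,
    )


# ---------------------------------------------------------------------------
# Windowed profiles


def window_profile(
    small_variants: Sequence[SmallVariant],
    locus: LocusReference,
    condition: str = "",
) -> list[WindowProfile]:
    """Tile the locus in fixed 40-bp windows and assign each variant's
    supporting reads to the window containing its start position. A window is
    exonic iff it overlaps any exon base.

    Every window carries the same total-read denominator: the sequencing depth,
    inferred as the maximum per-variant total (amplicon depth is uniform in
    this assay). Tying the denominator to sequencing effort rather than to the
    number of calls keeps window frequencies comparable across conditions.
    """
    n = len(locus.sequence)
    starts = list(range(0, n, WINDOW_LEN))
    events = {s: 0 for s in starts}
    for v in small_variants:
        if not (0 <= v.pos < n):
            raise ValueError(f"variant at {v.pos} outside locus of length {n}")
        w = (v.pos // WINDOW_LEN) * WINDOW_LEN
        events[w] += v.supporting_reads
    depth = max((v.total_reads for v in small_variants), default=0)
    profiles = []
    for s in starts:
        end = min(s + WINDOW_LEN, n)
        exonic = any(ex.overlaps(s, end) for ex in locus.exons)
        profiles.append(
            WindowProfile(
                window_start=s,
                window_len=end - s,
                event_reads=events[s],
                total_reads=depth,
                region="exonic" if exonic else "intronic",
            )
        )
    return profiles


def compare_region_frequencies(
    profile_a: Sequence[WindowProfile],
    profile_b: Sequence[WindowProfile],
    conf_level: float = 0.95,
) -> dict[str, RateRatioResult]:
    """Aggregate event/total reads per region class and compare the two
    profiles with the exact rate-ratio test (exposures = total reads)."""
    if [p.window_start for p in profile_a] != [p.window_start for p in profile_b]:
        raise ValueError("profiles cover different windows")
    results: dict[str, RateRatioResult] = {}
    for region in ("exonic", "intronic"):
        ea = sum(p.event_reads for p in profile_a if p.region == region)
        ta = sum(p.total_reads for p in profile_a if p.region == region)
        eb = sum(p.event_reads for p in profile_b if p.region == region)
        tb = sum(p.total_reads for p in profile_b if p.region == region)
        if ta == 0 or tb == 0:
            raise ValueError(f"zero total reads in {region} region")
        results[region] = exact_poisson_rate_ratio_test(
            ea, ta, eb, tb, conf_level=conf_level
        )
    return results


def write_window_profile_tsv(profiles: Sequence[WindowProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("window_start\twindow_len\tevent_reads\ttotal_reads\tfrequency\tregion\n")
        for p in profiles:
            fh.write(
                f"{p.window_start}\t{p.window_len}\t{p.event_reads}\t{p.total_reads}\t"
                f"{p.frequency!r}\t{p.region}\n"
            )
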