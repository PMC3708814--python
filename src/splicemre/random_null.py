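"""Randomized MRE catalogs and the one-sample Wilcoxon comparison.

To gauge how often the splicing-regulated call fires by chance, random MREs
are drawn as intervals on the real reference transcripts: a source sequence,
a start position and a length between 18 and 22 nt are all randomized, and
the resulting sites (100 per set by default) run through exactly the same
isoform-enrichment machinery as the curated catalogs.  The observed
regulated fraction of a true (or false) catalog is then compared against the
distribution of per-set random fractions with a one-sample Wilcoxon
signed-rank test; the random fractions are not normally distributed, which
is why a rank test is used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata

from .formats_io import ESTDataset, MRESite, ReferenceSequence
from .splicing_enrichment import EnrichmentSettings, fraction_regulated

__all__ = [
    "RandomMRESpec",
    "WilcoxonResult",
    "NullComparison",
    "generate_random_mres",
    "set_fractions",
    "wilcoxon_one_sample",
    "compare_to_null",
]

logger = logging.getLogger(__name__)

#: Above this many nonzero differences the exact sign-enumeration
#: distribution is replaced by the tie-corrected normal approximation.
EXACT_WILCOXON_LIMIT = 25


@dataclass(frozen=True)
class RandomMRESpec:
    """How to draw random MRE sets: *n_sets* sets of *set_size* intervals of
    length 18-22 nt from the full-length references or their 3'UTRs."""

    n_sets: int
    set_size: int = 100
    length_range: tuple[int, int] = (18, 22)
    source: str = "full_length"  # or "three_prime_utr"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 1 or self.set_size < 1:
            raise ValueError("n_sets and set_size must be >= 1")
        lmin, lmax = self.length_range
        if not (1 <= lmin <= lmax):
            raise ValueError(f"invalid length range {self.length_range}")
        if self.source not in {"full_length", "three_prime_utr"}:
            raise ValueError(f"unknown source {self.source!r}")


class WilcoxonResult:
    __slots__ = ("W", "p_value", "n")

    def __init__(self, W: float, p_value: float, n: int) -> None:
        self.W = W
        self.p_value = p_value
        self.n = n

    def __iter__(self):
        return iter((self.W, self.p_value))

    def __repr__(self) -> str:
        return f"WilcoxonResult(W={self.W}, p_value={self.p_value}, n={self.n})"


@dataclass
class NullComparison:
    set_fractions: list[float]
    observed_fraction: float
    W: float
    p_value: float
    n_sets_used: int = 0


def generate_random_mres(
    sources: Sequence[ReferenceSequence],
    spec: RandomMRESpec,
    utr3: dict[str, tuple[int, int]] | None = None,
) -> list[list[MRESite]]:
    """Draw seeded random MRE sets as coordinates on the source references.

    For each site: a source is drawn uniformly among those whose allowed
    region (full length, or the annotated 3'UTR sub-interval) can hold the
    minimum length; then a valid start uniformly; then a length uniform in
    the range, truncated so the site stays inside the region.  Because the
    sites are real substrings of the references they are directly testable
    by the enrichment stage without any re-matching.  Identical seeds yield
    identical catalogs.
    """
    lmin, lmax = spec.length_range
    regions: list[tuple[ReferenceSequence, int, int]] = []
    for ref in sources:
        if spec.source == "three_prime_utr":
            if utr3 is None or ref.id not in utr3:
                continue
            lo, hi = utr3[ref.id]
            if not (0 <= lo < hi <= ref.length):
                raise ValueError(f"invalid 3'UTR interval for {ref.id!r}")
        else:
            lo, hi = 0, ref.length
        if hi - lo >= lmin:
            regions.append((ref, lo, hi))
    if not regions:
        raise ValueError(
            f"no source region can hold a random MRE of length {lmin}"
        )
    rng = np.random.default_rng(spec.seed)
    sets: list[list[MRESite]] = []
    for set_idx in range(spec.n_sets):
        sites: list[MRESite] = []
        for j in range(spec.set_size):
            ref, lo, hi = regions[int(rng.integers(len(regions)))]
            start = int(rng.integers(lo, hi - lmin + 1))
            max_len = min(lmax, hi - start)
            length = int(rng.integers(lmin, max_len + 1))
            sites.append(
                MRESite(
                    site_id=f"rand-s{set_idx + 1}-{j + 1}",
                    reference_id=ref.id,
                    mirna_id="random",
                    start=start,
                    end=start + length,
                    site_sequence=ref.sequence[start : start + length],
                    validation="random",
                )
            )
        sets.append(sites)
    return sets


def set_fractions(
    random_sets: Sequence[Sequence[MRESite]],
    est_data: ESTDataset,
    settings: EnrichmentSettings = EnrichmentSettings(),
) -> list[float]:
    """Regulated fraction per random set, NaN for sets with no testable site."""
    fractions: list[float] = []
    for idx, sites in enumerate(random_sets, start=1):
        try:
            result = fraction_regulated(list(sites), est_data, settings)
        except ValueError:
            logger.warning(
                "random set %d has no testable site; excluded from the test",
                idx,
            )
            fractions.append(math.nan)
            continue
        fractions.append(result.fraction)
    return fractions


def _exact_signed_rank_tails(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) over all 2^n sign assignments.

    ``ranks2`` holds the doubled (hence integer) ranks; the distribution of
    the doubled positive-rank sum is built by convolving ``(1 + x^r)`` over
    all ranks, which enumerates every sign vector exactly.
    """
    total = ranks2.sum()
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = counts.sum()  # == 2^n, exact in float64 for n <= 52
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return p_le, p_ge


def wilcoxon_one_sample(
    values: Sequence[float],
    hypothesized: float = 0.0,
    alternative: str = "two_sided",
) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test of location.

    Differences equal to the hypothesized value are dropped (the standard
    signed-rank convention) and ties among absolute differences receive
    average ranks.  ``W`` is the sum of the ranks of positive differences.
    The P-value is exact (full sign enumeration) for up to 25 nonzero
    differences, and a tie-corrected normal approximation with continuity
    correction beyond that.  Raises when every difference is zero.
    """
    if alternative not in {"two_sided", "less", "greater"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(values, dtype=float) - hypothesized
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError(
            "all values equal the hypothesized value; the signed-rank test "
            "is undefined"
        )
    ranks = rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_LIMIT:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        w2 = int(round(2 * W))
        p_le, p_ge = _exact_signed_rank_tails(ranks2, w2)
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        sd = math.sqrt(var)
        p_ge = float(ndtr(-(W - mu - 0.5) / sd))
        p_le = float(ndtr((W - mu + 0.5) / sd))
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return WilcoxonResult(W=W, p_value=min(max(p, 5e-324), 1.0), n=n)


def compare_to_null(
    observed_fraction: float,
    fractions: Sequence[float],
    alternative: str = "two_sided",
) -> NullComparison:
    """Wilcoxon test of the random-set fractions against the observed one.

    NaN fractions (untestable sets) are excluded.  The hypothesized location
    is the observed true- or false-catalog fraction, two-sided by default.
    """
    arr = np.asarray(fractions, dtype=float)
    usable = arr[np.isfinite(arr)]
    if usable.size == 0:
        raise ValueError("no usable random-set fractions")
    result = wilcoxon_one_sample(usable, observed_fraction, alternative)
    return NullComparison(
        set_fractions=list(arr),
        observed_fraction=observed_fraction,
        W=result.W,
        p_value=result.p_value,
        n_sets_used=result.n,
    )
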