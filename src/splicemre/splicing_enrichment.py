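"""Tissue-wise Fisher exact tests for splicing-regulated MREs.

For each MRE the informative ESTs (configurations II, III, IV) are grouped
per tissue into a 2x2 table

====================  ===============  ==================
cell                  MRE-free         MRE-containing
====================  ===============  ==================
focal tissue          a                b
all other tissues     c                d
====================  ===============  ==================

Under the null hypothesis that the free:containing proportion is identical
in the focal tissue and everywhere else, ``a`` follows a hypergeometric
distribution with the table margins fixed.  The left tail (few MRE-free,
i.e. MRE-containing isoforms enriched in the tissue), right tail (MRE-free
enriched) and minimum-likelihood two-tail P-values are all computed in
log-space from log-factorials.  An MRE with a significant tissue at the
chosen level is called splicing-regulated.

Tests are restricted to MREs with at least ten informative ESTs overall and
tissues with at least ten informative ESTs, mirroring the depth limits of
EST-library evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .est_classification import ClassifiedEST, IsoformClass, classify_all
from .formats_io import ESTAlignment, ESTDataset, LibraryAnnotation, MRESite

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "TissueEnrichmentResult",
    "SplicingRegulatedCall",
    "EnrichmentSettings",
    "FractionRegulatedResult",
    "build_tables",
    "fisher_exact",
    "enrich_mre",
    "fraction_regulated",
]

#: Relative tolerance used when comparing point probabilities for the
#: minimum-likelihood two-tailed rule, guarding against floating-point ties.
TWO_TAIL_TOLERANCE = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """MRE-free / MRE-containing counts, focal tissue vs all others."""

    a: int  # MRE-free, focal tissue
    b: int  # MRE-containing, focal tissue
    c: int  # MRE-free, other tissues
    d: int  # MRE-containing, other tissues

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in contingency table {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


class FisherResult(NamedTuple):
    p_left: float
    p_right: float
    p_twotail: float


@dataclass(frozen=True)
class TissueEnrichmentResult:
    tissue: str
    stratum: str  # "pooled", "normal" or "cancer"
    table: ContingencyTable
    p_left: float
    p_right: float
    p_twotail: float
    tested: bool


@dataclass(frozen=True)
class SplicingRegulatedCall:
    site_id: str
    significant_tissues: tuple[tuple[str, str, str], ...]  # (tissue, stratum, tail)
    is_regulated: bool
    alpha: float
    tested: bool = True


@dataclass(frozen=True)
class EnrichmentSettings:
    alpha: float = 0.05
    min_gene_ests: int = 10
    min_tissue_ests: int = 10
    stratify_histology: bool = False


def _lchoose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact(table: ContingencyTable) -> FisherResult:
    """Left, right and two-tailed Fisher exact P-values for a 2x2 table.

    With N = a+b+c+d, K = a+c (MRE-free margin) and n = a+b (focal-tissue
    margin), and X ~ Hypergeometric(N, K, n):

    * ``p_left  = P(X <= a)`` - small ``a`` means MRE-containing isoforms are
      enriched in the focal tissue;
    * ``p_right = P(X >= a)`` - MRE-free isoforms enriched;
    * ``p_twotail`` sums P(X = k) over every k whose point probability does
      not exceed P(X = a), with a ``1 + 1e-7`` relative tolerance against
      floating-point ties (the minimum-likelihood rule).

    A degenerate margin (an all-zero row or column) yields (1, 1, 1).
    Deterministic; computed in log-space via log-factorials.
    """
    a = table.a
    N = table.n
    if N < 1:
        raise ValueError("contingency table must contain at least one EST")
    K = table.a + table.c
    n = table.a + table.b
    if K == 0 or K == N or n == 0 or n == N:
        return FisherResult(1.0, 1.0, 1.0)
    kmin = max(0, n - (N - K))
    kmax = min(n, K)
    k = np.arange(kmin, kmax + 1)
    logpmf = _lchoose(K, k) + _lchoose(N - K, n - k) - _lchoose(N, n)
    log_pa = logpmf[a - kmin]
    p_left = float(np.exp(logsumexp(logpmf[k <= a])))
    p_right = float(np.exp(logsumexp(logpmf[k >= a])))
    in_tail = logpmf <= log_pa + math.log1p(TWO_TAIL_TOLERANCE)
    p_two = float(np.exp(logsumexp(logpmf[in_tail])))
    clip = lambda p: min(max(p, 5e-324), 1.0)
    return FisherResult(clip(p_left), clip(p_right), clip(p_two))


def build_tables(
    classified: Sequence[ClassifiedEST],
    libraries: Sequence[LibraryAnnotation],
    stratify_histology: bool = False,
) -> list[tuple[str, str, ContingencyTable]]:
    """Per-tissue 2x2 tables from classified ESTs of a single MRE.

    Excluded ESTs (configurations I and V) contribute to no cell.  With
    *stratify_histology* the normal and cancer libraries are analysed as
    separate strata (each tissue compared against the other tissues of the
    same stratum); otherwise one pooled stratum is built.  Tables are
    returned in sorted (stratum, tissue) order for determinism.
    """
    lib_by_id = {lib.library_id: lib for lib in libraries}
    counts: dict[tuple[str, str], list[int]] = {}  # (stratum, tissue) -> [free, containing]
    for cl in classified:
        if cl.isoform_class is IsoformClass.EXCLUDED:
            continue
        lib = lib_by_id[cl.library_id]
        stratum = lib.histology if stratify_histology else "pooled"
        key = (stratum, lib.tissue)
        cell = counts.setdefault(key, [0, 0])
        if cl.isoform_class is IsoformClass.FREE:
            cell[0] += 1
        else:
            cell[1] += 1
    totals: dict[str, list[int]] = {}
    for (stratum, _), (free, cont) in counts.items():
        tot = totals.setdefault(stratum, [0, 0])
        tot[0] += free
        tot[1] += cont
    out: list[tuple[str, str, ContingencyTable]] = []
    for stratum, tissue in sorted(counts):
        free, cont = counts[(stratum, tissue)]
        tot_free, tot_cont = totals[stratum]
        out.append(
            (
                tissue,
                stratum,
                ContingencyTable(
                    a=free, b=cont, c=tot_free - free, d=tot_cont - cont
                ),
            )
        )
    return out


def enrich_mre(
    ests: Iterable[ESTAlignment],
    mre: MRESite,
    libraries: Sequence[LibraryAnnotation],
    settings: EnrichmentSettings = EnrichmentSettings(),
) -> tuple[list[TissueEnrichmentResult], SplicingRegulatedCall]:
    """Tissue-wise enrichment tests and the splicing-regulated call for one MRE.

    The MRE is untested (``call.tested`` False) when fewer than
    ``min_gene_ests`` informative ESTs cover it; a tissue result has
    ``tested`` False when its own informative count (a+b) is below
    ``min_tissue_ests``.  ``is_regulated`` is True iff any tested tissue has
    a two-tailed P below alpha; the contributing tail is recorded as left if
    the left one-tailed P is below alpha, else right.
    """
    classified = classify_all(ests, mre, libraries)
    informative = sum(
        1 for c in classified if c.isoform_class is not IsoformClass.EXCLUDED
    )
    if informative < settings.min_gene_ests:
        return [], SplicingRegulatedCall(
            site_id=mre.site_id,
            significant_tissues=(),
            is_regulated=False,
            alpha=settings.alpha,
            tested=False,
        )
    results: list[TissueEnrichmentResult] = []
    significant: list[tuple[str, str, str]] = []
    for tissue, stratum, table in build_tables(
        classified, libraries, settings.stratify_histology
    ):
        tested = (table.a + table.b) >= settings.min_tissue_ests
        p_left, p_right, p_two = fisher_exact(table)
        results.append(
            TissueEnrichmentResult(
                tissue=tissue,
                stratum=stratum,
                table=table,
                p_left=p_left,
                p_right=p_right,
                p_twotail=p_two,
                tested=tested,
            )
        )
        if tested and p_two < settings.alpha:
            tail = "left" if p_left < settings.alpha else "right"
            significant.append((tissue, stratum, tail))
    call = SplicingRegulatedCall(
        site_id=mre.site_id,
        significant_tissues=tuple(significant),
        is_regulated=bool(significant),
        alpha=settings.alpha,
        tested=True,
    )
    return results, call


@dataclass
class FractionRegulatedResult:
    fraction: float
    n_unique: int
    n_tested: int
    n_regulated: int
    calls: dict[tuple[str, int, int], SplicingRegulatedCall] = field(
        default_factory=dict
    )


def fraction_regulated(
    catalog: Sequence[MRESite],
    est_data: ESTDataset,
    settings: EnrichmentSettings = EnrichmentSettings(),
) -> FractionRegulatedResult:
    """Fraction of unique catalog sites called splicing-regulated.

    Catalog rows with identical (reference, interval) - e.g. one MRE bound
    by several microRNAs - are collapsed to a single site before counting.
    The fraction is regulated / tested unique sites; sites below the EST
    thresholds do not enter the denominator.  Raises on an empty catalog or
    when no site is testable.
    """
    if not catalog:
        raise ValueError("empty MRE catalog")
    unique: dict[tuple[str, int, int], MRESite] = {}
    for site in catalog:
        key = (site.reference_id, site.start, site.end)
        unique.setdefault(key, site)
    calls: dict[tuple[str, int, int], SplicingRegulatedCall] = {}
    n_tested = 0
    n_regulated = 0
    for key, site in unique.items():
        ests = est_data.alignments_for(site.reference_id)
        _, call = enrich_mre(ests, site, est_data.libraries, settings)
        calls[key] = call
        if call.tested:
            n_tested += 1
            if call.is_regulated:
                n_regulated += 1
    if n_tested == 0:
        raise ValueError("no testable site in the catalog (EST thresholds)")
    return FractionRegulatedResult(
        fraction=n_regulated / n_tested,
        n_unique=len(unique),
        n_tested=n_tested,
        n_regulated=n_regulated,
        calls=calls,
    )
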