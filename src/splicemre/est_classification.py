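"""Classify spliced EST alignments relative to an MRE interval.

Each EST has exactly one of five configurations with respect to a given MRE:

* ``I``   - the MRE is not fully contained in the EST's aligned footprint
  (partial or no overlap); the EST is uninformative and excluded.
* ``II``  - the MRE lies entirely inside one aligned exon block: the EST
  represents an MRE-containing isoform.
* ``III`` - the MRE lies entirely inside one inter-block gap (a putative
  intron): the EST represents an MRE-free isoform.
* ``IV``  - the MRE straddles an exon-intron junction inside the footprint,
  so the isoform carries only a partial, potentially non-functional MRE; it
  is counted as MRE-free.
* ``V``   - defensive catch-all for alignments that violate the structural
  assumptions (unsorted or overlapping blocks) at classification time;
  excluded from all counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats_io import ESTAlignment, LibraryAnnotation, MRESite

__all__ = [
    "Configuration",
    "IsoformClass",
    "ClassifiedEST",
    "classify_est",
    "classify_all",
]


class Configuration(enum.Enum):
    I = "I_partial_or_no_overlap"
    II = "II_mre_in_exon"
    III = "III_mre_in_intron"
    IV = "IV_partial_mre_at_junction"
    V = "V_other"


class IsoformClass(enum.Enum):
    CONTAINING = "containing"
    FREE = "free"
    EXCLUDED = "excluded"


#: Fixed mapping from configuration to isoform class: II is MRE-containing,
#: III and IV are MRE-free, I and V are excluded from the contingency table.
ISOFORM_CLASS_OF: dict[Configuration, IsoformClass] = {
    Configuration.I: IsoformClass.EXCLUDED,
    Configuration.II: IsoformClass.CONTAINING,
    Configuration.III: IsoformClass.FREE,
    Configuration.IV: IsoformClass.FREE,
    Configuration.V: IsoformClass.EXCLUDED,
}


@dataclass(frozen=True)
class ClassifiedEST:
    est_id: str
    library_id: str
    configuration: Configuration
    isoform_class: IsoformClass


def classify_est(
    est: ESTAlignment, mre_interval: tuple[int, int]
) -> Configuration:
    """Assign one of the five configurations to (EST, MRE).

    Interval arithmetic is half-open, so an MRE sharing an endpoint with a
    block boundary counts as contained, not straddling.
    """
    if not est.blocks:
        raise ValueError(f"EST {est.est_id!r} has no aligned blocks")
    s, e = mre_interval
    if s < 0 or e <= s:
        raise ValueError(f"invalid MRE interval [{s}, {e})")
    if not est.structure_ok():
        return Configuration.V
    fp_start, fp_end = est.footprint
    if s < fp_start or e > fp_end:
        return Configuration.I
    for bs, be in est.blocks:
        if bs <= s and e <= be:
            return Configuration.II
    for (_, prev_end), (next_start, _) in zip(est.blocks, est.blocks[1:]):
        if prev_end <= s and e <= next_start:
            return Configuration.III
    return Configuration.IV


def classify_all(
    ests: Iterable[ESTAlignment],
    mre: MRESite | tuple[int, int],
    libraries: Sequence[LibraryAnnotation],
) -> list[ClassifiedEST]:
    """Classify every EST against one MRE, checking library membership.

    Returns one :class:`ClassifiedEST` per input EST, in input order, with
    the isoform class derived from the configuration by the fixed mapping.
    """
    interval = mre.interval if isinstance(mre, MRESite) else tuple(mre)
    known = {lib.library_id for lib in libraries}
    out: list[ClassifiedEST] = []
    for est in ests:
        if est.library_id not in known:
            raise ValueError(
                f"EST {est.est_id!r} references unknown library "
                f"{est.library_id!r}"
            )
        config = classify_est(est, interval)
        out.append(
            ClassifiedEST(
                est_id=est.est_id,
                library_id=est.library_id,
                configuration=config,
                isoform_class=ISOFORM_CLASS_OF[config],
            )
        )
    return out
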