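"""Bundled literature-derived example catalogs."""

from __future__ import annotations

from importlib import resources

from .formats_io import MRESite, read_mre_table

__all__ = ["load_vegf_mre_catalog"]


def load_vegf_mre_catalog() -> list[MRESite]:
    """The curated VEGF microRNA recognition element catalog.

    Thirty experimentally reported microRNA sites on the VEGF reference
    transcript (UniGene cluster Hs.73793), with repressive ratios measured
    by introducing synthetic microRNA duplexes into hypoxia-induced CNE
    cells, and tissue-support annotations from EST-based isoform enrichment
    (cancer and normal strata).  Under 90%-overlap merging the 30 sites form
    13 MRE regions; coordinates are 1-based inclusive in the file and
    0-based half-open on the returned sites.
    """
    path = resources.files("splicemre.data").joinpath("vegf_mre_catalog.tsv")
    with resources.as_file(path) as p:
        return read_mre_table(p)
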