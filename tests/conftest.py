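import pytest
from hypothesis import HealthCheck, settings

from splicemre.formats_io import ESTAlignment, LibraryAnnotation, MRESite

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def _est(est_id, lib, blocks, ref="G1"):
    return ESTAlignment(
        est_id=est_id, reference_id=ref, library_id=lib, blocks=tuple(blocks)
    )


@pytest.fixture
def worked_example():
    """The narrated EST example: an MRE present in 7 brain ESTs, absent from
    3 others; present in 1 and absent from 6 across colon/lung; 2 liver ESTs
    not covering the full MRE.  Yields (ests, mre, libraries)."""
    mre = MRESite(
        site_id="G1:site1",
        reference_id="G1",
        mirna_id="hsa-miR-x",
        start=120,
        end=140,
    )
    libraries = [
        LibraryAnnotation("brain-lib", "brain"),
        LibraryAnnotation("colon-lib", "colon"),
        LibraryAnnotation("lung-lib", "lung"),
        LibraryAnnotation("liver-lib", "liver"),
    ]
    exon = [(100, 200)]  # MRE inside one exon block -> configuration II
    intron = [(50, 110), (150, 300)]  # MRE inside the gap -> III
    junction = [(50, 130), (200, 300)]  # MRE straddles block end -> IV
    partial = [(130, 300)]  # footprint misses the MRE start -> I
    ests = []
    for i in range(7):
        ests.append(_est(f"brain-c{i}", "brain-lib", exon))
    ests.append(_est("brain-f0", "brain-lib", intron))
    ests.append(_est("brain-f1", "brain-lib", intron))
    ests.append(_est("brain-f2", "brain-lib", junction))
    ests.append(_est("colon-c0", "colon-lib", exon))
    for i in range(3):
        ests.append(_est(f"colon-f{i}", "colon-lib", intron))
    for i in range(3):
        ests.append(_est(f"lung-f{i}", "lung-lib", intron))
    ests.append(_est("liver-x0", "liver-lib", partial))
    ests.append(_est("liver-x1", "liver-lib", partial))
    return ests, mre, libraries


@pytest.fixture(scope="session")
def vegf_catalog():
    from splicemre.datasets import load_vegf_mre_catalog

    return load_vegf_mre_catalog()
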