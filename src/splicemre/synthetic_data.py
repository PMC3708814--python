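"""Synthetic references, ESTs, MRE catalogs and protein tables with ground truth.

The generator emulates the structure of EST evidence over UniGene-style
reference transcripts.  Each synthetic gene is a single reference sequence
carrying one or more cassette exons; each cassette exon contains one MRE.
An EST is simulated by (1) choosing a tissue-specific isoform - every
cassette exon is retained independently with that tissue's inclusion
probability - and (2) sampling a contiguous footprint window uniformly on
the chosen isoform, which is then mapped back to reference coordinates as
exon blocks.  ESTs whose window retains the exon place the MRE inside an
exon block (configuration II); ESTs from skipping isoforms whose window
straddles the splice junction place the MRE in a block gap (configuration
III); windows that do not cover the whole MRE yield uninformative
configuration-I ESTs, exactly as in real EST data.

A planted "regulated" site is one whose inclusion probability differs
between tissues; everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import formats_io as fio
from .formats_io import (
    ESTAlignment,
    ESTDataset,
    LibraryAnnotation,
    MRESite,
    ProteinChangeRecord,
    ReferenceSequence,
)

__all__ = [
    "TissueSpec",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedESTData",
    "simulate_est_dataset",
    "simulate_null_est_dataset",
    "simulate_protein_table",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TissueSpec:
    """One simulated tissue: its histology, library count and EST depth."""

    name: str
    histology: str = "normal"
    n_libraries: int = 2
    n_ests: int = 30


#: Default tissues mirror the worked EST example: brain against colon,
#: lung and liver, all normal histology.
DEFAULT_TISSUES: tuple[TissueSpec, ...] = (
    TissueSpec("brain"),
    TissueSpec("colon"),
    TissueSpec("lung"),
    TissueSpec("liver"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the EST simulator.

    ``exon_layout`` lists ``(exon_interval, mre_interval)`` pairs shared by
    every gene: each cassette exon carries one MRE strictly inside it.
    ``inclusion_prob`` maps tissue name to the probability that a sampled
    EST's isoform retains a cassette exon (key ``"default"`` is the
    fallback, 0.5 if absent).  ``regulated_sites`` overrides the inclusion
    probability per planted site id and tissue, making those sites truly
    splicing-regulated.  ``est_window`` bounds the EST footprint length on
    the isoform; windows longer than an isoform are truncated to it.
    """

    n_genes: int = 20
    gene_length: int = 2000
    exon_layout: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = (
        ((900, 1100), (975, 996)),
    )
    tissues: tuple[TissueSpec, ...] = DEFAULT_TISSUES
    inclusion_prob: Mapping[str, float] = field(
        default_factory=lambda: {"default": 0.5}
    )
    regulated_sites: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    est_window: tuple[int, int] = (300, 800)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.exon_layout:
            raise ValueError("exon_layout must contain at least one cassette")
        prev_end = 0
        skipped_total = 0
        for (es, ee), (ms, me) in self.exon_layout:
            if not (0 < es < ee < self.gene_length):
                raise ValueError(f"cassette exon [{es}, {ee}) outside the gene")
            if es < prev_end + 1:
                raise ValueError("cassette exons must be disjoint and ordered")
            if not (es <= ms < me <= ee):
                raise ValueError(
                    f"MRE [{ms}, {me}) not inside its cassette exon [{es}, {ee})"
                )
            prev_end = ee
            skipped_total += ee - es
        wmin, wmax = self.est_window
        if not (1 <= wmin <= wmax):
            raise ValueError(f"invalid est_window {self.est_window}")
        if wmax > self.gene_length:
            raise ValueError("est_window max exceeds gene_length")
        min_isoform = self.gene_length - skipped_total
        if wmin > min_isoform:
            raise ValueError(
                f"infeasible window bounds: min window {wmin} exceeds the "
                f"shortest isoform length {min_isoform}"
            )
        for tissue, p in self.inclusion_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"inclusion_prob[{tissue!r}] outside [0, 1]")
        known_sites = {
            f"{self._gene_id(g)}:site{k + 1}"
            for g in range(self.n_genes)
            for k in range(len(self.exon_layout))
        }
        for site_id, overrides in self.regulated_sites.items():
            if site_id not in known_sites:
                raise ValueError(f"planted site id {site_id!r} does not exist")
            for tissue, p in overrides.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"override for {site_id!r}/{tissue!r} outside [0, 1]"
                    )

    def _gene_id(self, gene_index: int) -> str:
        return f"g{gene_index + 1:04d}"

    def inclusion(self, site_id: str, tissue: str) -> float:
        override = self.regulated_sites.get(site_id, {})
        if tissue in override:
            return override[tissue]
        if tissue in self.inclusion_prob:
            return self.inclusion_prob[tissue]
        return self.inclusion_prob.get("default", 0.5)


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    inclusion: dict[tuple[str, str], float]  # (site_id, tissue) -> probability
    regulated_site_ids: list[str]


@dataclass
class SimulatedESTData:
    references: list[ReferenceSequence]
    alignments: list[ESTAlignment]
    libraries: list[LibraryAnnotation]
    est2lib: dict[str, str]
    sites: list[MRESite]
    truth: GroundTruth

    def est_dataset(self) -> ESTDataset:
        return ESTDataset(
            alignments=self.alignments,
            libraries=self.libraries,
            references={r.id: r for r in self.references},
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the full input bundle; files pass formats_io validation."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "references.fasta",
            "bed": outdir / "ests.bed",
            "libraries": outdir / "libraries.tsv",
            "est2lib": outdir / "est2lib.tsv",
            "mre_catalog": outdir / "mre_catalog.tsv",
            "ground_truth": outdir / "ground_truth.tsv",
        }
        fio.write_fasta(self.references, paths["fasta"])
        fio.write_est_bed12(self.alignments, paths["bed"])
        fio.write_library_table(self.libraries, paths["libraries"])
        fio.write_est2lib(self.est2lib, paths["est2lib"])
        fio.write_mre_table(self.sites, paths["mre_catalog"])
        regulated = set(self.truth.regulated_site_ids)
        rows = [
            {
                "site_id": site_id,
                "tissue": tissue,
                "inclusion_prob": prob,
                "regulated": site_id in regulated,
            }
            for (site_id, tissue), prob in sorted(self.truth.inclusion.items())
        ]
        fio.write_results_tsv(
            rows,
            paths["ground_truth"],
            columns=["site_id", "tissue", "inclusion_prob", "regulated"],
        )
        return paths


def _window_to_blocks(
    segments: Sequence[tuple[int, int]], ws: int, we: int
) -> tuple[tuple[int, int], ...]:
    """Map a half-open window in isoform coordinates to reference blocks."""
    blocks: list[tuple[int, int]] = []
    offset = 0
    for seg_start, seg_end in segments:
        seg_len = seg_end - seg_start
        lo = max(ws, offset)
        hi = min(we, offset + seg_len)
        if lo < hi:
            blocks.append((seg_start + lo - offset, seg_start + hi - offset))
        offset += seg_len
    return tuple(blocks)


def simulate_est_dataset(config: SimulationConfig) -> SimulatedESTData:
    """Generate the full synthetic bundle from *config*; seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    references: list[ReferenceSequence] = []
    sites: list[MRESite] = []
    truth_inclusion: dict[tuple[str, str], float] = {}
    for g in range(config.n_genes):
        gene_id = config._gene_id(g)
        seq = "".join(_BASES[rng.integers(0, 4, size=config.gene_length)])
        ref = ReferenceSequence(id=gene_id, sequence=seq)
        references.append(ref)
        for k, ((_, _), (ms, me)) in enumerate(config.exon_layout):
            site_id = f"{gene_id}:site{k + 1}"
            sites.append(
                MRESite(
                    site_id=site_id,
                    reference_id=gene_id,
                    mirna_id=f"syn-miR-{k + 1}",
                    start=ms,
                    end=me,
                    site_sequence=seq[ms:me],
                    validation="true",
                )
            )
            for tissue in config.tissues:
                truth_inclusion[(site_id, tissue.name)] = config.inclusion(
                    site_id, tissue.name
                )

    libraries: list[LibraryAnnotation] = []
    libs_by_tissue: dict[str, list[str]] = {}
    for tissue in config.tissues:
        ids = [f"{tissue.name}-lib{j + 1}" for j in range(tissue.n_libraries)]
        libs_by_tissue[tissue.name] = ids
        libraries.extend(
            LibraryAnnotation(lib_id, tissue.name, tissue.histology)
            for lib_id in ids
        )

    alignments: list[ESTAlignment] = []
    est2lib: dict[str, str] = {}
    wmin, wmax = config.est_window
    counter = 0
    for g in range(config.n_genes):
        gene_id = config._gene_id(g)
        for tissue in config.tissues:
            tissue_libs = libs_by_tissue[tissue.name]
            probs = [
                config.inclusion(f"{gene_id}:site{k + 1}", tissue.name)
                for k in range(len(config.exon_layout))
            ]
            for _ in range(tissue.n_ests):
                counter += 1
                est_id = f"est{counter:06d}"
                lib_id = tissue_libs[int(rng.integers(len(tissue_libs)))]
                keep = [rng.random() < p for p in probs]
                # isoform = gene minus the skipped cassette exons
                segments: list[tuple[int, int]] = []
                pos = 0
                for kept, ((es, ee), _) in zip(keep, config.exon_layout):
                    if not kept:
                        if es > pos:
                            segments.append((pos, es))
                        pos = ee
                if pos < config.gene_length:
                    segments.append((pos, config.gene_length))
                # merge adjacent segments when no exon was skipped between them
                merged: list[tuple[int, int]] = []
                for seg in segments:
                    if merged and merged[-1][1] == seg[0]:
                        merged[-1] = (merged[-1][0], seg[1])
                    else:
                        merged.append(seg)
                iso_len = sum(e - s for s, e in merged)
                lo = min(wmin, iso_len)
                hi = min(wmax, iso_len)
                wlen = int(rng.integers(lo, hi + 1))
                wstart = int(rng.integers(0, iso_len - wlen + 1))
                blocks = _window_to_blocks(merged, wstart, wstart + wlen)
                alignments.append(
                    ESTAlignment(
                        est_id=est_id,
                        reference_id=gene_id,
                        library_id=lib_id,
                        blocks=blocks,
                    ).validate(config.gene_length)
                )
                est2lib[est_id] = lib_id

    truth = GroundTruth(
        inclusion=truth_inclusion,
        regulated_site_ids=sorted(config.regulated_sites),
    )
    return SimulatedESTData(
        references=references,
        alignments=alignments,
        libraries=libraries,
        est2lib=est2lib,
        sites=sites,
        truth=truth,
    )


def simulate_null_est_dataset(config: SimulationConfig) -> SimulatedESTData:
    """Simulate under the null: identical inclusion in every tissue.

    Requires *config* to plant nothing and to give all tissues the same
    inclusion probability; the ground truth then lists no regulated site.
    """
    if config.regulated_sites:
        raise ValueError("null simulation must not plant regulated sites")
    probs = {
        config.inclusion_prob.get(t.name, config.inclusion_prob.get("default", 0.5))
        for t in config.tissues
    }
    if len(probs) > 1:
        raise ValueError(
            f"null simulation requires one shared inclusion probability, "
            f"got {sorted(probs)}"
        )
    data = simulate_est_dataset(config)
    assert not data.truth.regulated_site_ids
    return data


@dataclass
class ProteinGroundTruth:
    delta_seed: float
    delta_as: float
    sigma: float
    n_background: int
    n_seed: int
    n_predicted: int
    n_as: int


def simulate_protein_table(
    n_background: int,
    n_seed: int,
    n_predicted: int,
    n_as: int,
    sigma: float = 0.3,
    delta_seed: float = 0.5,
    delta_as: float = 0.5,
    seed: int = 0,
) -> tuple[list[ProteinChangeRecord], ProteinGroundTruth]:
    """Protein log2-fold-change table with planted repression shifts.

    Background (seed-free) records draw lfc ~ Normal(0, sigma^2); every
    seed-carrying record is shifted down by *delta_seed*; the alternatively
    spliced subset is shifted down by an additional *delta_as*.  Nesting
    n_as <= n_predicted <= n_seed is enforced and the emitted flags satisfy
    the partition invariants.  Seed-deterministic.
    """
    if not (0 <= n_as <= n_predicted <= n_seed):
        raise ValueError("need 0 <= n_as <= n_predicted <= n_seed")
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    if sigma < 0 or delta_seed < 0 or delta_as < 0:
        raise ValueError("sigma and deltas must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[ProteinChangeRecord] = []
    idx = 0
    for _ in range(n_background):
        idx += 1
        records.append(
            ProteinChangeRecord(
                gene_symbol=f"PROT{idx:05d}",
                log2_fold_change=float(rng.normal(0.0, sigma)),
                has_seed=False,
                predicted_target=False,
                splicing_regulated=False,
            )
        )
    for i in range(n_seed):
        idx += 1
        is_predicted = i < n_predicted
        is_as = i < n_as
        shift = delta_seed + (delta_as if is_as else 0.0)
        records.append(
            ProteinChangeRecord(
                gene_symbol=f"PROT{idx:05d}",
                log2_fold_change=float(rng.normal(0.0, sigma) - shift),
                has_seed=True,
                predicted_target=is_predicted,
                splicing_regulated=is_as,
            )
        )
    truth = ProteinGroundTruth(
        delta_seed=delta_seed,
        delta_as=delta_as,
        sigma=sigma,
        n_background=n_background,
        n_seed=n_seed,
        n_predicted=n_predicted,
        n_as=n_as,
    )
    return records, truth
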