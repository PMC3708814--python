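# splicemre

Detection of **splicing-regulated microRNA recognition elements (MREs)**
from spliced EST evidence.

MicroRNAs repress protein output by binding short recognition elements on
their target mRNAs. When an MRE sits inside a cassette exon (or any
alternatively used region), splicing decides per transcript whether the
binding site is present at all: MRE-containing isoforms remain under
microRNA control while MRE-free isoforms escape it. A tissue that shifts
the balance between the two isoform classes is thereby fine-tuning the
repression of a single gene without touching the microRNA itself. This
package detects that situation from expressed-sequence-tag (EST) evidence
and asks whether the splicing-regulated sites are also the strongly
repressive ones.

It is aimed at transcriptomics researchers who have (or simulate)
spliced EST alignments over reference transcripts, tissue-annotated cDNA
libraries, and curated MRE catalogs.

## The method

1. **Placement.** MRE sequences are placed on each reference transcript by
   perfect full-length exact match (`locate_mre`); candidate sites can also
   be nominated by seed complementarity — the 7-mer reverse complement of
   microRNA nucleotides 2–8 (`find_seed_matches`).
2. **EST configuration.** Each spliced EST alignment is classified against
   a given MRE interval into one of five configurations: (i) partial or no
   overlap (uninformative), (ii) MRE inside an exon block
   (MRE-**containing** isoform), (iii) MRE inside a block gap / putative
   intron (MRE-**free**), (iv) MRE split across an exon–intron junction
   (counted MRE-free: the partial site is presumed non-functional), and
   (v) a defensive catch-all for structurally anomalous alignments.
3. **Fisher exact test.** For every tissue *t* the informative ESTs form a
   2×2 table of MRE-free / MRE-containing counts in *t* versus all other
   tissues. With margins fixed, the MRE-free count *a* in the focal tissue
   follows a hypergeometric law

   P(X = k) = C(K, k) · C(N−K, n−k) / C(N, n)

   and the package reports P_left = P(X ≤ a) (containing-isoform
   enrichment), P_right = P(X ≥ a) (free-isoform enrichment) and the
   minimum-likelihood two-tailed P. Tests are restricted to genes and
   tissues with ≥ 10 informative ESTs; an MRE significant (two-tailed
   P < 0.05) in at least one tissue is called **splicing-regulated**.
   Optionally the test stratifies libraries by histology (normal vs
   cancer).
4. **MRE regions.** Sites overlapping by ≥ 90 % of the shorter site are
   merged (single linkage) into *MRE regions*; a region whose maximum
   member repressive ratio reaches 30 % is called **highly repressive**.
5. **Null model.** Random MREs (18–22 nt, 100 per set) are drawn as real
   substrings of the references and pushed through the same test; the
   observed regulated fraction is compared with the per-set random
   fractions by a one-sample Wilcoxon signed-rank test (exact sign
   enumeration up to n = 25).
6. **Protein-level shifts.** SILAC-style log2 fold changes are converted
   to percent expression change, (2^lfc − 1)·100, partitioned into nested
   sets (seed-free, seed, seed∩predicted, seed∩predicted∩spliced), drawn
   as cumulative curves and compared with two-sample Kolmogorov–Smirnov
   tests.

A synthetic-data module generates references, tissue-labelled EST
libraries with controllable per-tissue MRE-exon inclusion probabilities,
and protein tables with planted repression shifts, so every stage is
testable with known ground truth.

## Worked example

```python
from splicemre import ContingencyTable, fisher_exact, merge_regions, region_report, summarize_region
from splicemre.datasets import load_vegf_mre_catalog

# A gene whose MRE appears in 7 brain ESTs but is absent (spliced out) in 3,
# while the other tissues show 1 containing vs 6 free; a = MRE-free in brain.
res = fisher_exact(ContingencyTable(a=3, b=7, c=6, d=1))
print(f"left={res.p_left:.6f} right={res.p_right:.6f} two-tail={res.p_twotail:.6f}")

# The bundled VEGF catalog: 30 curated microRNA sites with repressive ratios.
regions = merge_regions(load_vegf_mre_catalog())
print(region_report(regions))
print(summarize_region(regions[1]))
```

prints

```
left=0.036405 right=0.998149 two-tail=0.049774
RegionReport(n_regions=13, n_highly_repressive=9, n_supported_any=5,
             n_supported_cancer=4, n_supported_normal=2,
             n_supported_and_highly_repressive=5)
RegionSummary(repression_min=19.0, repression_max=41.0,
              highly_repressive=True, n_mirnas=9, available=True)
```

The left-tailed P of 0.036 says brain tissue carries significantly more
MRE-containing isoforms than the rest of the body, so brain is the tissue
where this microRNA can act on the gene. The VEGF catalog merges into 13
MRE regions, of which 9 are highly repressive (ratio ≥ 30 %); all 5
regions with tissue-level splicing support are among the highly
repressive ones — the association the pipeline is designed to expose.

The same stages are available as a CLI:

```bash
splicemre simulate --config sim.yaml --out bundle/
splicemre enrich --bed bundle/ests.bed --est2lib bundle/est2lib.tsv \
    --libraries bundle/libraries.tsv --mre-table bundle/mre_catalog.tsv --out enr/
splicemre regions --mre-table mre_catalog.tsv --out regions/
splicemre nulltest ... / splicemre silac ... / splicemre report ...
```

Every run writes TSV results plus a `manifest.json` recording inputs,
parameters and seed; identical configuration and seed give byte-identical
outputs.

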