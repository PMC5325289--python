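# smartbias

Quality control for the poly dA/dT bias of SMART (template-switching) DNA
sequencing libraries.

Template-switching library preparation appends a poly dT tail to each DNA
fragment's 3' end (terminal deoxytransferase) and captures fragments by
annealing a poly dA primer to that tail. When tailing is incomplete, the
primer instead anneals to *genomic* poly dT runs, so sequenced second-read
ends pile up immediately 5' of poly dT tracts (forward strand) and poly dA
tracts (reverse strand), internally primed fragments are truncated and
shorter, and many reads end at exactly the same genomic coordinate. This
bias distorts any counting-based assay (ChIP-seq, CNV, ATAC-seq) built on
such libraries. `smartbias` detects the signature, quantifies it, and
removes it.

For a library of N fragments, the package computes per tract base b and
strand s the count n(b, s) of fragments whose tail-side window (the
fragment span extended 1 bp past the tailed end, `bedtools window`
arithmetic) overlaps a homopolymer tract of b with length >= 12, normalizes
it as

    enrichment(b, s) = [ n(b, s) / N x 10^6 ] / #{genomic tracts of b, >= 12}

and summarizes the deviation of {n(b, s)} from the census-expected
proportions with a chi-squared goodness of fit and Cramér's phi effect size

    phi_c = sqrt( chi2 / ( N_adj (k - 1) ) ),

which stays interpretable at depths where every p-value is significant.
Companion statistics: the forward/reverse fold-ratio curve by tract length,
position frequency / information-content matrices around read ends, the
coincident-end cluster fraction, a Welch t-test of fragment lengths split
by adjacency, shift-randomization and random-fragment nulls, and the
recommended mitigation — removing all reads adjacent to mismatch-tolerant
poly dA/dT tracts (>= 12 bp, up to 2 mismatches). A truth-labeled simulator
(genome with planted tracts + libraries with a configurable
internal-priming fraction) makes every stage testable without external
data. See `docs/methods.md` for the full model.

## Worked example

```python
import dataclasses
from smartbias import (
    SimConfig, make_genome, simulate_smart_library, adjacent_fragments,
    find_exact_tracts, tract_census, normalized_enrichment, filter_reads,
)

cfg = SimConfig(genome_length=1_000_000, n_fragments=200_000, p_internal=0.15)
genome, truth_tracts = make_genome(cfg, seed=101)
frags, truth = simulate_smart_library(genome, truth_tracts, cfg, seed=1)

tracts = [t for b in "ACGT"
          for t in find_exact_tracts(genome["chr1"], b, 5, chrom="chr1")]
table = adjacent_fragments(frags, tracts, distance=1)
report = normalized_enrichment(table, tract_census(genome), min_len=12)
print(report.frame[report.frame.strand == "+"][["base", "count", "normalized"]])
print("phi(+) = %.3f" % report.gof["+"].phi)

kept, removed, fr = filter_reads(frags, genome=genome)
print("removed %.1f%%, clusters %.3f -> %.3f"
      % (100 * fr.fraction_removed, fr.cluster_before, fr.cluster_after))
```

Output:

```
  base  count   normalized
0    A   1186    97.213115
1    C      0          NaN
2    G     22   110.000000
3    T  16043  1743.804348
phi(+) = 0.721
removed 18.8%, clusters 0.151 -> 0.000
```

Reading it: on the forward strand 16,043 of 200,000 fragments overlap or
end against a poly dT tract >= 12 (the planted 15% internal-priming
fraction plus the unbiased background), versus 1,186 for poly dA and almost
none for C/G; normalized by how many such tracts the genome offers, T is
~18-fold above A and the per-strand effect size is phi = 0.72 (an unbiased
library gives phi < 0.01). C has no tract >= 12 in this genome, so its
normalized value is flagged undefined rather than zero. The tolerant-tract
filter removes 18.8% of this library and takes the coincident-end cluster
fraction from 0.151 to 0.

The same operations are exposed as a CLI for file-based work:

```sh
smartbias simulate --out-dir sim/ --seed 3 --p-internal 0.15
smartbias tracts --fasta sim/genome.fa --base T --min-len 12 --max-mm 2 --out tracts.bed
smartbias adjacency --frags sim/fragments.bed --tracts sim/tracts_truth.bed --fasta sim/genome.fa
smartbias filter --frags sim/fragments.bed --fasta sim/genome.fa --out kept.bed --rejects rejects.bed
```

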