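# regmut

Statistics of somatic single-nucleotide variants (SNVs) within arbitrary
small sets of genomic regions — transcription-factor binding sites,
promoters, CTCF sites at TAD boundaries, or any other BED3 interval
collection. `regmut` is a scriptable library plus CLI for cancer
genomicists who want to ask, for a region set *R* and a tumor cohort *M*:

- Are the regions locally **hyper- or hypomutated** relative to their own
  flanking sequence?
- How do two region sets, or two tumor types, **differ** in their
  region-versus-flank mutation rates?
- What does the **96-channel trinucleotide spectrum** of the in-region
  mutations look like, per cohort and per donor (with Ti/Tv counts)?
- Which **mutational processes** produced those mutations — i.e. what are
  the signature exposures, once the signatures are adjusted for the
  regions' trinucleotide content?

## The statistics at the core

**Local enrichment.** Each region *r<sub>i</sub>* is aligned on its
central point ⌊(start + stop)/2⌋ and wrapped in a window of half-width
*h* (by default *h* = the largest region size, floored at 1 kbp and capped
at 5 kbp). All mapped mutations are re-positioned uniformly at random
within their windows; the *P*-value is the fraction of 10 000 permutations
in which the permuted in-target count reaches the observed one (≥ for
hypermutation, ≤ for hypomutation). Comparing targets with their own
flanks sidesteps accessibility and chromatin biases. Two conditions are
compared with a Pearson χ² test of independence (df = 1, no continuity
correction) on C = [[f₁, r₁], [f₂, r₂]], the per-base mutation rates in
flanks (f) and targets (r).

**Region-adjusted signature refitting.** Given a signature catalog
S = {s_k} and the in-region spectrum ⟨m_j⟩ over the 96
substitution-in-context channels, exposures e solve

    min ‖ m − Σ_k e_k s_k ‖²   s.t.  e_k ≥ 0,  Σ_k e_k = 1.

COSMIC signatures are normalized to whole-genome trinucleotide
frequencies, which small region sets do not share. Each signature is
therefore adjusted first with opportunity correction factors

    c_t = freq_R(t) / freq_G(t),   s'_k(j) = c_{t(j)} · s_k(j),

renormalized so Σ_j s_k^adj(j) = 1. The quadratic program is solved
exactly by a deterministic active-set method.

## Worked example

Simulate a cohort with known ground truth (10 donors, 400 mutations each,
drawn from three synthetic signatures with exposures 0.6/0.3/0.1 and a
5-fold in-region enrichment), then test enrichment and refit:

```sh
regmut simulate --out-dir demo --seed 5 --genome-length 50000 \
    --n-regions 30 --region-size 60 --n-donors 10 \
    --mutations-per-donor 400 --exposures 0.6,0.3,0.1 \
    --n-signatures 3 --enrichment 5

regmut test-enrichment --regions demo/regions.bed \
    --mutations demo/mutations.tsv --n-perm 10000 --seed 1 \
    --out demo/enrich.json
# observed 625/4724 in targets; P < 0.0001

regmut refit --regions demo/regions.bed --mutations demo/mutations.tsv \
    --genome demo/genome.fa --signatures demo/signatures.tsv \
    --per-donor --out demo/refit.json
```

`demo/enrich.json` reports 625 of 4724 mapped mutation–window pairs inside
the targets, far above the uniform expectation, with a permutation
*P* < 10⁻⁴ (no permutation reached the observed count, so the plain
fraction is reported as a bound). `demo/refit.json` contains the
per-donor exposures and the cohort mean in percent:

```json
{"SYN01": 58.97, "SYN02": 31.23, "SYN03": 9.80}
```

— recovering the planted 60/30/10% mixture. Other subcommands follow the
same pattern: `histogram`, `compare-regions`, `compare-tumors`, `trinuc`,
`per-donor`. Donor cohorts can be restricted with predicates such as
`--donor-filter "(donor_sex = 'M') AND (first_therapy_type IN
{'chemotherapy', 'surgery'})"`.

Everything is equally usable as a library:

```python
from regmut import read_bed, read_mutations, read_fasta, \
    read_signature_catalog, refit_regions

cohort = refit_regions(
    read_mutations("demo/mutations.tsv"), read_bed("demo/regions.bed"),
    read_fasta("demo/genome.fa"), read_signature_catalog("demo/signatures.tsv"),
    adjust=True, per_donor=True,
)
print(cohort.mean_as_dict())
```

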