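# hybridogen

Tools for characterizing **hybridogenetic water-frog populations** from
reduced-representation sequencing and microsatellite data.

The edible frog *Pelophylax* kl. *esculentus* is a hybrid between the
pool frog *P. lessonae* (genomes LL) and the marsh frog *P. ridibundus*
(genomes RR).  Hybrids are usually diploid (LR) but triploid LLR and LRR
forms sustain some all-hybrid populations, and hemiclonal reproduction
(hybridogenesis) makes the genetics of these assemblages unusual: one
parental genome is excluded from the germline and the other is
transmitted clonally.  Surveying such systems requires answering, from
marker data: which frogs are parental and which hybrid, whether hybrids
are diploid or triploid, and which cross outcomes a hypothesized system
can actually produce.  `hybridogen` implements that toolkit for
geneticists working on hybridogenetic or otherwise hemiclonal taxa:

* **Diagnostic-locus discovery** — find SNPs with an allele-frequency
  difference of 1.0 between LL and RR reference panels, oriented as
  L-allele / R-allele.
* **Ploidy from allele depths** — at each diagnostic locus of a hybrid,
  the coverage ratio `max(d_L, d_R) / min(d_L, d_R)` tends to **1** in
  LR diploids (one copy of each genome) and to **2** in LLR/LRR
  triploids (one allele on two of three copies).  Per-individual mean
  and pooled ratios are reported with a guard-banded call, plus a
  binomial-likelihood call over dosage fractions p_L ∈ {½, ⅓, ⅔}.
* **Ploidy from microsatellite peaks** — the peak-height ratio
  `PHR = log10(H_R / H_L)` of co-amplifying L/R-specific alleles,
  classified against genotype-specific calibrated ranges (LR diploids
  −0.23–0.00; LLR −0.54 – −0.29; LRR 0.09–0.25 for the packaged
  RICA1b5-type calibration), with tri-allelic detection.
* **Population summaries** — observed heterozygosity H_o per
  (population × taxon) group and a diagnostic-locus hybrid index that
  assigns LL / LR / RR.
* **Cross models** — exact gamete and offspring distributions for
  hybridogenetic systems with sex-chromosome tracking (the R genome is
  strictly X-linked; hybrid males are L<sub>y</sub>R<sub>x</sub>,
  females L<sub>x</sub>R<sub>x</sub>), with presets for the L-E and R-E
  systems, mixed-ploidy all-hybrid systems, and diploid all-hybrid
  maintenance by "hybrid amphigamy".
* **Synthetic cohorts** — a generator for genotype matrices with
  per-allele depths, population maps, peak tables and truth tables, so
  the whole pipeline is testable end to end.

## Worked example

Simulate a cohort (8 LL, 5 RR, 12 LR, 3 LLR, 3 LRR over 600 SNPs, 250
of them diagnostic, mean depth 50×) and run the full pipeline:

```sh
hybridogen simulate --config sim.yaml --out cohort
hybridogen run --config run.yaml
```

prints the summary

```json
{
  "n_diagnostic_loci": 250,
  "ploidy_counts":    {"DIPLOID_LR": 12, "TRIPLOID_LLR": 3, "TRIPLOID_LRR": 3},
  "ploidy_counts_ml": {"DIPLOID_LR": 12, "TRIPLOID_LLR": 3, "TRIPLOID_LRR": 3},
  "taxon_counts":     {"LL": 8, "LR": 18, "RR": 5}
}
```

All 250 planted diagnostic loci are recovered; the hybrid index calls
the 8+5 parental frogs and the 18 L/R-heterozygous hybrids; within the
hybrids, both the depth-ratio heuristic and the likelihood call split
12 diploids from the 3+3 triploids — matching the simulated truth.

Single crosses print exact offspring tables; under the hypothetical
diploid all-hybrid system, where both sexes transmit L or R gametes
with probability ½:

```
$ hybridogen cross --preset E_E_DIPLOID_AMPHIGAMY --mother LxRx --father LyRx
genotype composition sex  pre_viability_p  post_viability_p
    LxLy          LL   M             0.25               0.0
    LxRx          LR   F             0.25               0.5
    LyRx          LR   M             0.25               0.5
    RxRx          RR   F             0.25               0.0
```

Note the sex linkage: every RR by-product is female, every LL male, and
both carry the hybridogenetic load (zero post-viability mass).

The library mirrors each CLI subcommand
(`hybridogen.diagnostics.find_diagnostic_loci`,
`hybridogen.dosage.individual_dosage_profile`,
`hybridogen.phr.compute_phr`, `hybridogen.crosses.cross`, …); see
`docs/methods.md` for the statistical model behind each stage.

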