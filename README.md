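# lipidlink

Coupled marker-gene / lipidome inference for microbial community time
series, built for the setting where groundwater erupting from a cold,
CO2-driven geyser samples aquifers of different depths over an eruption
cycle. Organisms are tracked across samples by the relative abundance of
scaffolds carrying the single-copy marker gene rpS3 (ribosomal protein S3);
intact polar lipids (IPLs) — membrane lipids retaining their polar
headgroup, a proxy for living biomass — are tracked by the same kind of
percent-abundance trajectories. The package answers three questions a
community lipidomics study asks:

1. **Who makes which lipid?** Organism and lipid trajectories are
   correlated pairwise (Pearson r, two-sided p from the t distribution with
   n−2 df) over features detected in at least 7 of 14 samples. p-values are
   Bonferroni-corrected, and the corrected value q is weighted by organism
   abundance, `score = q / mean percent abundance`, so that abundant
   organisms — much more likely to leave a detectable lipid signal — are
   preferred. Each lipid is assigned to at most one organism (lowest score
   among records with q < 0.005): a **primary** lipid. Lipids without a
   direct assignment but co-correlated (q < 0.005, separate Bonferroni
   universe) with a primary lipid are **secondary**; a candidate touching
   primary lipids of two or more organisms is **unspecific**. The result is
   a network (GraphML/TSV export) plus a per-organism assignment table.

2. **Where does the carbon come from?** Lipid δ13C values (‰ vs. VPDB) are
   decomposed with two-endmember mass balances. On the fractionation scale,
   the bacterial fatty-acid pool's observed εCO2–lipid is split between the
   rTCA cycle (ε ≈ 12‰) and the CBB cycle (ε ≈ 30‰), each optionally
   deepened by a 5‰ lipid-vs-biomass offset:
   `f_rTCA = (ε_CBB − ε_obs) / (ε_CBB − ε_rTCA)`.
   On the δ scale, archaeal phytane is split between Wood–Ljungdahl
   autotrophy (εDIC–lipid ≈ 63‰) and uptake of bacterial organic carbon:
   `f_auto = (δ_obs − δ_het) / (δ_auto − δ_het)`. Fractions are clamped to
   [0, 1] with an explicit flag.

3. **How is the membrane built?** Lipid names are parsed by a small grammar
   (`C36:4-PC`, `lyso_C18:2-DGTA`, `2G-1uns-ext-AR`, …) into headgroup,
   summed acyl carbons, double-bond equivalents and lyso/ether/archaeal
   flags; abundance is aggregated into double-bond classes (0–6, "7+") per
   sample, and lysolipid content is profiled with a betaine-headgroup
   breakdown.

A seeded synthetic-data generator produces coupled organism/lipid/isotope
bundles with known planted truth (producer links, symbiont-derived lipids,
shared lipids, isotope mixing fractions), so the whole chain is testable
without any external download.

## Worked example

```sh
lipidlink simulate --seed 42 --noise-sd 0.1 --out-dir bundle/
lipidlink run-all --in-dir bundle/ --out-dir out/
```

prints (stderr logging omitted):

```
archaeal_autotrophic_fraction: max 0.700 min 0.399
bacterial_rTCA_fraction: max 0.711 min 0.114
lysolipids: 8/40 (20%)
{
 "n_primary_lipids": 33,
 "n_organisms_with_lipids": 20,
 "n_secondary_lipids": 0,
 "n_unspecific": 0,
 "n_unassigned": 7,
 "truth_precision": 1.0,
 "truth_recall": 1.0,
 ...
}
```

Reading: all 20 planted producer→lipid links were recovered
(`truth_precision`/`truth_recall` = 1.0 against the bundle's `truth.json`);
33 lipids got a direct organism assignment; the isotope series implies that
rTCA-fixed carbon contributes up to 71% of bacterial biomass in
shallow-aquifer samples of this synthetic cycle, and archaeal biomass is up
to 70% autotrophic. `out/` contains the correlation table, assignment
table, network (TSV + GraphML), per-sample mixing fractions and
unsaturation profiles.

The packaged reference assignment table (transcribed organism/lipid roles
from a 14-sample groundwater study) summarises as:

```sh
lipidlink summarize
# {"n_primary_lipids": 44, "n_organisms_with_lipids": 22,
#  "n_secondary_lipids": 63, ...}
```

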