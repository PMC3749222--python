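# Supplementary genotype tables (not distributed)

`test_supplementary_reference_values` expects here a file
`minht_haplotypes.tsv` converted from the source study's per-sample
supplementary genotype spreadsheets, which cannot be redistributed with
this package. Layout (tab-delimited, UTF-8):

```
sample_id  population  region  haplogroup  DYS19  DYS389I  DYS389B  DYS390  DYS391  DYS392  DYS393
```

* `region` groups populations as `Mexico`, `Andes`, `Central America`,
  `South East America`, `Asia`.
* `haplogroup` is a node-marker label as produced by `ystrkit.classify`
  (e.g. `Q1a3a1a-M3*`).
* `DYS389B` may be replaced by a `DYS389II` column (the reader derives
  DYS389B by subtraction). Micro-variant alleles keep their decimal form
  (`13.2`); duplicated alleles are comma-joined in one cell.

Without this file the test fails at data load.
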