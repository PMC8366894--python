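# pennid

Molecular identification of ornamental fountain grasses: does a plant in
trade belong to the invasive *Pennisetum setaceum*, to the cultivated
species *P. advena*, or is it a hybrid of the two?

The two species are hard to separate morphologically but differ at three
DNA barcode loci: the chloroplast rbcL gene (2 fixed substitutions), the
chloroplast trnH-psbA intergenic spacer (4 fixed substitutions), and the
nuclear ribosomal ITS region (~90% identity between species). ITS is
present in many copies per genome, so a single plant can carry several
ITS sequence variants at once — *P. advena* carries two (aI/aII,
differing at 3 positions), *P. setaceum* two (sI/sII, at 2 positions) —
and a hybrid carries variants of both species simultaneously. Because the
chloroplast is maternally inherited, a hybrid's chloroplast haplotype
names its seed parent.

`pennid` implements that identification workflow end to end:

- **refpanel** — locus reference panels, global pairwise alignment
  (match +1, mismatch −1, gap open −3, gap extend −1), percent identity,
  and extraction of diagnostic sites between the species.
- **simdata** — a synthetic-data generator reproducing the divergence
  structure above, with per-specimen Sanger-style read pairs and short
  reads drawn from configurable intra-individual ITS variant mixtures,
  fully reproducible from one master seed.
- **sangerproc** — primer trimming, PHRED>30 quality trimming, and
  bidirectional consensus assembly with IUPAC ambiguity codes; assembly
  fails when the template is a mixture of two haplotypes offset by an
  indel (the frameshifted double trace).
- **readmap** — semi-global read mapping to amplicon references and
  pileup construction.
- **varcall** — frequency-threshold variant detection, ITS informative
  sites, and mixture deconvolution: each read votes for its
  nearest ITS variant by Hamming distance over the informative sites it
  covers; ties are reallocated in proportion to the estimated mixture
  (a fixed-point/EM iteration), giving consistent proportion estimates.
- **speccall / pipeline** — per-locus haplotype assignment
  (a/s/mixed/unresolved), the species/hybrid verdict with maternal
  lineage, an advisory morphological range check (leaf width, stipe
  length, inflorescence posture, leaf blade), and the per-specimen
  report table.

## Worked example

```python
from pennid.pipeline import run_study
from pennid.simdata import PanelConfig, ReadSimConfig
from pennid.speccall import render_report

calls, frame, scenarios, panel = run_study(
    PanelConfig(seed=7),
    ReadSimConfig(coverage=1000, error_rate=0.001, seed=7))
print(render_report(frame))
```

This simulates the 13-specimen study (2 wild/trade *P. advena*, 5 named
cultivars, 6 *P. setaceum* accessions) and types every specimen.
Abridged output:

```
    specimen_id rbcL trnH-psbA         ITS ITS_ratio_pct  verdict maternal_lineage
Valkenburg 4026    a         a     aI, aII         55/45   advena           advena
Cherry Sparkler    a         a aI, aII, sI      44/15/41   hybrid           advena
     Sky Rocket    a         a aI, aII, sI      19/50/31   hybrid           advena
    Mooney 9419    s         s     sI, sII         33/67 setaceum         setaceum
    Simons 2006    s         s     sI, sII         70/30 setaceum         setaceum
```

Reading a row: `rbcL`/`trnH-psbA` carry the species' fixed chloroplast
alleles (`a` = advena, `s` = setaceum); `ITS` lists the intra-individual
ITS variants detected with their estimated percentages. "Cherry
Sparkler" carries both advena variants *and* a setaceum variant at
44/15/41 — nuclear additivity marking a hybrid — while its all-`a`
chloroplast makes *P. advena* the seed parent. For "Simons 2006" the
trnH-psbA Sanger pair fails to assemble (two co-occurring haplotypes
offset by a 1-nt insertion); the pipeline falls back to short reads,
detects the ~50/50 indel mixture, and still types the locus as `s`.

The same workflow is available from the shell:

```bash
pennid simulate --seed 7 --out study/
pennid run --panel study/panel.fasta --manifest study/manifest.tsv --out report.tsv
```

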