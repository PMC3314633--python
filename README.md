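# mirnovel

Discovery of novel microRNAs from small-RNA sequencing data, with
microarray cross-validation.

Most mammalian miRNA catalogs are incomplete — the rat, despite its role
as a toxicology model, has far fewer annotated miRNAs than mouse or
human.  `mirnovel` re-implements, as a tested and reusable pipeline, the
classic discovery procedure used to find novel miRNAs in rat kidney
small-RNA libraries: deep-sequencing reads are cleaned, routed against
known-miRNA and contaminant references, mapped to the genome, clustered
into putative mature loci, folded into hairpin candidates, screened by
Dicer cleavage geometry, aggregated across samples, and finally
cross-checked against a custom miRNA microarray.  It is aimed at desk
scale: method development, teaching, and reanalysis of the published
worked examples — not whole-genome production runs.

## The procedure

For each strand-aware cluster of genome-mapped reads (the putative
mature locus), genomic windows are extracted under both arm hypotheses
and folded with a minimum-free-energy (MFE) algorithm.  A candidate
hairpin must satisfy

* a single stem–loop with **≥ 19 base pairs** in the structure and
  **≥ 11 base pairs** touching the read-cluster region;
* a mature/mature\* duplex with a **1–4 nt 3′ overhang** at both duplex
  ends (the canonical Dicer signature is 2 nt), computed from the pair
  table under a duplex-register convention anchored at a paired 5′
  terminus;
* **< 2 nt fluctuation** of read 5′ start positions around the
  predominant (most expressed) read, whose length defines the mature
  product.

The precursor is trimmed at the first bulge 5′ of the mature arm and the
structure-paired position opposite it, with a 65-nt floor when no bulge
is reached.  Calls require detection in **≥ 4 of 8** sequencing samples;
homologous calls (matching a known miRNA of another species) need read
counts > 10 in those samples *or* rescue by array evidence, while
species-specific calls need ≥ 10 reads in **every** sample and an array
intensity ≥ 32 in **every** array.  Group differences on the array use a
two-sample t-test on log2 intensities (Welch by default).

Two folding models sit behind one interface: the ViennaRNA
nearest-neighbor thermodynamic model (used when its Python bindings are
importable) and a built-in maximum-weighted-pairing dynamic program
(GC = 3, AU = 2, GU = 1, loop ≥ 3 nt) that keeps the pipeline
dependency-free.

A synthetic benchmark generator (`mirnovel.synthetic`) plants verifiable
hairpin loci — Dicer-consistent read stacks with mature/star asymmetry
and isomiR end variants — alongside degradation and shuffled-sequence
decoys, known-miRNA and ncRNA loci for routing, and a matching 3 + 3
intensity matrix, all bit-reproducible from a seed.  The printed
precursor and expression tables of the original rat-kidney study are
packaged as fixtures (`mirnovel.fixtures`) and drive the worked-example
tests.

## Worked example

Simulate a benchmark and run the species-specific discovery pass:

```python
from mirnovel.pipeline import PipelineConfig, run_specific_pass, funnel_table
from mirnovel.synthetic import (build_reference_sets, plant_genome,
                                simulate_intensities, simulate_reads, score_calls)

truth = plant_genome(n_true=8, n_decoy=8, contig_len=1_000_000, seed=1)
reads = simulate_reads(truth, seed=1)
matrix, probes = simulate_intensities(truth, seed=1)
calls, funnel = run_specific_pass(reads, build_reference_sets(truth),
                                  PipelineConfig(), matrix, probes)
print(funnel_table(funnel))
```

prints the per-stage funnel

```
input_molecules       97316
input_unique_reads    393
cleaned_unique_reads  388
routed_kept_reads     310
genome_mapped_reads   294
read_clusters         35
dicer_candidates      22
consensus_calls       12
not_known_mirna       10
final_calls           4
```

reading top to bottom: ~97k simulated read molecules collapse to 393
unique sequences; routing removes reads matching known miRNAs and
excluded RNA classes; 35 read clusters survive genome mapping, of which
22 pass the hairpin and Dicer-pattern screens, 12 consensus loci are
seen in ≥ 4 samples, 10 are not re-discoveries of known miRNAs, and 4
clear the every-sample read and array cutoffs.  Those four calls are
exactly the four planted rat-specific-style loci
(`score_calls(truth, calls, "specific")` reports recovery 1.0 with zero
decoy calls):

```
rno-mir-5001  chrS1:233995-234067(+)  mature=CCCGUCACAAGAUAUCGGCACU  samples=8  validated=True
rno-mir-5002  chrS1:269065-269133(-)  mature=UAUCAUGCAAUAUGAUGUGUUU  samples=8  validated=True
rno-mir-5004  chrS1:454417-454481(+)  mature=GAAUCGCUAGGAGCCUUCCC   samples=8  validated=True
rno-mir-5006  chrS1:921260-921326(-)  mature=GUAAGGUGGUCUGGGGUAUGUC  samples=8  validated=True
```

The same machinery runs from the shell:

```bash
mirnovel simulate --preset paperlike --seed 1 --outdir bench/
mirnovel discover --config cfg.yaml --mode both
mirnovel validate-array --calls out/calls_specific.tsv \
    --intensities bench/intensities.tsv --groups aCTL1=control,...,aAA3=treated
```

On the packaged reference data, folding the rno-mir-1839 precursor and
locating its two published arms reproduces the canonical Dicer geometry:

```python
>>> from mirnovel.fold import fold
>>> from mirnovel.dicer import duplex_overhangs
>>> import mirnovel.fixtures as fx
>>> pre = fx.all_precursors()["rno-mir-1839"]
>>> arms = fx.homologous_matures().set_index("name")["sequence"]
>>> m, s = arms["rno-miR-1839-5p"], arms["rno-miR-1839-3p"]
>>> duplex_overhangs(fold(pre, "thermo"),
...                  (pre.find(m), pre.find(m) + len(m)),
...                  (pre.find(s), pre.find(s) + len(s)))[0]
(2, 2)
```

— a 2-nt 3′ overhang at both duplex ends.

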