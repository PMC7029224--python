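# pelagimine

Mining myophage genomes of SAR11-like hosts from metagenomic contigs.

SAR11 (*Pelagibacterales*) bacteria dominate the ocean's photic zone, yet
their large contractile-tailed phages — pelagimyophages (PMPs) — are barely
represented in culture collections. They can, however, be recovered from
cellular metagenomes directly: screen assembled contigs for the terminase
large subunit (terL) marker, keep the ones that look like the known PMP
baits but not like their closest relatives (the cyanomyophages, CMPs), and
cross-assemble the survivors into metagenome-assembled viral genomes
(MAVGs). `pelagimine` implements that workflow as a reusable, tested
library plus CLI, together with the downstream analytics used to
characterise the recovered genomes: RPKG read-recruitment profiling,
fragment-based ANI, core-protein concatenation prep, consensus annotation,
proteome isoelectric points, and operon cooccurrence networks.

## The method in brief

* **Mining.** Contigs > 5 kb are screened with a terL profile HMM
  (pyhmmer). Candidate markers are placed on a neighbor-joining tree with
  labelled in-group (PMP) and out-group (CMP) reference markers; candidates
  in the smallest clade containing every in-group reference and no
  out-group reference are the seeds. Two reference protein-cluster
  collections are built (greedy centroid clustering), clusters shared
  between them are removed, and a contig is kept iff it matches ≥ 1 bait
  cluster and 0 decoy clusters (E < 1e-5, alignment spanning 70–130% of the
  gene).
* **Cross-assembly.** After removing duplicate/contained sequences, an
  all-versus-all comparison finds overlaps; an overlap qualifies only at
  identity > 99% over > 1,000 nt with < 10 nt of gaps. Bins (connected
  components) are merged by consensus, every junction must be corroborated
  by ≥ 3 contigs, and freshwater/marine contigs are never merged. Final
  genomes must be > 100 kb with GC in the host range (30–35%).
* **Completeness.** A genome is complete if it carries identical terminal
  repeats > 10 nt, or if it shares ≥ 90% of a complete reference's
  widely-shared protein clusters in ≥ 80% syntenic order.
* **Recruitment.** RPKG = reads recruited per kb of genome per Gb of
  metagenome; reads count at > 95% identity over ≥ 50 nt, samples are kept
  when some genome exceeds 5 RPKG, and linear recruitment plots use a
  70% / 50 nt cutoff.
* **Networks.** Operons are maximal same-strand gene runs uninterrupted by
  a same-strand terminator; protein clusters co-occurring in one operon in
  ≥ 2 genomes are linked, edges at ≤ 0.05% of total strength are pruned.

Because real mining needs terabytes of metagenomes, the package ships a
ground-truthed synthetic community generator (`pelagimine.synthetic`):
modular 100–180 kb phage genomes with conserved core modules, one
hypervariable host-recognition cluster (HRC), planted terL markers,
staggered overlapping contig shreds, bait/decoy reference families and
simulated read sets — every pipeline stage is tested against known truth.

## Worked example

```bash
pelagimine simulate --seed 5 --out demo --n-targets 2 --n-decoys 1 \
    --n-background 40 --genome-len 60000 --shred-sub-rate 0
printf 'inputs:\n  community_dir: demo\nconfig:\n  min_mavg_len: 50000\n' > demo.yaml
pelagimine run --config demo.yaml --out demo_run
```

prints the stage funnel and recovers both planted genomes:

```
        stage  n_in  n_out  mean_len_in  mean_len_out
length_filter    67     45       8893.9       11517.8
     classify    45     18      11517.8       14888.9
        dedup    18     14      14888.9       15428.6
     assemble    14      2      15428.6       60000.0
 final_filter     2      2      60000.0       60000.0
           qc     2      2      60000.0       60000.0
2 MAVGs -> demo_run/mavgs.fasta
```

Reading the funnel: 67 contigs enter; 45 exceed the 5 kb screen; the
exclusion classifier keeps the 18 shreds of the two bait-family genomes
(decoy and background contigs drop out); deduplication collapses 4
error-free shreds contained in longer ones; cross-assembly merges the
rest into 2 MAVGs, byte-identical to the planted 60 kb genomes, which
pass the final filters. `demo_run/` also holds the per-contig
decision table, the per-genome feature table with completeness calls, and
a manifest echoing every parameter. The same stages are available as
library functions (`pelagimine.pipeline.run_pipeline`) and as
single-stage commands (`pelagimine qc|ani|pi|recruit`).

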