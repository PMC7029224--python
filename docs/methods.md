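# Methods

This note documents the models, rules and numerical choices behind
`pelagimine`, and what the synthetic-data tests do and do not establish
about real metagenomes.

## The mining model

The pipeline assumes the target phage group (pelagimyophage-like
myophages of SAR11 hosts) satisfies three premises: (i) its members carry
a detectable terminase large subunit (terL), the near-universal phage
marker; (ii) a set of reference genomes of the group ("baits") exists;
and (iii) the group's closest confounder — cyanomyophages in the marine
setting — is also available as a reference set ("decoys"). Candidate
discovery is marker-driven; candidate *retention* is driven by an
exclusion classifier over protein-cluster collections built from baits
and decoys.

Three implementation decisions deserve explanation:

* **Clade selection is a seed/validation step; the exclusion classifier
  decides membership.** Only a minority of a genome's contigs carry the
  terL gene, so a pipeline that forwarded marker-positive contigs alone
  could never reassemble a complete 140 kb genome from 20 kb contigs.
  The classifier is therefore applied to every contig passing the length
  screen, and each emitted genome must additionally contain a
  clade-selected marker contig. This preserves both halves of the logic
  — the marker tree anchors what counts as "the group", the
  bait-but-not-decoy rule decides each contig — while making whole-genome
  recovery possible.
* **Shared-cluster removal is what keeps the marker usable.** terL is
  homologous between the bait and decoy families; without removing
  clusters shared between the two collections, the decoy terL cluster
  would veto every marker-carrying bait contig. Clusters are shared when
  their representatives align globally at >= 50% identity over a >= 0.7
  length ratio (the threshold is configuration, defaulted, since no
  canonical value exists for "shared").
* **Match engine.** Cluster matching uses phmmer (pyhmmer) with cluster
  representatives as the profile side — one profile per representative,
  searched against all gene proteins at once, which is several-fold
  cheaper than profiling each gene and produces the same (score,
  E-value) contract. A match requires E < 1e-5 and an alignment spanning
  70–130% of the gene protein. The backend is pluggable: everything
  downstream consumes only (gene, cluster, E-value) triples.

Clade selection builds a neighbor-joining tree (scikit-bio) on pairwise
global-alignment distances (1 − identical-column fraction, via edlib)
and searches all bipartitions for the smallest side containing every
in-group reference and no out-group reference. If the in-group is not
separable, the smallest side containing the in-group is used and the
intrusions are reported rather than silently accepted.

## Cross-assembly

Overlap detection seeds exact 21-mers between contig pairs (both
orientations), takes the best seed diagonal, and end-to-end aligns the
implied overlap with edlib. Identity is matches / alignment columns —
gap columns count as mismatches and are also tallied separately for the
gap rule. An overlap qualifies at identity > 99%, length > 1,000 nt and
gaps < 10 nt, all strict.

Merging places contigs by breadth-first traversal of qualifying edges
from the longest contig; repeat-induced inconsistent placements drop the
weakest conflicting edge once and are otherwise flagged. "Corroborated
by more than two contigs" is enforced per junction: walking placed
contigs left to right, the junction region between the incoming contig
and the coverage so far must be intersected by >= `min_support`
(default 3) distinct contigs, i.e. the overlapping pair plus at least
one independent witness; otherwise the layout splits there. Consensus is
per-column majority with ties resolved by the longest spanning contig's
base. Habitat coherence excludes contigs that disagree with the bin's
majority habitat (freshwater vs marine); the cellular/virome fraction is
deliberately *not* a coherence criterion. Final filters: length strictly
> 100 kb, GC inclusively within 30–35% (the host's range), at least one
host-protein match above 70% identity and, when tRNAs are present, a
tRNA match above 95% identity; absent hit tables downgrade those two
criteria to "not evaluated" with a warning.

## Completeness and genome features

Terminal repeats: the longest exact match between the first and last
500 nt (windows configurable; they shrink for short sequences), found by
seed-and-extend on 11-mers; values below 11 nt (the strict "> 10 nt"
rule) report 0. Alignment completeness: the query must contain >= 90% of
the reference's *widely shared* clusters — clusters of the reference
that occur in at least one other genome in the cluster map, so that the
reference's private hypervariable clusters do not penalise a complete
query — and the longest common subsequence of their genome order must
cover >= 80% of them; evidence is the smaller of the two fractions.

Mean intergenic spacer averages max(0, next.start − prev.end) over
consecutive gene pairs sorted by start; overlapping genes contribute 0
and the genome ends are excluded. Host-protein match counts take each
query's best hit and require >= 70% identity with an alignment spanning
70–130% of the *smaller* protein.

## Recruitment

RPKG = reads / (genome kb) / (metagenome Gb), where metagenome size is
the total bases of the read set before any filtering. Each read counts
once, for its best hit (bitscore, then identity, then subject id).
Counting requires identity strictly > 95% over >= 50 nt; sample
retention requires some genome strictly > 5 RPKG; linear-recruitment
points (subject-interval midpoint, identity) use an inclusive 70%
cutoff over >= 50 nt. The >= 50 nt floor is applied to both the 95%
screen and the linear rule. Hits normally arrive as BLAST outfmt-6
tables; a built-in seeded mapper (13-mer seeds, infix alignment, both
strands) provides a self-contained fallback.

## Comparative analytics

ANI follows the fragment protocol: consecutive 1,020 nt query windows
(trailing partial dropped), each placed on the subject by the built-in
aligner with a >= 5-seed chain requirement that mimics BLAST locality —
unrelated sequences essentially never produce a hit, so coverage of
random pairs is 0 rather than an artifact of edit-distance alignment.
Fragments pass at >= 30% identity over >= 70% of their length; ANI is
the mean passing identity and coverage the passing fraction of the
query. A test cross-checks the whole protocol against BLASTN on the
same fragments.

Isoelectric points solve net charge = 0 by bisection under the
Henderson–Hasselbalch model with the EMBOSS pKa table (N-terminus 8.6,
C-terminus 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1);
the termini guarantee a valid bracket on [0, 14]. Accuracy is verified
against a 0.001-pH grid search. Proteome pI distributions are 0.2-pH
histograms normalised to integrate to 1.

Consensus annotation accepts, per database, each protein's best hit with
E < 1e-5 spanning 70–130% of the query, and labels a cluster by strict
majority over databases and members; ties re-vote with second and third
hits, and unresolved clusters are "hypothetical".

## Operons and networks

A new operon starts at a strand change or at a terminator on the
current strand strictly between consecutive genes; terminators on the
opposite strand do not split (rho-independent terminators are
strand-specific; a bidirectional option exists). Two protein clusters
are linked when they share an operon in >= 2 genomes. Edge strength
defaults to the number of such genomes; a genome-pairs mode (C(n,2)) is
provided because the two conventions disagree in the field's usage, and
the choice is surfaced in the graph's attributes. Pruning removes edges
at <= 0.05% of total strength (inclusive by default, strict optional);
since pruning lowers the total, surviving fractions only grow, which
makes pruning idempotent. Components are plain connected components —
no MCL-style inflation is attempted.

## The synthetic community

The generator emulates the statistical structure the pipeline relies on,
not sequencing physics:

* Genomes are 100–180 kb (default 140 kb) at GC 0.33 ± 0.01, tiled by
  four modules — structural core (32%), HRC (24%), replication core
  (28%), hypervariable island (16%). Module classes carry distinct
  dinucleotide textures (homopolymer-leaning core, alternation-leaning
  HRC) with the marginal GC held exactly at target, so conserved and
  hypervariable regions are statistically distinguishable.
* Genes are an annotation overlay on the backbone (proteins are its
  translation, internal stops rendered as X), except planted genes — the
  terL marker and any imported genes — whose reverse-translated coding
  sequence is written into the backbone.
* Families descend from a common ancestor by substitution-only mutation:
  core modules at a low rate, HRC/island at a high rate (or full
  replacement). Substitutions use a group-balanced model (a G/C site
  leaves its group with probability 1 − GC) so heavy mutation does not
  drag the composition toward 50% GC. References are drawn *more*
  diverged from the ancestor (core 0.04) than targets (core 0.02) so
  target markers fall inside the reference radiation on the marker tree,
  as baits chosen to bracket a group's diversity would.
* The decoy family shares the marker at 0.30 amino-acid divergence and
  five near-identical imported core genes, so shared-cluster removal has
  real work; the rest of its gene content is independent.
* Targets and decoys are shredded into two staggered tilings (4 + 5
  contigs, 2 kb overlaps, substitution rate 0.002), giving every
  junction a third witness; 200 random background contigs (1–8 kb) have
  no genes. Reads are drawn multinomially with probability proportional
  to weight × genome length.

What passing tests show: the decision rules, the assembly geometry, the
normalisations and the network algebra are implemented correctly and
recover planted truth under realistic divergence structure. What they do
not show: robustness to indels and misassemblies, chimeric contigs,
strain microdiversity within one population, sequencing error profiles,
or amplification bias — none of which the generator models (indels are
available as an option but default off so the identity and gap
dimensions of the overlap rule stay independently testable).

## Problem sizes and numerics

Tests and the acceptance script run the full pipeline on 3 target +
3 decoy 140 kb genomes with 200 background contigs (~40 s), recruitment
on 10⁵ reads × 20 seeds, a 20-genome family for the network brute-force
check, and 100 random peptides for the pI oracle. Bisection tolerance
for pI is |charge| < 1e-4 within a 0.01-pH guarantee; overlap placement
tolerates 50 nt of offset disagreement before declaring a conflict;
k-mer sizes are 21 (contig overlaps), 13 (read/fragment mapping) and 11
(terminal repeats), each chosen so chance matches are negligible at the
relevant scales.
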