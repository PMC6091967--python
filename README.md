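# coidiet

A COI-minibarcode metabarcoding pipeline for diet analysis from fecal
samples, built for studies of insectivores whose prey is covered by a
curated reference phylogeny (the motivating case is a small semi-aquatic
mammal feeding on freshwater macroinvertebrates).

Fecal DNA is messy: target prey sequences are mixed with decomposers,
environmental DNA and PCR chimeras, and BLAST-only identification
struggles with rate heterogeneity across the wide taxonomic range of
metazoan prey. `coidiet` implements the tree-based alternative end to
end:

1. **Preprocessing** — primer trimming, a 124-bp minimum-length filter,
   greedy abundance-sorted clustering at ≤ 3 mismatches, removal of
   clusters with ≤ 10 reads, and pooled de novo bimera detection across
   samples.
2. **Phylogenetic placement** — each cluster representative is aligned
   into the fixed columns of a reference alignment and attached to every
   edge of the reference tree by maximum likelihood (evolutionary
   placement, EPA-style), producing standard jplace documents with
   per-edge log-likelihood L(e), like-weight ratio
   LWR(e) = exp(L(e) − L_max) / Σ_e' exp(L(e') − L_max), optimized
   pendant branch length and distal attachment position.
3. **Identification** — a query is accepted as a prey OTU iff the best
   placement's pendant length is *shorter than* a threshold taken as the
   99.9% quantile of the reference tree's terminal branch-length
   distribution; longer pendants mark non-target sequences. Accepted
   queries are labelled with the species of the closest leaf (patristic
   distance from the attachment point). A 0–18 ID score quantifies
   concordance with two external database identifications
   (6 = same species, 5 = same genus, 3 = same order, 1 = same phylum,
   summed over the three pairwise comparisons).
4. **Quantification** — cluster read counts act as an abundance
   surrogate: OTU×sample tables, % target reads, OTU richness, Shannon
   H′ = −Σ pᵢ ln pᵢ, Jaccard J = |A∩B|/|A∪B| between OTU presence sets,
   per-group (fresh vs. old sample) comparisons with Mann–Whitney tests,
   and order-level composition tables (Chironomidae split out of
   Diptera).
5. **Simulation** — a first-class generator of synthetic references
   (Yule trees, JC69-evolved minibarcodes, clade-derived taxonomy) and
   fecal read sets with planted targets, outgroup contaminants and
   chimeras, carrying full ground truth for validation.

## Worked example

```python
import numpy as np
from coidiet.config import PipelineConfig
from coidiet.pipeline import run_pipeline
from coidiet.simulate import simulate_reference_db, simulate_sample

refdb, ref_truth = simulate_reference_db(n_species=50, seq_len=130, seed=1)
rng = np.random.default_rng(42)
prey = rng.choice(list(refdb.alignment), size=5, replace=False)
mixture = dict(zip(prey, rng.dirichlet(np.ones(5) * 3)))
reads, truth = simulate_sample(
    refdb, mixture, n_reads=1000, error_rate=0.005,
    contam_frac=0.10, chimera_frac=0.05, seed=42,
    sample_id="fecal1", ref_truth=ref_truth,
)
result = run_pipeline({"fecal1": reads}, refdb, PipelineConfig())

print(f"pendant-length threshold: {result.threshold_value:.3f} subst/site")
for r in result.identifications:
    print(f"{r.query_id}  reads={r.n_reads:<4} status={r.status:<12} "
          f"otu={r.otu_label or '-':<20} pendant={r.pendant_length:.3f}")
s = result.summaries[0]
print(f"\nsample {s.sample_id}: {s.reads_total} reads, "
      f"{s.pct_target:.1f}% target, {s.otu_richness} OTUs, H'={s.shannon:.2f}")
```

prints:

```
pendant-length threshold: 0.199 subst/site
fecal1_c0  reads=299  status=identified   otu=Genus016 species3    pendant=0.008
fecal1_c1  reads=246  status=identified   otu=Genus017 species3    pendant=0.000
fecal1_c2  reads=125  status=identified   otu=Genus012 species1    pendant=0.021
fecal1_c3  reads=110  status=identified   otu=Genus003 species3    pendant=0.000
fecal1_c5  reads=65   status=identified   otu=Genus007 species3    pendant=0.006
fecal1_c6  reads=50   status=outlier      otu=-                    pendant=0.488
fecal1_c4  reads=49   status=outlier      otu=-                    pendant=0.316

sample fecal1: 1000 reads, 84.5% target, 5 OTUs, H'=1.47
```

All five prey species in the mixture are recovered as identified OTUs
with short pendant branches; the two clusters built from outgroup
contaminant reads attach with pendants of 0.3–0.5 substitutions/site,
well past the 0.199 threshold, and are discarded as non-target. Two
planted chimera clusters were already flagged during preprocessing and
never reach placement. The per-sample summary row (total reads, %
target, OTU richness, H′) is the schema used for the study's sample
table.

The same flow is available from the shell:

```bash
coidiet simulate refdb --n-species 50 --seed 1 --out ref/
coidiet simulate sample --refdb ref/ --n-reads 1000 --seed 42 --out sim/
coidiet preprocess --fastq-dir sim/ --out clusters.fasta --report stages.tsv
coidiet place --refdb ref/ --queries clusters.fasta --out placements.jplace
coidiet identify --jplace placements.jplace --refdb ref/ --out ids.tsv
coidiet quantify --identifications ids.tsv --sample-meta samples.tsv --out-dir results/
```

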