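# conftop

Detecting intermediate protein conformations with persistent homology.

Proteins that switch between two stable states — an open and a closed form,
say — pass through transient intermediate conformations that are hard to
observe experimentally. `conftop` finds candidate intermediates
computationally: it samples a pathway of coarse-grained conformations
between two endpoint structures, projects the pathway to a few reaction
coordinates, and then clusters the reduced conformational cloud using the
0-dimensional persistent homology of a lazy witness filtration. Densely
populated, well-separated regions of the cloud — the clusters — are the
candidate intermediate states, and the barcode yields a full nested
hierarchy of them rather than a single flat partition.

The package is aimed at structural bioinformaticians who want a
reproducible, parameter-light alternative to K-means-style clustering of
conformational ensembles.

## Method

1. **Conformational search.** Each protein is reduced to its Cα trace.
   Starting from endpoint *A*, a Monte-Carlo search grows a pool of
   conformations toward endpoint *B*: a parent is drawn from the pool, a
   virtual Cα–Cα bond is selected with probability proportional to
   |Δφᵢ| (the pseudo-dihedral difference to the goal, similar angles
   skipped), rotated by a uniform angle in (−5°, +5°), filtered by a
   Cα energy threshold, and accepted when either

   RMSD_new < RMSD_parent    or    ln r < −(RMSD_new − RMSD_parent)/(a·RMSD_new),

   with r ~ U(0,1) and scaling factor *a*. RMSDs are Kabsch-superposed Cα
   RMSDs to the goal.

2. **Dimensionality reduction.** The M×3N matrix of conformation vectors is
   reduced by either *spherical PCA* (each data vector rescaled to unit
   norm, then standard PCA — robust to outliers) or *Isomap* (K-nearest
   neighbour graph with the minimal K giving one connected component,
   exact Dijkstra geodesics, classical MDS). The first three coordinates
   are used.

3. **Topological clustering.** A maxmin landmark subset Z₀ of the reduced
   cloud Z is chosen; the landmark count comes from the stabilization of
   the coverage radius R (growth in steps of 10 until the relative drop in
   R is below 5%, averaged over 5 runs, +2 sd). The H₀ barcode of the lazy
   witness filtration LW⁰(Z, Z₀, t) is computed by union-find; the number
   of clusters is the finest filtration level preceded by a bar gap larger
   than 0.1. Connected components at the per-level plateau scales give
   nested partitions; blocks smaller than 2 landmarks are discarded as
   outliers; the surviving partitions assemble into a laminar dendrogram.

4. **Reporting.** Each cluster is summarized by its size, the mean ± sd of
   member Cα RMSDs to both endpoints, and a representative structure (the
   member nearest the cluster centre in the reduced space). Clusters are
   numbered by increasing RMSD to the designated endpoint; a clustering
   that spans the transition shows monotone RMSD columns in both
   directions.

H₁ persistence (cycle detection) is implemented at oracle scale via exact
GF(2) boundary-matrix reduction on flag complexes and is used to validate
the filtration machinery against analytically known fixtures.

## Worked example

The library ships a toy generator so the whole pipeline runs without any
input files: a self-avoiding 10-residue Cα chain is perturbed by random
dihedral rotations into a distinct goal conformation, and the pipeline is
run between the two.

```python
from conftop.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(max_iterations=3000, toy_n_res=10, seed=1006,
                     out_dir="results/example")
res = run_pipeline(cfg)
print(len(res.trajectory), res.n_clusters)
print(res.report.table.round(3).to_string(index=False))
```

which prints

```
2981 2
 cluster  size  mean_rmsd_a  sd_rmsd_a  mean_rmsd_b  sd_rmsd_b  representative
       1   126        0.186      0.081        1.663      0.122             577
       2     2        0.245      0.129        1.676      0.084            2021
```

Reading this: 3,000 search iterations produced a pool of 2,981
conformations (start RMSD to goal 1.72 Å, best sampled 1.40 Å); Isomap
reduced them to three coordinates, 128 maxmin landmarks survived outlier
pruning, and the barcode gap rule found two clusters. Columns
`mean_rmsd_a/b` are the mean Cα RMSD (Å) of cluster members to the start
and goal structures — on a real transition these columns grade monotonically
between the endpoints. `representative` is the pool index of each
cluster's medoid; the pipeline writes it out as a Cα PDB file.

The same run is available from the shell:

```bash
conftop run --iters 3000 --seed 1006 --out-dir results/example
```

and the individual stages as `conftop synth | sample | embed | cluster |
report`.

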