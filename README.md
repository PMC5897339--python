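# netexpr

Linking spatial gene expression to cortico-striatal functional networks.

Functional MRI organizes the brain into distributed networks — limbic,
somato/motor, default, and so on — that span anatomically distinct
territories such as cerebral cortex and striatum. `netexpr` implements the
analysis chain that asks whether those networks carry dissociable *genetic*
signatures: it maps post-mortem tissue samples (with MNI coordinates) onto
volumetric network parcellations, finds genes expressed more in one network
than all others, builds region-to-region gene co-expression matrices, and
quantifies how well genetic and functional connectivity structure agree —
within a dataset, across independent datasets, and across species. It is
aimed at researchers working with brain transcriptional atlases (e.g. the
Allen Human Brain Atlas and similar multi-donor resources) alongside
functional-connectivity parcellations.

## The statistics at its core

- **Expanding-ROI assignment.** A sample at MNI coordinate **x** is tested
  against cubes of side 1, 2, 3 voxels in order; the network with the most
  overlapping labeled voxels in the first non-empty cube wins, otherwise the
  sample is omitted.
- **Moderated one-vs-rest differential expression.** Expression is averaged
  samples → parcels → networks per donor; per gene, a linear model of the
  donor × network means on a target-network indicator gives the log2 fold
  change Δg. Residual variances are shrunk toward an empirical-Bayes prior,
  s̃g² = (d₀s₀² + d·sg²)/(d₀ + d), and tg = Δg/(s̃g·√v) has d₀ + d degrees of
  freedom. Repeated measures from the same donor are handled by a pooled
  intra-donor correlation used as a compound-symmetric block correlation in
  GLS (or by donor fixed effects). Network-biased genes satisfy
  BH-adjusted q ≤ 0.01 and Δg > 0.
- **Fisher-averaged co-expression.** Per donor, regions are
  Spearman-correlated across a gene subset; donor matrices are averaged via
  z = atanh(r). Correspondence between a genetic and a functional matrix is
  Pearson r over their vectorized unique region pairs.
- **Replication.** Gene-set overlaps use the exact upper-tail hypergeometric
  probability P(X ≥ k) in an explicit gene universe; fold-change concordance
  is Pearson r over shared genes.
- **Enrichment.** Cell-type calls use the top-vs-second expression ratio
  (log2 FC > 1.5); annotation enrichment is hypergeometric with BH
  correction; laminar contrasts (layers 2/3 vs 5/6) reuse the moderated
  machinery.

A fully synthetic study generator (`netexpr.synthetic_data`) plants known
network-biased genes, donor random effects, compartment shifts, redundant
probes, and block-structured functional connectivity, so every stage can be
validated against ground truth without any downloads.

## Worked example

```python
import netexpr as nx

cfg = nx.SimulationConfig(seed=7)                  # 2000 genes, 6 donors
matrix, manifest, truth = nx.make_expression(cfg)  # log2 expression + manifest

atlas, _ = nx.make_atlas(cfg, "cortex")
assigned = nx.assignment_table(atlas, manifest[manifest.compartment == "cortex"])
print("assigned:", dict(assigned.network_counts))

norm = nx.mean_normalize(matrix, manifest)          # center per compartment
nexpr = nx.aggregate_to_networks(norm, assigned.table, manifest)
de = nx.fit_network_ovr(nexpr, "limbic")            # moderated one-vs-rest
limbic = nx.positive_de_set(de, q_max=0.01)
print(f"limbic-biased genes: {len(limbic)}")

report = nx.truth_report(truth, {"limbic": limbic}, "cortex",
                         universe=set(cfg.genes))
print(report.to_string(index=False))

res = nx.overlap_test(limbic, truth.planted_for("cortex", "limbic"),
                      set(cfg.genes))
print(f"overlap k={res.k} (expected {res.expected:.1f} by chance), "
      f"p={res.p_hyper:.3g}")
```

Output:

```
assigned: {'control': 36, 'default': 36, 'dorsal_attention': 36, 'limbic': 36,
           'somato_motor': 36, 'ventral_attention': 36, 'visual': 36}
limbic-biased genes: 200
network  n_called  n_planted  sensitivity  specificity  fdr
 limbic       200        200          1.0          1.0  0.0
overlap k=200 (expected 20.0 by chance), p=1.46e-281
```

Every cortical sample lands in its network (36 per network = 6 donors × 3
parcels × 2 samples). The one-vs-rest fit recovers exactly the 200 planted
limbic genes (10% of 2000) with no false positives, and the hypergeometric
test confirms the called set overlaps the planted set far beyond chance —
200 shared genes where 20 would be expected.

A command-line interface mirrors the library
(`netexpr simulate | assign | normalize | de | coexpr | correspond |
overlap | concordance | enrich`); see `netexpr --help`.

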