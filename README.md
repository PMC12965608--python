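# dualnet

Dual-network inference of hierarchies among modifiable risk variables from a
single cross-sectional cohort table:

1. **RPCN** — a regularized partial correlation network: EBIC-selected
   graphical lasso (γ = 0.5 by default) on a rank-latent correlation matrix,
   with node centrality (strength, expected influence, closeness,
   betweenness), per-node predictability (R²), non-parametric edge
   bootstraps, and case-dropping centrality-stability CS-coefficients.
2. **Consensus DAG** — a bootstrap consensus ensemble: four Bayesian network
   structure learners (hill climbing, tabu search, MMHC, H2PC) × four data
   transformations (3- and 5-level mutual-information discretization,
   nonparanormal shrinkage, inverse normal transformation) × B bootstrap
   resamples per cell. Each of the 16 cells is thresholded (arc strength
   ≥ 85%, strict direction majority > B/2) into a directed subnetwork; the
   final graph keeps only arcs retained under **all** algorithms in at least
   three of the four transformations (≥ 12 of 16 subnetworks), annotated
   with learned/grand strength and direction statistics
   (grand = learned × k/16).

A synthetic-cohort module (`dualnet.synthetic`) generates 20-variable
cohort-like datasets from planted linear-Gaussian structural models —
bounded integer scale scores, ordinal demographics, skewed activity
measures, blacklisted (sink-forbidden) variables — so the whole pipeline is
testable end to end, with recovery scoring (skeleton precision/recall/F1,
SHD, orientation accuracy) against the planted DAG.

## CLI

```bash
# generate a synthetic cohort with its ground-truth DAG
dualnet simulate --preset cohort20 --n 1000 --seed 1 --out cohort.csv --truth truth.json

# individual stages
dualnet transform --kind all --schema schema.yaml --in cohort.csv --out views/
dualnet rpcn --in cohort.csv --schema schema.yaml --gamma 0.5 --out rpcn/
dualnet learn --algo hc --in cohort.csv --schema schema.yaml --view disc5 --out dag.json

# end-to-end: exclusions -> transforms -> RPCN -> ensemble -> consensus -> overlap
dualnet run --in cohort.csv --schema schema.yaml --B 10000 --seed 1 --out results/
```

The schema YAML declares one entry per variable (`role`,
`admissible_range`, `ordinal_levels`, `discretization_exempt`,
`blacklist_sink_forbidden`) plus optional value screens; see
`dualnet.schema.load_schema` for the format. Every run writes a
`manifest.json` recording all thresholds, seeds and grid choices;
`dualnet.reporting.run_from_manifest` reproduces a run byte-identically.

## Layout

| module | contents |
| --- | --- |
| `dualnet.schema` | variable schema, CSV loading, value screens, complete-case filtering, exclusion logs |
| `dualnet.transforms` | disc3/disc5/npn/int dataset views |
| `dualnet.rpcn` | correlation, EBIC glasso, centrality, predictability, edge/case-drop bootstraps |
| `dualnet.structure` | BIC scores, HC/TABU search, MMPC/HPC skeletons, hybrid learners, blacklists |
| `dualnet.ensemble` | per-cell bootstrap arc strengths, ad-hoc thresholding, cross-grid consensus, overlap report |
| `dualnet.synthetic` | planted SEMs, the 20-variable cohort preset, recovery scoring |
| `dualnet.reporting` / `dualnet.cli` | orchestration, manifests, GraphML/DOT/CSV/JSON export, `dualnet` CLI |
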