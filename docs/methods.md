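# Methods

## The pipeline model

`hubnet` analyzes condition-specific protein sets through a fixed
sequence of graph operations on a shared interactome. All graphs are
simple, undirected and unweighted: interaction-type annotations are
discarded after parsing because every downstream statistic is purely
topological. Gene identifiers are normalized to uppercase,
whitespace-stripped tokens; no alias or ortholog resolution is
attempted (deterministic and reversible beats guessed mappings, and
unmapped seeds are reported rather than silently dropped). miRNA
identifiers are kept verbatim, since miRBase-style names are
conventionally lowercase.

**First-order extraction.** A condition's network is the induced
subgraph on (seeds ∩ interactome) ∪ neighbors(seeds). This is the
standard "first-order interaction network": on a dense interactome it
expands a hundred seeds into a network of thousands of nodes, which
is the regime the global statistics are designed for. Seeds absent
from the interactome are listed in `seeds_missing`; seeds present but
partnerless are kept only on request (`keep_isolated_seeds`), because
isolated nodes distort path-length statistics.

**Topology panel.** Conventions follow Cytoscape's NetworkAnalyzer,
the tool of record for this kind of descriptive PPI statistics:
centralization `(N/(N−2))·(k_max/(N−1) − density)` (undefined below
N = 3 and reported as null, not a number); heterogeneity as the
coefficient of variation of degree using the *population* variance
(so the 1-center/3-leaf star gives exactly √0.75/1.5); mean local
clustering with degree < 2 nodes contributing 0; characteristic path
length averaged over connected pairs only, with the connected-pair
fraction reported alongside and an optional flag to restrict every
statistic to the largest component first (whether real studies did so
before quoting path lengths is usually unstated, so it is exposed
rather than hard-wired). The degree-distribution fit is least squares
on log n(k) vs log k for k ≥ 1 — the NetworkAnalyzer-style fit, not a
maximum-likelihood tail fit — and requires at least three distinct
positive degrees.

**Centralities.** Betweenness (normalized by (N−1)(N−2)/2) and
characteristic path length are delegated to igraph's C
implementations; closeness (per-component, (reachable)/(Σ distances))
and stress are computed by a hand-written BFS over each source's
shortest-path DAG: the number of s–t geodesics through v equals
σ(s,v) times the number of geodesic suffixes from v, accumulated in
reverse BFS order and halved because each unordered pair is seen from
both endpoints. Stress is kept as an exact integer. The test suite
checks all three against an independent brute-force enumerator that
materializes every shortest path.

**Hub selection.** No single published rule defines "HUB node", so
three auditable strategies are shipped and the chosen one travels
with every output: (1) *degree_betweenness_borda* (default) — sum of
the competition ranks in degree and betweenness, lowest score wins;
(2) *degree_topk*; (3) *sd_threshold* — degree > mean + k·sd, which
may legitimately select nothing on near-regular graphs (logged, not
an error). All ties break by higher betweenness, then lexicographic
symbol, making rankings total and deterministic. The Borda rule is
invariant to positive rescaling of betweenness.

**Hub subnetwork.** Three readings of "the network connecting the
hubs": induced subgraph on hubs; hubs plus first neighbors; and the
default *geodesic_union* — every node and edge on any shortest path
between any hub pair, with all tied geodesics kept (no sampling, so
the result is order-independent and deterministic). Disconnected hub
pairs contribute nothing and are logged.

**Merge and linking region.** The merged network is the node- and
edge-wise union of the condition subnetworks; each node's provenance
is the set of conditions containing it. The partition rule is
membership: provenance ≥ 2 ⇒ *linking*, else *specific:&lt;condition&gt;*.
This is the only rule under which the four class sizes necessarily
sum to the union size. An alternative *bridge* rule (specific nodes
whose merged-graph neighbors span ≥ 2 conditions are promoted to
linking) is available behind a flag. The linking sub-network is the
induced subgraph on linking nodes — edges from specific to linking
nodes stay in the merged graph but not here, for consistency with
every other induced-subgraph stage — and is then re-analyzed with the
same topology/hub machinery.

**miRNA overlay.** Strictly bipartite: edges (m, g) with g in the
node set of interest and g ∈ targets(m); miRNAs with no retained
target are omitted, so no isolated miRNA nodes exist. The hub
targeting summary classifies each miRNA by how many hubs it targets;
the identity total = multi-hub + Σ single-hub is asserted on every
call. A reference miRNA→hub map for the seven linking hubs of the
bladder/kidney/prostate arsenical networks is packaged as a TSV (84
miRNA–hub pairs, 73 distinct miRNAs) and doubles as a self-contained
acceptance fixture. No tissue filtering is applied to target
evidence.

## Synthetic data: what it emulates, what it does not

The generator stands in for interactome/seed/miRNA database
snapshots, which cannot be redistributed and whose exact contents
drift between versions.

* **Interactome** — Barabási–Albert preferential attachment (star
  seed graph), because the one robust distributional claim about real
  interactomes here is scale-freeness. Exponent is whatever the
  mechanism yields (≈ −1.8 at n = 2000, m = 2, log-log r² > 0.8); it
  is not tuned to any published value. `n_nodes = 2000`,
  `attachment_m = 2` are the default study conditions — big enough
  for a clean heavy tail, small enough for exact centralities in
  seconds.
* **Planted hubs** — `plant_hubs` boosts randomly chosen nodes to
  `boost_factor ×` the maximum pre-planting degree (capped at n−1),
  default boost 5. The boost is deliberately relative to the natural
  *maximum*, not the median: a planted hub must dominate the natural
  hubs for "recovery of planted hubs" to be a meaningful test, just
  as disease hubs dominate first-order disease networks. A
  consequence worth knowing: boosted hubs are near-universal nodes,
  so conditions that share all planted hubs produce nearly identical
  hub subnetworks. Recovery studies therefore use planting; partition
  demonstrations use the natural-hub regime (`n_planted_hubs = 0`) or
  share only a fraction of planted hubs across conditions
  (`shared_hub_fraction`, default 0.5, remainder dealt round-robin).
* **Seed sets** — every condition receives a common core of
  `round(overlap_fraction × seeds_per_condition)` genes (default
  overlap 0.2, 100 seeds/condition — between the two real list sizes
  the pipeline is modeled on, at the scaled-down interactome), drawn
  degree-proportionally when `hub_bias` is set; remaining seeds are
  drawn disjointly, so every pairwise seed intersection equals the
  core exactly. This makes the "planted linking ancestry" a
  set-arithmetic ground truth.
* **miRNA targets** — per-miRNA target counts are Poisson truncated
  at ≥ 1 (mean 5); with `hub_enrichment` (default 0.5) that fraction
  of targets is drawn degree-proportionally, producing miRNAs that
  target several hubs, as the reference map shows real miRNAs do.

What the generator does *not* emulate: literature-curation bias,
interaction confidence scores, dose–response structure, tissue
specificity of miRNA targeting, or the particular identities of any
real gene. Passing tests therefore demonstrate correctness of the
*method* under a realistic topology, not agreement with any
database-snapshot-dependent published count (network sizes, partition
counts and hub identities all depend on those snapshots and are out
of scope by design).

## Determinism and numerics

Every stochastic routine takes an explicit seed and threads it
through a single `numpy.random.Generator`; the pipeline derives
per-stage seeds by fixed offsets from the config seed. Outputs are
written in sorted order (edges, nodes, miRNAs, JSON keys), so an
unchanged config reproduces the artifact tree byte for byte — checked
by a test and by the acceptance script. Degenerate inputs have
defined behavior rather than exceptions where a value is meaningful:
empty overlays warn, an sd-threshold that selects no hubs warns,
centralization below N = 3 is null, CPL of an edgeless graph is NaN
(null in JSON). Floating-point comparisons in tests use 1e-9 where
the quantity is a ratio of path counts; stress is compared exactly as
an integer.

## Problem sizes used in the shipped checks

Centrality-oracle agreement uses 50 random graphs with n ≤ 40 (where
exhaustive geodesic enumeration is cheap); planted-hub recovery uses
20 replicates at n = 2000; the linking-partition check uses a
3-condition instance on an 800-node interactome with a 30-gene core;
the reproducibility check runs the full pipeline twice at n = 400.
These sizes were chosen so each property is exercised in the regime
where it is informative while the whole suite runs in well under a
minute of compute per check.

## Known limitations

* Identifier normalization is purely lexical; real CTD/INTACT symbol
  mismatches need an external mapping step before input.
* `sd_threshold` uses the population sd of degree; on heavy-tailed
  networks the threshold is dominated by the hubs themselves.
* The geodesic-union subnetwork can be large on small-world graphs
  with many tied shortest paths; the induced and neighbors strategies
  bracket it from below and above.
* Stress centrality is O(V·E) in pure Python; fine to ~10⁴ nodes,
  and excludable via the `measures` argument when only degree and
  betweenness are needed.
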