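# wellnet

Ensembles of microbial co-occurrence networks from dilution-series 96-well
cultivation arrays — with everything needed to go from well-level Zotu count
tables to experimentally testable taxon pairs.

Co-occurrence networks predict microbial interactions but rarely get tested
at the bench. One route to testable predictions: serially dilute an
environmental sample to extinction across 96-well plates so each well holds a
small random sub-community, sequence every well, infer one co-occurrence
network per plate, and keep only the taxon pairs that recur across many
independent plate networks. Those *prevalent pairs* are few enough to match
against cultured isolates and co-culture directly. `wellnet` implements that
whole chain for anyone designing or analysing such a cultivation array —
plus a synthetic plate-array generator with planted, known interactions, so
the statistical machinery can be validated end to end without sequencing
data.

## The statistics at the core

Per plate (wells *w*, Zotus *i*):

- wells grow iff total reads ≥ a threshold; a plate is *effective* iff
  \>30% of its wells grew;
- Zotus occurring in <30% of growing wells are filtered;
- for every remaining pair, tie-corrected Spearman ρ on per-well relative
  abundances, with two-sided p from t = ρ√((n−2)/(1−ρ²)), n−2 df;
- Benjamini–Hochberg FDR within the plate; an edge requires |ρ| > 0.6 and
  q < 0.01 (strict);
- the analysis restricts to nodes with degree centrality < 5 (single pass).

Across the ensemble, for each pair within a (sample type, medium) group of
Ng networks, the frequency of occurrence is

    FO = Np / Ng

where Np counts the group's networks containing the pair as an edge. Pairs
with FO > 30% are the robust prevalent pairs; a top-k report per group and
Jaccard similarities between edge sets summarize the ensemble.

Downstream, cultured isolates are matched to network Zotus by V4 amplicon
extraction (515F/806R, IUPAC-aware, mismatch budget), global-alignment
identity, and nearest-leaf distance on a Saitou–Nei neighbor-joining tree;
isolate pairs representing a Zotu pair are enumerated for co-culture. A
co-culture's interaction is classified from the divergence of log-scale
growth-curve AUC between co- and mono-culture into the classical taxonomy
(mutualism, commensalism, exploitation, amensalism, competition,
neutralism), per time window for biphasic interactions; qPCR standard
curves (E = 10^(−1/slope) − 1) convert Cq to cells via rrn copy number.

## Worked example

Simulate a demo array (2 groups × 9 plates × 96 wells × 40 taxa, 3 planted
positive pairs), infer the ensemble, and report:

```
$ wellnet run --seed 1 --out demo/
{
  "n_plates": 18,
  "n_effective": 18,
  "unique_pairs": 6,
  "n_robust_pairs": 8,
  "planted_recall": {
    "roots/R2A": 1.0,
    "roots/TSB": 1.0
  }
}
```

All 18 plates pass the 30%-growth filter; the ensemble contains 6 unique
pairs; 8 (pair, group) records exceed FO > 0.30 — the 3 planted pairs in
both groups plus two low-FO extras — and planted-pair recall is 1.0 in both
groups. The per-group report (`demo/top_pairs.tsv`) mirrors the usual
summary-table layout:

```
sample_type  medium  zotu_a  zotu_b  Np  Ng  FO      consensus_sign  mean_rho
roots        R2A     Zotu1   Zotu37  6   9   0.667   1               0.883
roots        R2A     Zotu13  Zotu23  6   9   0.667   1               0.874
roots        R2A     Zotu11  Zotu3   6   9   0.667   1               0.862
roots        TSB     Zotu13  Zotu23  6   9   0.667   1               0.885
...
```

Each planted pair appears as an edge in Np = 6 of the Ng = 9 group networks
(the six plates at informative dilutions; the most dilute plates contribute
no edges), hence FO = 0.667, with a consensus-positive mean ρ ≈ 0.87. The
run directory also contains every intermediate: plate TSVs with JSON design
sidecars, per-plate edge lists, the full pair-prevalence and robust-pair
tables, synthetic Zotu/isolate FASTA with the isolate–Zotu match table, and
windowed interaction calls for the enumerated co-culture combinations.

Individual stages run standalone (`wellnet simulate / filter / infer /
ensemble / match / assay`), reading and writing the same plain-text formats.

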