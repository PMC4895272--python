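# dicore

Discovery of miRNA–mRNA regulatory modules (MMRMs) from matched expression
profiles, by mining *collective group relationships*: instead of scoring
individual miRNA–target pairs, the pipeline finds cohesive groups of miRNAs
and groups of mRNAs and quantifies the strength of each (miRNA group, mRNA
group) pair as a single canonical correlation. It is aimed at systems
biologists who have matched miRNA and mRNA expression matrices over the same
samples (e.g. differentially expressed features from a cancer cohort) and
want ranked candidate regulatory modules with a quantitative strength.

## Method

Given miRNA expression **X** (p × n) and mRNA expression **Y** (q × n) over n
matched samples:

1. **Interaction weights.** W is the p × q matrix of |PCC(X_i, Y_j)| (or, in
   the repression-only variant, |PCC| where PCC < 0). Entries below a cutoff
   η ∈ [0, 1] are zeroed; survivors keep their weight, interpolating between
   unweighted and fully weighted bipartite-graph mining.
2. **Collaboration scores.** Two miRNAs collaborate through shared targets:

       v_ij = (Σ_k w_ik·w_jk)² / (Σ_k w_ik · Σ_k w_jk)

   giving the p × p matrix S; the q × q mRNA-side matrix T applies the same
   formula to Wᵀ. For binary W this is the squared shared-neighbor count
   over the product of neighborhood sizes.
3. **Greedy overlapping clustering.** Each side is clustered separately by
   neighborhood expansion maximizing the cohesiveness

       cs(C) = w_int(C) / (w_int(C) + w_ext(C) + α·|C|)

   (internal vs boundary collaboration weight, with a per-member penalty α
   for undetected interactions), in the style of the ClusterONE algorithm
   for protein complexes: seeds in descending total-collaboration order,
   single best add/remove moves until a local maximum, size filters
   (θ_m = 3 miRNAs, θ_g = 5 mRNAs, at most 500 mRNAs), and merging of groups
   with overlap score |A∩B|²/(|A||B|) ≥ ω = 0.8.
4. **CORE scoring.** Every (miRNA group, mRNA group) pair is scored by its
   first canonical correlation r = max_{a,b} corr(a′X_C, b′Y_C); pairs with
   r ≥ ρ = 0.50 are reported as COREs, ranked by r. Because mRNA groups
   routinely exceed the sample count, the default solver is a sparse
   diagonal-penalized CCA (penalized matrix decomposition); exact classical
   and ridge-regularized solvers are also available.

Everything is deterministic: identical inputs and parameters give
byte-identical outputs.

## Worked example

Generate a synthetic matched dataset with two planted anti-correlated
modules (4 miRNAs × 20 mRNAs and 5 miRNAs × 30 mRNAs over 60 samples), run
the pipeline, and validate against the planted truth:

```bash
dicore synth --seed 1 --out data/
dicore run --mirna data/mirna.tsv --mrna data/mrna.tsv \
           --reference data/reference.tsv \
           --eta 0.4 --rho 0.5 --out out/
```

which prints

```
eta=0.40: #C=2 mean_mRNAs=25.00 mean_miRNAs=4.50 mean_r=0.89
artifacts written under out/
```

i.e. exactly two COREs were found, averaging 25 mRNAs and 4.5 miRNAs per
CORE with mean canonical correlation 0.89 — the two planted modules, each
recovered with its full membership. `out/eta_0.40/` contains `groups.json`,
`cores.json`, `cores.tsv` and `confirmed.tsv` (per-miRNA confirmed targets
from the reference list); `out/summary.tsv` concatenates one row per η.
`dicore validate --cores out/eta_0.40/cores.json --reference
data/reference.tsv` reports the confirmed-interaction count per CORE.

The same pipeline is available as a scikit-learn-style estimator:

```python
from dicore import DICORE
from dicore.synthetic import PlantedScenario, generate

pair, truth = generate(PlantedScenario(seed=1))
est = DICORE(eta=0.4, rho=0.5).fit(pair)
est.cores_[0].strength        # 0.902
len(est.cores_)               # 2
```

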