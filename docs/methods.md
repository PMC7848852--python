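# Methods

## The model

`lipidpath` analyses a two-condition quantitative lipidomics experiment at
the level of *reactions* between lipid subclasses rather than individual
species. The premise: groups of structurally related lipids are regulated
together by the same enzyme isoforms, so a coordinated shift in the
product/substrate balance of a known enzymatic step is a more interpretable
signal than any single species change, and it points directly at candidate
genes.

The analysis pipeline is:

1. **Name normalisation.** Input species names in any accepted shorthand
   dialect are collapsed to a *sum composition* — subclass code plus total
   chain carbons and double-bond equivalents (`PC 18:0/20:4(5Z,8Z,11Z,14Z)`
   → `PC(38:4)`). Chain positions, double-bond locations, stereochemistry
   and sn-order are deliberately discarded; reaction matching is defined on
   bulk compositions. Sphingolipid long-chain bases (`d18:1`, `18:1;O2`)
   contribute their stated carbons and double bonds; the `d`/`;O2` hydroxyl
   annotation is carried on the composition but not used in matching.
   Plasmalogen `P-` prefixes are normalised to the `O-` ether subclass with
   one extra double-bond equivalent (the vinyl-ether bond) — a documented
   shorthand convention, since sum-composition bulk rules do not
   distinguish alkyl from alkenyl linkages.

2. **Reaction instantiation.** The shipped database holds 41 lipid
   subclasses and 94 directed mammalian reactions, each annotated with
   human (HGNC) gene symbols. A reaction is instantiated on a dataset when
   species with balancing compositions are present: composition-preserving
   steps (headgroup transfers, sphingoid-backbone steps) need substrate and
   product species with identical C:D; acylation needs product = substrate
   + one measured FA species (and deacylation the mirror image); FA
   elongation/desaturation steps join fixed compositions (+2 C / +1 DB).
   Species are *unrecognised* (unparseable or subclass outside the
   registry), *processed* (on ≥1 instantiated edge) or *unprocessed*;
   only processed species are analysed further.

3. **Reaction scoring.** For each edge, the per-sample activity is
   `a_j = ln((Σ product + ε) / (Σ substrate + ε))`, a flux proxy; sums run
   over the species instantiating the edge (one species each at species
   level). Activities are compared between the condition of interest and
   the control with a Welch-type statistic (or a one-sample statistic on
   per-pair differences for matched designs), read on the standard-normal
   scale: `p = 1 − Φ(z)`, *active* if `z > Φ⁻¹(1−α)` (1.645 at α = 0.05),
   *suppressed* if `z < −Φ⁻¹(1−α)`.

4. **Pathway combination.** Chains of consecutive reactions are scored
   with the Stouffer rule `z_path = Σ zᵢ / √k`. This combiner is pinned by
   an internal-consistency property of the bundled reference table
   (aged-vs-young mouse liver): chain-level scores over-determine the
   single-step scores, and inverting the rule on some rows then recombining
   reproduces the other rows to ~1e-3 (the propagated rounding of 3-d.p.
   inputs).

5. **Calling and gene prediction.** All simple chains up to a length cap
   (default 6 reactions — the longest reference chain has 4) are enumerated
   from every node; each chain's gene list is the concatenation of per-step
   gene lists, de-duplicated preserving order. The *most-active* display
   rule walks greedily from each starting substrate, taking the
   continuation with the highest z at each branch (lowest for the
   suppressed side; ties broken by lexicographically smaller product
   label), and reports the prefix with the extreme combined z, one route
   per substrate.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | one-sided significance level; 0.05 ↔ critical Z 1.645 |
| `paired` | False | matched-pairs design; per-pair differences are tested |
| `level` | subclass | aggregate nodes to subclasses, or keep species |
| `network_type` | lipid | lipid network, or the FA elongation/desaturation network |
| `max_chain_length` | 6 | cap on reactions per enumerated chain (simple paths only) |
| `require_fa_for_deacylation` | True | deacylation needs a balancing measured FA, symmetric with acylation |
| `ε` pseudo-count | half the smallest positive abundance | tolerates zero totals in the log ratio |

Replicates: a minimum of two per condition is enforced; three or more are
recommended. Species observed in fewer than two replicates of either
condition are excluded before analysis. Missing cells are treated as
missing, not zero; zero abundances are retained.

## Design choices made where the design was open

- **The per-sample statistic.** The log product/substrate ratio with a
  Welch-type comparison is this package's reconstruction of the
  reaction-level statistic; the fraction-based alternative
  (product/(product+substrate)) would be a drop-in replacement behind
  `reaction_activity`. The log ratio was chosen because it is exactly
  normal under the lognormal generator, is antisymmetric under swapping
  the conditions, and makes a doubling of product and a halving of
  substrate equivalent.
- **Normal rather than t calibration.** The t-like statistic is mapped
  directly to the normal scale (p < 0.05 ↔ Z > 1.645, a normal quantile),
  with no t-distribution p-value conversion and no multiple-testing
  correction. Consequence: at very small n the calls are anti-conservative
  (for n = 5 per group the true one-sided level at 1.645 is ≈ 0.07); the
  type-I calibration test therefore uses n = 30 per group, where the
  normal mapping holds to within binomial error.
- **Deacylation and FA availability.** Acylation reactions cannot be
  instantiated without a measured FA species; the hydrolysis direction is
  treated symmetrically (default) because both directions move a defined
  acyl chain. The `require_fa_for_deacylation` switch relaxes this to a
  plain carbon/double-bond-decrease check.
- **Collapsed intermediates.** Routes through CDP-diacylglycerol are
  stored as single PA→PG / PA→PI / PA→PS edges carrying the collapsed
  step's genes (CDS1/CDS2/PTPMT1/CDIPT/PTDSS1); no CDP-DG node exists.
- **PC→CL** is modelled as composition-preserving so the edge exists in
  the database; since a diacyl PC rarely shares a sum composition with
  tetra-acyl CL, it seldom instantiates on species-resolved data. This is
  a known simplification.
- **Ether subclasses** (`O-PC`, `O-DG`, …) are independent nodes with
  parallel reactions; there are no O-↔diacyl cross edges.
- **Gene annotations** are human HGNC symbols; two annotations are kept
  as published in the reference table rather than re-curated (CRLS1 on
  PG→LPG; SGMS1/SGMS2 on dhSM→dhCer), so that chain gene lists reproduce
  the reference exactly. Users working in other species should map
  symbols accordingly.
- **Database membership.** The reference tables attest 24 chains and the
  single steps they decompose into; the remaining inventory (Lands-cycle
  reacylations, sphingolipid salvage, the ELOVL/FADS/SCD fatty-acid
  ladder, acyl-CoA/carnitine activation steps) was curated from standard
  mammalian lipid biochemistry to the stated 94-reaction / 41-subclass
  registry. The database is a TSV resource and can be overridden with
  `--database`.

## Numerical conventions

- Zero pooled variance with equal means gives z = 0; with unequal means a
  signed-infinity sentinel (status by sign). Non-finite edges are excluded
  from chain enumeration.
- Samples in which an edge's substrate and product totals are both
  missing are dropped for that edge (pairs are dropped jointly in matched
  designs).
- Node/edge orderings, JSON keys and float formatting (z to 3 d.p.) are
  fixed, so exports are byte-stable for a fixed input and configuration.
- Ties in the most-active rule break to the lexicographically smaller
  product label.

## What the synthetic generator does and does not emulate

`lipidpath.synthetic` draws i.i.d. lognormal abundances (default
σ = 0.1 on the log scale, five replicates per condition, baseline
ln-mean ln 100) and plants multiplicative fold-changes on the product
species of chosen reactions. Under this generator the activity statistic
is exactly normal, with expected Z ≈ ln(fold)/√(σ_a²/n_I + σ_a²/n_C),
σ_a the activity s.d. — so power and type-I behaviour have closed forms
and the generator can act as an oracle. It does **not** emulate
instrument noise structure, correlated species (beyond the planted
effect), batch effects, censoring at the detection limit, or
non-MCAR missingness. Passing tests therefore validate the statistical
machinery and the matching rules, not robustness to real-data artefacts.

## Known limitations

- Sum-composition matching cannot distinguish isomers (n-3 vs n-6 FA
  series collapse onto the same C:D nodes) and may join species that are
  not true substrate/product partners.
- Cholesterol, eicosanoid, oxidised-lipid and hexosyl-ceramide pathways
  are not covered; sterol subclasses are recognised but reaction-free.
- The per-reaction statistic is a reconstruction (see above); absolute z
  values on real data depend on that choice, although signs and ordering
  are stable across reasonable alternatives.
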