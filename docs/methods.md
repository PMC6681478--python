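# Methods

## Charge model and isoelectric point

The net charge of a chain is modeled as a sum of independent
Henderson–Hasselbalch terms over ionizable groups: basic groups
(His, Lys, Arg side chains plus one free N-terminus) contribute
`N/(1+10^(pH−pKa))`, acidic groups (Asp, Glu, Cys, Tyr side chains plus
one free C-terminus) contribute `−N/(1+10^(pKa−pH))`. The model
assumes a native, unmodified sequence — no post-translational
modifications, no electrostatic coupling between sites, exactly one
pair of free termini per chain. Each term is strictly decreasing in
pH, so the net charge has a unique root: the isoelectric point.

The root is found by bisection on [0, 14]. If the charge does not
change sign there (possible for extreme compositions, e.g. hundreds of
Arg with pKa 11.84 pushing the root slightly above 14), the bracket is
widened in 1 pH-unit steps, to at most [−5, 19]; failure to bracket
after that is an error, which no valid chain can trigger because the
termini guarantee a sign change at the extremes. The bisection
tolerance defaults to 1e−3 pH units — far below the two decimals at
which pI is reported — and is exposed as a parameter; the
grid-oracle equivalence test runs at 1e−5 so the comparison band
(2e−4) is not dominated by the solver tolerance itself.

The default pKa scale is the IPC protein scale (N-term 9.094, C-term
2.869, C 7.555, D 3.872, E 4.412, H 5.637, K 9.052, R 11.84, Y 10.85).
It was chosen because it reproduces both published anchor values
simultaneously: the tetrapeptide MIMF (no ionizable side chains) roots
exactly at the terminal midpoint (9.094 + 2.869)/2 = 5.9815 → 5.98,
and the epsin composition (Asp 68, Gly 68, Ile 65, Met 3, Trp 67)
roots at 1.991 → 1.99. EMBOSS and Sillero scales ship in the same TSV
and are selectable by name; user-supplied tables use the identical
format.

Selenocysteine (U) is non-ionizable by default, matching the
calculator convention the anchors were computed with; an optional
acidic group (suggested pKa ≈ 5.2) can be enabled via `sec_pka`.
Pyrrolysine (O) is non-ionizable. Ambiguity codes contribute as their
translation products: B as Asp, Z as Glu, J as Leu; X is inert.

## Mass, formula and reporting conventions

Average (isotope-abundance-weighted) residue masses are used
throughout; the chain mass is the residue sum plus one water
(18.01524 Da). The residue table stores both masses and element
counts (C, H, N, O, S, Se) and is validated on load for
self-consistency within 0.01 Da. Strict policy errors on any residue
without its own entry; the default lenient policy maps B/Z/J to their
translation products and gives X zero mass (any placeholder would bias
the mass, and no published rule exists), counting each skipped X on
the profile.

Reported kDa values are **truncated**, not rounded, to two decimals:
of the three published small-protein masses, 575.68 Da → 0.57 and
636.76 Da → 0.63 are reproducible only under truncation (rounding
gives 0.58/0.64), while 540.74 Da → 0.54 is unaffected. pI is
reported rounded (half away from zero) to two decimals; both anchors
are insensitive to that choice.

Classification uses the rounded pI: acidic < 7.00, neutral exactly
7.00, basic > 7.00. Neutrality is therefore a band of width 0.005 on
each side of 7, which is what makes a small nonzero neutral percentage
possible at proteome scale. The ≥ 100 kDa share uses an inclusive
threshold on the raw Da value. Extreme-protein rankings break ties on
the value by lexicographically smaller id, making all outputs
deterministic.

## Distributions and the virtual gel

pI histograms use uniform bins covering [0, 14] (default width
0.1 pH), half-open except the final closed bin so pH 14 is counted.
Mode detection smooths the counts with a Gaussian kernel (default
sigma 0.2 pH) under a reflective boundary, which conserves total
density; a mode is a local maximum of the smoothed density with
prominence at least a fraction (default 0.02) of the global maximum.
The defaults classify a constructed three-Gaussian mixture
(means 5.5/7.8/10.5, sd 0.3) as trimodal and a broad unimodal sample
as unimodal; no published bin width or bandwidth exists for the
proteome-scale figure these mimic, so the defaults are declared here
and exposed in configuration. The virtual gel bins proteins in
(pI, log10 kDa); the mass axis is logarithmic because real proteome
masses span ~0.5 to ~2200 kDa. The mass–pI association is the
product-moment Pearson r with the two-sided p-value from the
t-transform at n−2 degrees of freedom.

## PCA and influence statistics

Feature vectors per proteome are the 20 residue fractions
(renormalized over the standard alphabet) optionally joined by
pct_acidic, pct_basic and the average acidic/basic pI. Because the
features mix percentages and pH units, the default scaling is
autoscale (center, divide by sample sd, ddof 1); center-only is
available. The decomposition is an exact SVD of the scaled matrix —
inputs are at most a few hundred rows, so no iterative solver is
needed — with component signs fixed by making each component's
largest-magnitude loading positive. Hotelling's T² is
Σ score²/component variance over retained components (components with
numerically zero variance contribute nothing); the Q residual is the
squared reconstruction error of the scaled row using the retained
components. If a proteome has an empty acidic or basic class (its
average pI undefined), the pipeline falls back to composition-only
features and notes it in the run log.

## Synthetic study conditions

The generator emulates the statistical shape of downloaded plant
proteomes. Defaults, which constitute the study conditions of the
packaged experiments:

* **Lengths**: log-normal with mean 424.34 residues (the reported
  kingdom-wide average) and sigma 0.75 in log space, truncated by
  resampling to [4, 25000]. Sigma 0.75 yields both a realistic median
  (~320) and a heavy tail approaching giant-protein scale.
* **Composition**: base frequencies are the published kingdom-wide
  averages (Leu 9.62% … Trp 1.28%), renormalized (they print to a sum
  of 100.90). Every chain starts with Met, as every published small
  protein does; this adds ~1/424 to the realized Met fraction.
* **Per-proteome jitter**: Dirichlet around the lineage-shifted base
  with concentration 2000, so per-proteome percentages vary by tenths
  of a percentage point; `None` disables jitter. The concentration is
  a free parameter, not an estimate from data.
* **Lineage shifts**: log-fold perturbations arranged as two opposed
  pairs — algae vs bryophyte on {A, G, R, V, L, S, T} and monocot vs
  eudicot on {E, D, K, P, I, F, Q}, magnitudes 0.20–0.30. Abundant
  residues are used because the per-feature signal-to-noise scales as
  `lf·sqrt(conc·p/(1−p))`; the two-axis geometry puts the four lineage
  centroids in a plane the first two principal components can capture,
  which is what makes 12 proteomes separable (PC1–PC2 silhouette
  0.65–0.84 across seeds) despite small-sample noise eigenvalues.
* **Ambiguity codes**: injected per body residue (never position 1,
  never inside planted sequences) at rates X 2e−5, B 5e−6, Z 3e−6,
  J 3e−6 — X most common, as observed in real annotation — and U only
  via planted selenoproteins so Sec censuses are exact.
* **Planted extremes**: a 22,244-residue background-composition giant;
  the MIMF tetrapeptide; "M"+(GWID)×67 (67 Asp against one basic
  terminus forces pI ≈ 2.0 < 3); "M"+(QKLKSGLT)×64+(TRRGLTAV)×31
  (pI ≈ 13.6 > 11); selenoproteins of length 300 with exactly 9, 16
  and 11 Sec in the three algal proteomes. Background draws make a
  colliding extreme (a second length-4 chain, a >22,244-residue giant)
  astronomically unlikely (tail probability < 1e−8 per protein), so
  planted features are unambiguous.

What the generator does **not** emulate: per-protein compositional
heterogeneity (real proteomes mix acidic and basic protein families,
producing the characteristic trimodal pI distribution; i.i.d. draws
from a single frequency vector give a narrower, roughly bimodal
spread dominated by the Lys/Arg–Asp/Glu balance), codon or GC
structure, domain architecture, and phylogenetic covariance between
proteomes. Passing recovery tests therefore demonstrates that the
pipeline measures what is planted, not that real plant proteomes have
these properties; the published kingdom-wide percentages (56.44%
acidic etc.) are documentation and generator defaults, not test
targets, since they derive from ~5.87 million downloaded sequences.

## Problem sizes

The packaged experiments run at desk scale: the recovery study is
4 lineages × 3 proteomes × 2,000 proteins (~10 M residues, a few
seconds end to end); the grid-oracle comparison uses 1,000 random
compositions against an exhaustive 1e−4 pH scan; composition
convergence is checked at 200 and 20,000 proteins, and the
50,000-protein single-proteome draw bounds the realized Leu fraction
within ±0.3 percentage points of its target.

## Known limitations

* The charge model ignores site–site interactions, PTMs and solvent
  exposure; computed pI is the sequence-intrinsic estimate, which can
  differ from measured pI.
* X-containing masses are lower bounds under the default policy.
* Mode detection reports modes of a smoothed histogram; it is not a
  statistical test of multimodality (no dip test), matching its
  intended descriptive use.
* The calibration/validation split seen in chemometrics software
  influence plots is out of scope; influence statistics are fit
  statistics only.
* pI values can legitimately exceed 14 for pathological compositions
  (hundreds of Arg); per-protein profiles enforce (0, 14) because real
  annotated proteins stay inside it, while `isoelectric_point` itself
  reports the widened-bracket root.
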