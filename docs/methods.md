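# Methods

## Setting

One linked cohort of n patients has its attributes split *vertically*: two
or more data-contributing sites each hold a disjoint subset of the columns
(covariates and/or the outcome), with a shared patient identifier and a
common row order.  The goal is to fit the pooled regression

- linear: `y = β₀ + Xβ + ε`, `ε ~ N(0, σ²)`
- logistic: `y ~ Bernoulli(expit(β₀ + Xβ))`

without any party ever receiving another party's patient-level columns, and
to reproduce the pooled patient-level estimates essentially exactly — the
package's working standard is agreement within 1e−12 for the
non-iterative linear fit and 1e−8 for the iterative logistic fit.

The package assumes the cohort is pre-linked: every site lists the same
patients, alignment is by sorted integer patient ID, and readers reject
duplicate IDs and missing values.  Record linkage itself is out of scope.

## Sufficient statistics and the global Gram matrix

With the intercept-augmented design `A = [1 X]`, the linear fit needs only

- `G = AᵀA` (the global covariance/Gram matrix),
- `Aᵀy`, `yᵀy`, and `n`.

Coefficients solve the normal equations `G β = Aᵀy` (by Cholesky, never an
explicit inverse; a condition number above 1e12 raises a collinearity
error).  The error variance is computed from summaries alone,

    σ̂² = (yᵀy − 2βᵀAᵀy + βᵀGβ) / (n − p − 1),

with `cov(β̂) = σ̂² G⁻¹`, `R²` from `yᵀy` and the intercept column sum.  The
n − p − 1 denominator is the usual intercept-model convention; it is a
`df_resid` argument because production systems disagree about it.

`G` is assembled at the analysis center from blocks: each site computes its
own `XₖᵀXₖ` and column sums locally; each cross-site block `XᵢᵀXⱼ` runs the
secure protocol below.  The intercept row/column is synthesized at the
center from `n` and the column sums, so no site owns an intercept column.
The outcome column rides along with its owner's columns in the cross-site
products, so `Xₖᵀy` needs no extra protocol round.  The global column order
is: intercept, then sites in plan order, each site's columns in declared
order.

## The secure cross-product protocol

The protocol computing `XₐᵀX_b` between sites A and B is a two-message,
strictly sequential projection-masking exchange:

1. A draws `Z`, an n×g matrix with orthonormal columns spanning a random
   g-dimensional subspace of the orthogonal complement of span(Xₐ), and
   sends it to B.
2. B replies with the masked payload `M = X_b − Z(ZᵀX_b)`.
3. A computes `XₐᵀM = XₐᵀX_b − (XₐᵀZ)(ZᵀX_b) = XₐᵀX_b`, exactly, because
   `ZᵀXₐ = 0` by construction.

A never sees raw `X_b`: each of B's columns arrives with its component in
the g masked directions removed.  B sees only `Z`, which is independent of
A's data values (it is a random basis of the complement).  This is a
masking construction, not a cryptographic one: no security proof is
claimed, and the degenerate `g = 0` case (payload = raw) is detectable by
`leakage_check`, which reports payload–raw correlations and flags
`NO-MASKING`.

Numerical details that matter:

- `Z` is built by projecting an n×g Gaussian matrix out of span(Xₐ) and
  QR-orthonormalizing, with the projection and orthonormalization each
  applied twice ("twice is enough" re-orthogonalization).  This drives
  `‖ZᵀXₐ‖` to ~1e−15·‖Xₐ‖, which is what keeps the end-to-end fit at the
  1e−12 standard even for cohorts of several thousand rows; a single pass
  leaves ~1e−12-level residuals that contaminate the Gram blocks at ~1e−9.
- Default mask dimension `g = ⌊(n − pₐ)/2⌋` — half the dimensions the rank
  bound `g ≤ n − pₐ` allows, a balance between information hidden and
  payload conditioning.  Configurable everywhere.
- The n×n operator `I − ZZᵀ` is never materialized; B applies it as
  `X_b − Z(ZᵀX_b)`.  A `materialize_full_operator` option reproduces the
  n×n payload for transfer-metrics experiments, since the n×n transfer is
  the canonical cost driver of the vertical setting.
- All masks are seeded; per-pair/per-block seeds derive from
  (seed, site-pair CRC, block index), so runs are exactly reproducible.
- Tolerances: orthonormality and protocol-vs-direct equivalence at 1e−10
  absolute; final regression equivalence at 1e−12.

The payload is n×g / n×p — it grows with cohort size, not covariate count.
This is the structural difference from the horizontal setting, where only
p×p summaries travel, and is why the transfer fabric's metrics track
maximum payload rows separately from Gram-block dimensions.

## Distributed IRLS for logistic regression

Fisher scoring on the logistic likelihood is iteratively reweighted least
squares.  Per iteration:

1. each site sends its partial linear predictor `η_k = X_k β_k` (an
   n-vector) to the center; `η = β₀ + Σ_k η_k`;
2. the center computes `μ = expit(η)`, weights `w = μ(1−μ)` (clipped via
   `μ ∈ [1e−10, 1−1e−10]`), and the working response `z = η + (y − μ)/w`,
   and broadcasts `(w, z)` to the sites;
3. sites produce the weighted blocks: `XₖᵀWXₖ` and `XₖᵀWz` locally (they
   hold `w, z`), `XᵢᵀWXⱼ` by the secure protocol on √w-scaled columns;
4. the center solves the weighted normal equations.

The outcome site transfers `y` to the semitrusted center once so the center
can form `z`; together with the per-iteration `η_k` vectors this is
summary-level but n-granular disclosure — a real concession of the vertical
iterative setting, documented rather than hidden (the metrics count these
n-row payloads).

Convergence: stop when `max|Δβ| < tol` (strict inequality; default
tol = 1e−8, max_iter = 25; a relative-deviance-change criterion is
available).  β starts at zero; warm starts via `beta_init`.  On
convergence one extra round evaluates `(XᵀWX)⁻¹` and the deviance at the
final β, so standard errors come from the information matrix at the
reported coefficients.  Divergent coefficients (|β| > 1e10) raise a
separation error.  Deviance is non-increasing across iterations on
separation-free problems and is asserted as such in the tests.

The pooled oracle for verification is statsmodels (OLS; GLM-Binomial fitted
to tol 1e−12 so the oracle's information matrix is evaluated at the ML
optimum rather than one deviance-rule step short of it).  The oracle is
only ever a comparator — the distributed path never calls it.

## Divide-and-conquer blocking

Cross products are additive over disjoint row blocks, so a `BlockPlan`
(contiguous half-open row ranges covering the cohort, identical at every
site) lets each cross-site block be computed per row block — with its own
seeded mask, g capped at the block's rank bound — and summed.  Results are
invariant to the plan at 1e−12; blocking only bounds the size of any one
masked payload.

## The transfer fabric

The file-transfer simulation models a governed research network portal:

- Parties are one analysis center plus ≥2 sites, each with inbox/outbox
  directories under a versioned run directory (re-running never disturbs a
  prior run's audit trail).
- Files move in manifests: batches delivered atomically (all files verified
  by SHA-256 before any is placed), each manifest one audited "leg".
  Batched multi-file manifests model simultaneous upload/download; OS-level
  concurrency is deliberately not simulated — the observable contract (one
  delivery event, many files) is what matters.
- The trust matrix is owned by the center, deny-by-default for site↔site
  pairs, center transfers always allowed.  Only the center can mutate it
  (version-incrementing, audited).  A forbidden transfer is rejected and
  the entire run is terminated — no manifest is delivered afterwards
  (halt-without-purge: already-delivered files remain, logged).  A checksum
  failure merely rejects the manifest; the stricter response is reserved
  for governance violations.  Enforcement is at submission time.
- Routing: `direct` sends a site→site exchange in one leg; `hub_and_spoke`
  relays it through the center in exactly two.  Hence the exact accounting
  law: hub legs = direct legs + (number of site↔site exchanges).  Results
  are identical between modes; only metrics differ.
- Time is a logical integer clock; the audit log is append-only JSON lines;
  matrices travel as full-precision (%.17g) CSV with a JSON sidecar
  carrying dimensions, producer, provenance and checksum.

## The synthetic-cohort generator

The generator emulates a pre-linked multi-site cohort with a known
regression structure: binary covariates as Bernoulli(π), continuous as
Normal(μ, σ), outcome by the linear or logistic model above.  Each column
draws from its own stream keyed by (global seed, column-name CRC), so
adding a covariate never perturbs existing columns.  The canonical small
fixture mirrors a two-site surgery-outcomes scenario — surgery, sex, race
(binary) at site 1, continuous BMI outcome at site 2.

What it does *not* emulate: missing data (generators never emit it, readers
reject it), measurement error, dates/code systems, linkage error, or
realistic claims-data dependence structures.  Passing tests therefore
demonstrate *numerical* equivalence of distributed and pooled estimation
and *exact* governance semantics; they say nothing about robustness to the
messiness of real multi-site data.

## Verification study sizes

The reference studies (`vdra.studies`, re-run by `scripts/acceptance.py`)
use: n = 5452, p = 10 standardized covariates, two sites for the linear
equivalence study; n = 2000, p = 5 for the logistic study; 100 random
instances (n ≤ 100, p ≤ 5) for the secure-product oracle suite; and a
200-patient two-site fixture for the governance, routing and blocking
studies, which measure exact counts and bit-level invariances that do not
improve with cohort size.  The networked (file-fabric) runs use the small
fixture because a masked payload is an n×g matrix — at n = 5452 a single
mask basis is ~15M numbers, which is faithful to why the vertical setting
strains file transfer but pointless to serialize repeatedly; the large-n
equivalence studies run the identical protocol over the in-memory channel.

## Known limitations

- The masking protocol is information-reducing, not cryptographic; collusion
  between the center and a site, or knowledge of `Z` plus side information,
  narrows what the mask hides.  Perturbation/encryption layers are out of
  scope.
- Iterative fits disclose n-granular vectors (η_k, w, z, and y to the
  center); acceptable only under a semitrusted-center model.
- Cox proportional hazards is not implemented (no summary-statistic
  algorithm of the same exactness class is available in this design).
- Categorical covariates must arrive pre-coded as numeric columns; no
  robust/sandwich variances; no regularization; no model-fit graphics.
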