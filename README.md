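# stemoran

Fixation probabilities and invasion dynamics of mutants in a stem /
non-stem cell hierarchy with phenotypic plasticity — a four-compartment
generalized Moran process.

## The problem

Tissues such as the intestinal crypt are maintained by a small niche of
stem cells (SCs) whose progeny, the differentiated / non-stem cells (DCs),
do the tissue's work but have limited proliferative potential.  An
oncogenic mutant arising in either compartment competes with the wild type
under constant compartment sizes N_S and N_D.  Two couplings connect the
compartments: SC offspring *differentiate* into the DC pool with
per-division probability u, and — under permissive microenvironments such
as inflammation — DC offspring can *dedifferentiate* back into a stem-like
state with probability η (plasticity).  The central question is the
fixation probability ρ of a single mutant: the chance its lineage takes
over both compartments, as a function of the division rates r₁, r₂
(wild-type / mutant SCs), r̃₁, r̃₂ (DCs), u₁, u₂ and η₁, η₂.

`stemoran` is aimed at researchers in evolutionary dynamics / mathematical
oncology who need these quantities exactly, stochastically, or in the
deterministic limit.

## The model

At each update a cell is chosen to reproduce with probability proportional
to its division rate; its offspring replaces a uniformly chosen cell of
the destination compartment.  The mutant counts (n_S, n_D) then form a
bivariate birth–death chain with one-step moves W_S±, W_D± (e.g.
W_S⁺ = [r₂(1−u₂)n_S + r̃₂η₂n_D]/N_r · (N_S−n_S)/N_S, with N_r the total
reproductive weight).  The package computes the mutant's fate four ways:

* **Generating-function (martingale) solution** — auxiliary constants
  (z_S*, z_D*) solving a coupled algebraic system give
  ρ_ij = (1 − z_S*^i z_D*^j)/(1 − z_S*^N_S z_D*^N_D), with closed forms in
  the decoupled, negligible-DC-division and zero-plasticity limits
  (`stemoran.exact_fixation`);
* **Markov-chain oracle** — exact absorption probabilities of the finite
  chain by sparse linear solve, the package's ground truth
  (`stemoran.markov_oracle`);
* **Monte-Carlo simulation** — vectorized realizations with the batch
  protocol (20,000 realizations × 5 repeats, 15,000-step cap)
  (`stemoran.moran_simulator`);
* **Replicator dynamics & phase diagrams** — the infinite-population flow
  for the frequencies (x_S, x_D), the invasion eigenvalue at the
  extinction state, and the transcritical neutrality boundary, including
  its closed-form polynomial (u+η−1)r² + [−u²+(η−1)u+2−η]r − 1 + u² = 0
  for the symmetric parameterization (`stemoran.replicator`,
  `stemoran.phase_diagram`).

A note on exactness: the martingale closure is exact in the hierarchical
(η = 0) and decoupled limits, but the chain's total fitness N_r is
frequency dependent, so for strongly coupled regimes (large u with
plasticity) the generating-function value can deviate from the true
absorption probability by a few percent; the oracle quantifies this —
see `docs/methods.md`.

## Worked example

The colorectal-crypt scenario: a P53 mutant is weakly deleterious
(r₂ = r̃₂ = 0.96) and differentiates less than the wild type
(u₂ = 0.25 vs u₁ = 0.5); inflammation grants it plasticity η₂ = 0.12.

```sh
stemoran exact --n-stem 10 --n-diff 10 --r2 0.96 --rt2 0.96 \
    --u1 0.5 --u2 0.25 --eta2 0.12
```

prints

```json
{
  "z_s": 0.6601465353394051,
  "z_d": 0.9470287461223944,
  "degenerate": false,
  "rho_s": 0.342981748207814,
  "rho_d": 0.053458843733858424,
  "rho_avg": 0.19822029597083624
}
```

(parameter echo omitted): a single mutant **stem** cell fixes with
probability ρ_S ≈ 0.343 — despite its raw fitness disadvantage — while a
single mutant **non-stem** cell still has a ρ_D ≈ 0.053 chance through
dedifferentiation.  Without plasticity (η₂ = 0) the same parameters give
ρ_S ≈ 0.314, and with balanced differentiation the deleterious mutant
would be purged; plasticity and division polarity together turn it
advantageous.

The neutrality boundary for balanced differentiation and plasticity:

```sh
stemoran phase --u 0.5 --eta 0.5
```

```text
u	eta	axis	method	critical_value
0.5	0.5	r	closed	0.75
```

i.e. with u = η = 0.5 a mutant is advantaged already for r > 0.75.

The same quantities are available from Python (`stemoran.fixation_summary`,
`stemoran.absorption_probability`, `stemoran.estimate_fixation`, ...), and
`stemoran scenario fig8` (or `fig2a` … `fig6b`, `table2`) regenerates the
published parameter sweeps as TSV tables.

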