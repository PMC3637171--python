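# growssa

Stochastic simulation of bacterial gene-regulation circuits in growing,
dividing cells.

`growssa` extends the direct-method Gillespie SSA with the physiology that a
constant-volume SSA ignores:

* **Exponential cell-volume growth.**  Bimolecular propensities scale as
  1/V(t) and concentration-defined influxes as V(t), so the total propensity
  between events is `A + b·exp(-mu·s) + g·exp(mu·s)` with `mu = ln2/T`.
  Waiting times are sampled exactly by inverting the cumulative hazard; the
  mixed volume-independent/bimolecular case has a closed form through the
  principal branch of the Lambert W function, refined to a residual of
  `1e-12·(1+L)` so delayed-event preemption can never starve slow channels.
* **Delayed reactions.**  A channel may consume its reactants at initiation
  and release its products a fixed delay later (multi-step transcription or
  translation); pending releases live in a time-ordered event queue that
  preempts sampled reactions.
* **Deterministic replication scheduling.**  Gene dosage follows
  replication-fork passage with constant C-period (default 40 min) and
  D-period (20 min) and supports overlapping cell cycles: a locus can be
  present in up to 8 copies at short generation times.  Replicated promoters
  release their bound transcription factors and new gene copies are
  regulated independently.
* **Cell division with lineage tracking.**  At age T the cell divides
  symmetrically: free molecules are partitioned binomially (exactly
  conserving totals), gene copies are split one-per-pair with their promoter
  occupancy states intact, and both daughters are simulated onward into a
  binary lineage tree with per-cell trajectories.
* **Optional extrinsic noise.**  A shared Ornstein–Uhlenbeck process can
  multiply selected rate constants by `exp(eta)`, advanced with the exact OU
  transition at every event.

Independent reference solvers (deterministic ODE, delayed ODE via fixed-step
RK4 with dense history, a classic constant-volume SSA, and dynamic
flux-balance ODEs) are included for validation, plus five packaged example
systems: negative autoregulation with and without a 1000 s translation
delay, a mutual-repression toggle, and a metabolic flux model with balanced
vs unbalanced chromosomal gene placement.

## CLI

```sh
growssa validate MODEL.yaml                # schema + unit validation
growssa simulate MODEL.yaml --t-end 12000 --seed 1 --out outdir/
growssa dosage --p 0.0 --t 50              # doubling age, copies at birth
growssa ode --system autoreg --out ode.tsv
growssa dde --delay 1000 --out dde.tsv
growssa classic-ssa MODEL.yaml --out ssa.tsv
growssa run-example negautoreg_delay --seed 1
```

`simulate` writes per-cell trajectory TSVs (`time_s`, `cell_id`,
`volume_L`, one column per species and gene copy number), an annotated
Newick lineage tree, a JSON summary (seed, config, per-cell cycle means) and
a run log.  Outputs are byte-identical across reruns with the same model,
config and seed.

## Model files

YAML with top-level keys `name`, `species`, `reactions`, `genes`, `config`,
and optionally `extrinsic_noise`; see `src/growssa/examples/data/` for
complete examples.  Conventions:

* Internal state is integer molecule counts; concentrations are µM with
  `Omega = N_A · V · 1e-6` molecules per µM (birth volume default
  1.1e-15 L).
* `rate_units`: `per_second`, `per_uM_per_second` (required for order-2
  channels, propensity `k·X1·X2/Omega(t)` or `k·X·(X-1)/Omega(t)`),
  `uM_per_second` (order-0; declare `volume_class: proportional` for
  true concentration-defined influxes), `per_gene_per_second`,
  `per_mRNA_per_second`.
* `modifiers` are catalytic templates (counted in the propensity, never
  consumed) — e.g. mRNA in translation.
* `rate_law: michaelis_menten` with `km` (µM) gives propensity
  `k·X_enz·X_sub/(km·Omega(t)+X_sub)`.
* Genes carry a chromosomal `position` in [0, 1] (origin to terminus), a
  per-copy transcription rate, and a promoter with TF binding sites
  (`k_on`, `k_off`, `bound_factor`), optional per-state factors and
  cooperativity multipliers.
* `config` times: `T`, `C`, `D` in minutes; `t_end`, `grid_dt` in seconds.

## Layout

```
src/growssa/
  model.py        domain types, validation, unit conventions
  dosage.py       replication-fork dosage scheduling (closed forms)
  engine.py       the growth-aware SSA (propensity split, Lambert-W
                  firing-time sampling, delayed/replication event loop)
  population.py   division, binomial partitioning, lineage trees, analytics
  noise.py        shared OU extrinsic noise
  reference.py    ODE / delayed-ODE / classic-SSA / flux-ODE oracles
  examples/       packaged example models (YAML) and runners
  io.py, cli.py   model file reader/writer, trajectory/lineage writers, CLI
  acceptance.py   recomputable acceptance metrics (shared by tests and
                  scripts/acceptance.py)
```
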