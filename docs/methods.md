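# Methods

## Model and assumptions

The pipeline treats a protein complex as a dense subgraph of the PPI network
whose members are *simultaneously present* in the cell. Presence is proxied
by transcription: a protein exists at timestamp `t` when its gene's mean
expression there strictly exceeds the gene's own three-sigma threshold

    AT = UE + 3σ·(1 − Fl),   Fl = 1/(1 + σ²),

with `UE` and `σ²` the mean and *population* variance (divide by `T`) of the
per-timestamp means. The fluctuation weight interpolates between the mean
(`σ² → 0`, flat genes: any rise counts, but a strictly constant gene can
never be active) and the full three-sigma bound (`σ² → ∞`, volatile genes:
only extreme peaks count). An edge survives into the subnetwork at `t` only
when **both** endpoints are active — the only reading under which a
subnetwork is a network of co-occurring proteins. Values are taken as
printed: no log-transform or normalization is applied to expression input.

A numerical guard treats exceedances below `1e-12 · max(1, |UE|)` as ties:
the mean of a floating-point-constant row can differ from its entries by one
ulp, and a constant gene must never be called active.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `λ_c` | seed clustering-coefficient threshold | 0.5 | midpoint; config-exposed |
| `λ_d` | refinement density threshold | 0.5 | midpoint; config-exposed |
| `ic` | MCL inflation | searched in [1, 6] | granularity knob |
| `b` | penalty balance | 0.5 | standard value for this family |
| `pp` | penalty proportion | 1.25 | standard value |
| expansion | MCL matrix power | 2 | canonical choice |
| `α` | pull toward clan best | 0.5 | reported optimum of the method family |
| `β` | scale of the best→center move | 0.1 | likewise |
| clans × pop | search population | 20 × 10 (paper), 5 × 5 (desk) | |
| max_gen / stagnation | stopping | 500 / 100 (paper), 50 / 10 (desk) | |
| CSS threshold | match cutoff | 0.2, strict `>` | |
| min complex size | noise rule | 3 | smaller clusters are discarded |

The desk profile is the package default: subnetworks at desk scale are
small (tens of nodes), the fitness landscape over `ic` is coarse, and the
archive invariably saturates within a handful of generations, so the larger
budget changes nothing but runtime. The paper profile is selected with
`profile="paper"` / `--profile paper`.

`λ_c` and `λ_d` have no published values; 0.5/0.5 are neutral midpoints and
both are exposed in the config and CLI. Warm-start clusters serve only as
the generation-1 incumbent of the archive — they do not bias MCL itself.

## Search design

Each elephant is a point in MCL-parameter space; by default the search is
one-dimensional (`ic` only), since `b` and `pp` have fixed standard values —
a three-dimensional mode (`dims=3`) searches `b ∈ [0, 1]` and `pp ∈ [1, 2]`
as well. Clans are independent populations searching the *same* subnetwork;
the alternative reading (one clan per subnetwork) would make clan size and
subnetwork count collide and is not implemented. The clan-separating
replacement `p_min + (p_max − p_min + 1)·rand` can exceed `p_max`; positions
are clamped rather than reflected, honoring the stated bounds with the
simplest contract. Because the best-elephant move `β·p_center` can be
detrimental, reported results come from a best-so-far archive whose fitness
is non-decreasing by construction. One uniform draw is made per elephant per
dimension per move. A single seeded `numpy` generator is threaded through
the whole pipeline; with a fixed seed the run is bit-reproducible.

The attractor-penalty record is shared across all MCL evaluations within one
subnetwork's optimization: columns of frequent attractors are scaled by
`pp^(−count^b)` before each expansion, steering later evaluations toward
alternative cluster nuclei. With a fresh record the step is the identity and
the loop is canonical MCL.

## Numerical choices

- Adjacency diagonal = maximum incident weight; defined as 1.0 for an
  isolated node so its column is normalizable (flow stays put).
- Convergence: max-abs elementwise change `< 1e-8` between successive full
  iterations (idempotence proxy), capped at 100 iterations with a warning.
- Pruning zeroes entries `< 1e-6` and renormalizes; a column zeroed entirely
  regains unit mass on its diagonal.
- Cluster extraction: attractors are nodes with positive self-flow; a node
  joins the connected component of any attractor supporting it. A node
  supported by two attractor systems joins their merged component, so the
  output is a partition of the clustered nodes (no overlapping output).
- Refinement ties (equal clustering coefficient) remove the
  lexicographically smallest ID first; coefficient values are those of the
  full subnetwork, held fixed over the removal loop.
- Empty subnetworks are legal, logged, and produce no clusters; missing
  expression rows drop the protein by default (`always_active` is available
  because real PPI/expression identifier coverage never matches fully).
- Merged predictions deduplicate exact member sets only; near-duplicates
  from adjacent timestamps are kept as distinct predictions.

## Synthetic data

The planted-complex generator emulates the structure the method targets:
disjoint dense complexes (`p_in = 0.9` within, `p_out = 0.02` elsewhere,
complex connectivity enforced by resampling) among background proteins, and
an expression matrix in which each complex's genes spike (`bump = 10` over
`baseline = 5`, noise SD 0.5, `T = 12`, `TR = 3` — the shape of a yeast
metabolic-cycle compendium) at that complex's active timestamps.

Default activity windows are a **single timestamp per complex**, assigned
round-robin. This is forced by the three-sigma rule itself: for a square
bump of amplitude `A` spanning a fraction `f` of timestamps, activity
requires `A(1−f) > 3·A·√(f(1−f))·(1−Fl)`, i.e. `f ≲ 0.1` once `A` is large —
wider windows inflate the gene's own variance until the threshold overtakes
the peak. The generator re-derives activity calls from its own output and
refuses (with guidance) to emit a fixture in which fewer than 95% of planted
activations are recoverable, coupling fixture validity to the decomposition
code: a regression there breaks generation loudly.

What the generator does *not* emulate: scale-free degree distributions,
overlapping complexes (a flag exists for exploratory use, but CSS matching
and partition output make overlap recovery a separate claim), correlated
noise between repetitions, and identifier mismatch between network and
expression. Passing tests therefore demonstrate correctness of the
machinery and recoverability under clean planted structure, not performance
on real interactomes.

The hand-crafted toy fixture uses a *small* bump (1 over baseline 1): with
`T = 4`, a large single-timestamp spike would raise `σ²` enough that the
threshold exceeds the peak, while a unit bump keeps `σ²` small, `Fl` close
to 1, and the threshold just below the peak — the flat-gene regime of the
three-sigma rule.

## Problem sizes

Tests and the acceptance script run the full pipeline on ~100-protein
fixtures (10 planted complexes, 20 background proteins) with the desk search
profile, and operator-level checks on hundreds of random graphs of up to 50
nodes. These sizes keep the whole suite under a minute while exercising
every code path; the implementation itself is dense-matrix `numpy` and is
comfortable to a few thousand nodes per subnetwork.

## Known limitations

- The benchmark-accuracy fitness is circular for de-novo discovery (it
  optimizes agreement with the catalog being evaluated); the
  `internal_quality` mode exists for that use, but the benchmark mode
  remains the default because it reproduces the reference protocol.
- MCL output is a partition per timestamp; complexes sharing proteins can
  only be recovered across different timestamps.
- Expression is the sole activity signal; proteins without expression rows
  are invisible under the default policy.
- No parallel execution; subnetworks are processed sequentially.
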