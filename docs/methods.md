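# Methods

## Model

`boolteams` analyses signed directed regulatory networks — nodes are
transcription factors or microRNAs, edges are activations (+1) or
inhibitions (−1) — under a threshold Boolean formalism. The network is an
N×N adjacency matrix `Adj` with `Adj[i, j]` the sign of the edge i→j.
Node activities are spins sᵢ ∈ {−1, +1}. Dynamics are asynchronous: at
each step one uniformly random node i is set by a majority rule on its
signed inputs,

    sᵢ ← sign( Σⱼ Adjⱼᵢ sⱼ ),    ties keep the current value.

A state unchanged by this rule at every node is a fixed point (steady
state). Trajectories run until a fixed point or a cap of 1000 single-node
update attempts; runs hitting the cap are reported as unconverged and
excluded from frequency estimates. Limit cycles are outside the model's
scope and simply appear as non-convergence.

The tie rule is load-bearing: input-less signal nodes never change (they
act as frozen boundary conditions), and a node whose activation and
inhibition cancel retains its value, which is why a toggle switch with
self-activations has four fixed points rather than two.

### Stability metrics

- **Steady-state frequency (SSF)** — fraction of converged trajectories
  from uniformly random initial states ending in a given fixed point; a
  global-stability (basin-size) proxy. Default sample: min(2^N, 10⁵)
  initial conditions; at 10⁵ the binomial error of an SSF of 0.5 is
  ±0.3%.
- **Coherence** — probability that flipping one node of a fixed point and
  relaxing returns the system exactly to that fixed point, averaged over
  all N nodes × K repeats (K = 100 by default); a local-stability proxy.
  Signal flips can never revert, so a core-restricted variant asks
  instead whether the core sub-configuration recovers under signal flips.
- **Frustration** — fraction of edges with Adjᵢⱼ sᵢ sⱼ < 0 in a state
  (activations across discordant nodes, inhibitions across concordant
  ones); an Ising-energy-style measure of how well the topology supports
  the state. It is invariant under a global sign flip of the state.
- **Bimodality coefficient (BC)** — Sarle's statistic
  (skew² + 1) / (excess kurtosis + correction); the uniform distribution
  gives 5/9 ≈ 0.555, and BC > 0.55 is read as bimodality evidence.
  Because SSF spans orders of magnitude, its BC is computed on
  log10(SSF) — the scale on which SSF distributions separate into
  terminal and hybrid modes; raw-scale BC is dominated by the skew of
  weak-state tails rather than by bimodality. Coherence and frustration
  BCs use raw values.

### Influence matrix, teams, team strength

The influence of node i on node j averages signed path evidence over path
lengths 1..lmax (default 10):

    Infl = (1/lmax) Σ_{l=1..lmax}  Adj^l ⊘ |Adj|^l,

where ⊘ is elementwise division with 0 wherever |Adj|^l is 0 (no path of
length l). Each term is a net-signed-path over total-path quotient in
[−1, 1], so influence entries are bounded by 1 and `lmax = 1` recovers
the adjacency itself. Path counts are accumulated in float64; they are
exact integers up to 2^53, ample for the network sizes considered.

**Teams** are found by hierarchical clustering of the rows of the
core×core influence submatrix (Euclidean distance, complete linkage,
tree cut at two clusters). Clustering settings are a design choice: the
split is validated post hoc by requiring the within-team mean influence
to exceed the cross-team mean, with a Ward-linkage retry (and warning)
when complete linkage fails the check. **Team strength** is

    T_kl = mean of Infl over (i ∈ team k, j ∈ team l)  (diagonal cells included),
    Ts   = ( |T₁₁| + |T₁₂| + |T₂₁| + |T₂₂| ) / 4  ∈ [0, 1].

Ts = 1 only for a perfectly sign-coherent two-team matrix with unit
entries; Ts is invariant to team relabeling and node order. Team identity
is assigned by microRNA content (miR-prefixed names): the miR-richer team
is epithelial, the other mesenchymal — microRNAs in curated EMP circuits
are epithelial players. Ties keep generic labels.

A state is **terminal** (E or M) when its active core nodes are nonempty
and drawn from one team only, otherwise **hybrid**; an all-inactive core
is treated as hybrid (no terminal identity without at least one active
team member). The **EMT score** of a state is the active fraction of the
mesenchymal team minus that of the epithelial team (range [−1, 1]); it
is not uniquely standardized in the literature, and this active-fraction
difference was chosen as the simplest monotone summary of team activity.
**State strength** sums Infl over pairs of active nodes (spins mapped
−1→0, +1→1).

The **influence–correlation distance** d = Σ|Cor − Infl| / (2N²)
compares the influence matrix against the Pearson (phi) correlation of
node activities across per-run converged final states, so states are
implicitly SSF-weighted; zero-variance nodes are flagged and their
off-diagonal correlations set to 0. Note a structural limit: in a
strong-team network every path from a signal into a team is
sign-coherent, so signal→core influence magnitudes approach 1 while the
correlation of a frozen, randomly initialized signal with the core is
diluted across signals; the signal block therefore keeps d well above
zero even when the core blocks agree closely. d is reported as computed;
its informative use here is comparative (d falls as team strength rises).

### Null model and percentiles

Randomized networks exchange the signs of two randomly chosen
opposite-sign edges, k = 10 times. Edge positions never move, so all
per-node in/out degrees and global activation/inhibition counts are
conserved exactly — asserted on every generated network. Ensembles are
seeded per member and exclude duplicates of the wild type. The WT
percentile of a metric is 100 × (#null values strictly below WT)/size;
ties count against the wild type.

### Perturbation experiments

Multi-node perturbations flip n of N nodes at once. For coherence-style
summaries, min(100, C(N, n)) distinct n-subsets are used, each relaxed
10 times. Transition ("population") experiments instead give each of 100
simulated cells its own uniformly random n-subset, repeated 10 times per
level, and record per level: mean/sd normalized Hamming distance to the
start state, exact-return coherence, phenotype fractions and mean EMT
score (classification per cell, then averaged). The mean-Hamming curve
h(p) over perturbation fractions p is fit by least squares to a Hill
form h₀ + A pⁿ/(p50ⁿ + pⁿ) with n ∈ [0.1, 25] and p50 ∈ (0, 1]; the
cooperativity n quantifies how switch-like the transition is. Under
these bounds a strictly linear curve fits best near n ≈ 1.8 (verified by
grid search), so "graded" in practice means n ≲ 2.5 against n ≳ 4 for
team-protected terminal states. The **half-minimum perturbation** is the
smallest p where coherence drops below 0.5, linearly interpolated;
curves never crossing 0.5 return 1.0 with a censoring flag. Low/medium/
high perturbation regions for phenotype AUCs are the fractions where the
fitted Hill curve passes 10% and 90% of its amplitude (fixed terciles as
fallback); AUCs are trapezoidal integrals normalized by region width.

### Greedy edge deletion

At each step every remaining edge is tentatively removed, teams are
re-detected on the reduced network, and the edge whose removal minimizes
Ts is deleted (ties broken by lowest row-major edge index). Teams are
re-clustered after every deletion because the partition may reshuffle as
the team structure erodes.

## Synthetic study system

The generator plants the architecture shared by curated EMP circuits:
two core teams with activating within-team and inhibiting cross-team
edges, plus peripheral signal (in-degree 0) and output (out-degree 0)
nodes. Defaults mirror the canonical 22-node EMP circuit: core teams of
9 (TF-style names) and 6 (miR-style names), 3 signals, 4 outputs,
p_within = 0.28, p_cross = 0.25, landing ≈80 edges (density ≈0.165, the
upper end of the 5–15% band typical of these circuits). A directed
within-team cycle guarantees core connectivity; each signal activates
one member of one team and inhibits one of the other (curated signals
are microRNAs with few targets); each output is activated by one team
and inhibited by the other, alternating, so outputs report the team axis
the way CDH1/VIM report the E/M axis. Team-discordant output wiring
matters: with same-sign inputs from both teams an output's input ties in
every terminal state, freezing it at its initial value and inflating the
fixed-point count 2^(#outputs)-fold with diluted frequencies. The
`sign_noise` dial flips each placed core edge to the team-discordant
sign with the given probability, degrading team strength continuously;
ladders over noise levels give planted Ts gradients for trend tests.

The seed-0 default network ("study network") has 40 fixed points out of
2^22 ≈ 4.2 M states, terminal cumulative SSF ≈ 0.98 and Ts ≈ 0.90.

What the generator does **not** emulate: curated degree sequences and
hub structure, autoregulatory loops, correlated edge placement, and the
specific hybrid-state repertoire of real EMP circuits. Passing tests
therefore demonstrate that the pipeline reproduces the team-driven
phenomenology on networks with planted team structure, not that any
particular biological network has these properties.

## Numerical and design choices

- One asynchronous "step" is a single-node update attempt; the 1000-step
  cap is ≈45 sweeps at N = 22. All trajectory batches run vectorized in
  lockstep and are bit-reproducible per seed.
- Exhaustive fixed-point enumeration scans all 2^N states in vectorized
  chunks and refuses above N = 25; sampling covers larger networks. On
  networks small enough for both, the sampled support equals the
  enumerated set when every state is used once as an initial condition
  (each fixed point is in its own basin).
- States are hashed as bit patterns; reported state order is
  lexicographic with −1 before +1.
- Unconverged runs are excluded from SSF and phenotype-fraction
  denominators and reported separately.
- Isolated nodes classify as signals (they too cannot revert) with a
  warning; duplicate identical topo edges collapse with a warning;
  contradictory duplicates are errors.
- Scaled defaults (`desk` preset: 10⁴ initial conditions, K = 25,
  50-member ensembles) keep interactive runs and the test suite fast;
  the `paper` preset restores the reference scales (10⁵, K = 100, 500).
  Problem sizes used by the acceptance script: 10⁵ initial conditions
  for the study-network landscape, 500 randomizations for the
  influence-only Ts percentile, 50-member ensembles for simulation-heavy
  batteries (5000 initial conditions, K = 10 each), 12-node systems for
  the 20-network trend ladder and deletion series.

## Known limitations

- Cyclic attractors are not characterized, only counted as unconverged.
- Team detection assumes exactly two teams; k-team generalizations and
  weighted edges are out of scope.
- The absolute influence–correlation distance carries the signal-block
  floor discussed above; comparisons of d across networks are meaningful,
  its absolute magnitude less so.
- Recovery of planted partitions degrades when teams are small (<5
  nodes) or when sign noise exceeds ~0.2 at the edge level, where path
  cancellation erases the block signature itself.
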