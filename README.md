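# boolteams

Teams of nodes in signed Boolean regulatory networks: attractor
landscapes, influence matrices, team strength, and phenotypic stability.

## The problem

Regulatory networks driving cell-fate decisions — epithelial–mesenchymal
plasticity (EMP) being the canonical example — are large and densely
interlocked, yet cells reliably settle into only a handful of phenotypes
(canalization). A recurring topological explanation is the presence of
two **teams** of core nodes: members of a team activate each other
(directly or through paths), while members of different teams inhibit
each other, collapsing the whole network into an effective toggle switch
between two composite players. Strong teams stabilize the two team-pure
("terminal", e.g. epithelial and mesenchymal) phenotypes and starve the
intermediate (hybrid) ones, producing a bimodal stability landscape.

`boolteams` is a complete, reproducible pipeline for quantifying this:
it is written for systems-biology modellers working with signed
transcriptional/post-transcriptional circuits in the whitespace-delimited
"topo" edge-list format (`Source Target Type`, 1 = activation,
2 = inhibition).

## The model and the statistics

Dynamics are asynchronous threshold-Boolean: node activities are spins
sᵢ ∈ {−1, +1}, and one random node per step is updated by a majority
rule sᵢ ← sign(Σⱼ Adjⱼᵢ sⱼ) with ties keeping the current value, until a
fixed point (steady state) or a 1000-step cap. Per steady state the
pipeline measures

- **SSF** — steady-state frequency, the fraction of random initial
  conditions converging to the state (global stability / basin size);
- **coherence** — probability that a single-node flip-and-relax returns
  the state exactly (local stability);
- **frustration** — fraction of edges with Adjᵢⱼsᵢsⱼ < 0 (topological
  support of the state, Ising-style);

and per network

- the **influence matrix** Infl = (1/lmax) Σ_{l≤lmax} Adj^l ⊘ |Adj|^l
  (path-weighted signed reachability, entries in [−1, 1]);
- the two **teams** (hierarchical clustering of the core influence
  block) and **team strength** Ts = Σ_{k,l} |T_kl| / 4, the mean
  absolute value of the four team-block means of Infl;
- Sarle's **bimodality coefficient** of the stability metrics
  (> 0.55 ⇒ bimodal landscape);
- WT **percentiles** of all metrics against degree- and
  sign-count-preserving edge-sign-swap null ensembles;
- multi-node perturbation **transition curves** (Hamming distance,
  phenotype fractions, Hill cooperativity n) and greedy
  team-strength-minimizing **edge deletion** series.

A built-in generator plants synthetic two-team networks with tunable
team sizes, densities and sign noise, emulating the curated EMP circuits
(two teams + signal/output peripherals at 5–15% edge density), so the
whole pipeline is testable without any curated inputs. See
`docs/methods.md` for the full model description and design choices.

## Worked example

Ready-made inputs live in `examples/` (`toggle.topo`,
`toggle_self.topo`, `two_team_4n.topo`, `emp_like_12n.topo`,
`emp_like_22n.topo` — all synthetic, regenerable via `boolteams synth`).
Generate the default 22-node EMP-like network (9 TF-style + 6 miR-style
core nodes, 3 signals, 4 outputs) and analyse it:

```
$ boolteams synth -o emp.topo --seed 0
wrote 22N 80E network to emp.topo (density 0.165)

$ boolteams teams emp.topo --seed 1
team strength Ts = 0.905; influence-correlation distance d = 0.1587
  epithelial: miRsyn2, miRsyn3, miRsyn4, miRsyn5, miRsyn1, miRsyn6
  mesenchymal: TF1, TF2, TF3, TF4, TF5, TF6, TF8, TF7, TF9

$ boolteams landscape emp.topo --seed 1
40 steady states; terminal cumulative SSF 0.985
                 state    ssf  coherence  frustration phenotype  emt_score
1111000001111101001101 0.0839   0.863636       0.0000         M   1.000000
0000111110000010110010 0.0833   0.863636       0.0000         E  -1.000000
0000111110000010110000 0.0744   0.863636       0.0250         E  -1.000000
...
```

Reading the numbers: clustering the influence matrix splits the 15 core
nodes into the two planted teams (the miR-named team is labeled
epithelial) with team strength 0.905 — a nearly perfect two-team
structure. The dynamics funnel all 2²² ≈ 4.2 million states into 40
steady states, and the team-pure E and M states carry 98.5% of the
steady-state frequency: a strongly bimodal landscape. Each row of the
table is one steady state (bitstring over node order, 1 = active); the
top states are exactly the terminal phenotypes — highest SSF, highest
coherence (0.86 ≈ the ceiling of 19/22 imposed by the three
never-reverting signal nodes), lowest frustration, EMT score ±1.

Other subcommands: `compare` (WT percentiles vs a null ensemble),
`perturb` (transition profiles and Hill fits per steady state),
`deletions` (greedy edge-deletion series). All accept `--preset
desk|paper` to switch between scaled-down and reference simulation
sizes, write tidy CSV/JSON with `-o`, and are fully seeded.

The same analyses are available as library functions
(`boolteams.sample_steady_states`, `influence_matrix`, `detect_teams`,
`transition_profile`, `generate_ensemble`, ...) operating on
`RegulatoryNetwork` objects.

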