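# Methods

## Dynamical model

The model is a deterministic synchronous Boolean network.  Each node `i`
carries a binary activity `x_i`; one update step evaluates, for every node
simultaneously,

    s_i = Σ_j w_ji x_j + b_i,      x_i' = 1 (s_i > 0), 0 (s_i < 0), x_i (s_i = 0)

with signed-integer link weights `w_ji` and basal levels `b_i`.  The
weighted-sum form is equivalent to a logic table per node; integer
parameters are kept minimal.  A zero sum *holds* the previous value.  This
tie rule is a convention, not a biological claim, so the package ships a
tie audit (`netdyn audit`, `network.tie_audit`) that enumerates every
regulator combination of every node; the bundled reference network is
tie-free, which makes the convention inert there.  Random test networks
are not tie-audited — for them the hold rule is part of the defined
dynamics, and both landscape solvers and the naive oracle implement it
identically.

Perturbations are clamps: a genotype status A/I forces a node to constant
1/0, a targeted drug forces its target node to 0, the MDM2→p53 link
inhibitor removes that single edge from p53's input sum, and the
DNA-damage input node is held at 1 under etoposide and 0 otherwise for the
whole simulation (sustained damage).  When drug and genotype clamp the
same node, the drug wins: inhibitors must be able to silence a
constitutively active oncoprotein.

## Reference p53 network

The 16-node reference config (`src/netdyn/data/p53_network.yaml`) is a
reconstruction assembled from the standard biology of the p53
DNA-damage-response circuit: DNAdamage → ATM → CHK2 → p53; negative
feedback through MDM2 (destabilizes p53; inhibited by p14ARF and ATM,
stabilized by AKT) and through Wip1 (p53-induced, silences ATM) — the
source of pulsatile p53 dynamics under damage; the arrest arm p53 → p21;
the proliferation axis Rb ⊣ E2F1 → Cyclin E with p21 ⊣ Cyclin E and
E2F1 → p14ARF; and the death arm p53 → PTEN ⊣ AKT, p53 → BAX ⊣⊣ BCL2
(AKT-supported), BAX → caspase.  Weights and basal levels are the smallest
integers realizing those logic tables tie-freely.  Phenotype markers are
proliferation = CyclinE, arrest = p21, death = caspase.

The reconstruction reproduces the qualitative clinic of the circuit:
undamaged cells proliferate; etoposide alone produces oscillatory
p53/p21 (arrest); sustained p53 — reachable by combining damage with Wip1
inhibition, or in genotypes that disable the feedbacks — activates
PTEN/BAX/caspase (death); AKT- or BCL2-activated genotypes resist the
death arm.  Because the published per-node logic tables of the original
model are network-file parameters here, any user can substitute their own
tables: every analysis is parameterized by the YAML config.

## Attractor landscape

For a clamped network the free (unclamped) nodes define a state space of
2^f states; initial states enumerate exactly this space (clamped nodes are
fixed, carrying no dynamical information), so basin sizes always sum to
2^f.  Two exact solvers are implemented and cross-checked: a vectorized
solver that builds the full one-step transition array with numpy and
composes it with itself f times (pointer doubling) so every state lands on
its attractor cycle, and a memoized per-state trajectory walk in plain
Python with linear total work.  The vectorized solver is the default (the
screens below need thousands of landscapes); the walk and a naive
per-state oracle guard its correctness in the test suite.  Attractor
identity is canonicalized by the smallest integer-encoded cycle state.

Phenotypes: death requires the death marker ON in *every* cycle state;
otherwise arrest accepts the arrest marker ON in *any* cycle state
(oscillatory p21 counts as arrest); otherwise proliferation requires the
proliferation marker ON throughout; anything else is unclassified (U).
U mass is never silently folded into another phenotype — it is reported
explicitly and a warning fires once per run.  The reference network
produces no U under the standard screen with one systematic exception:
clamping Cyclin E (drug C) without DNA damage yields a quiescent state
with every marker off.  Screen-level code therefore reports "U" as the
major response for an all-U landscape, while the strict
`major_phenotype` raises, preserving the contract that P/A/D majorities
are argmax with ties broken D > A > P.

## Screens and scores

The full screen is 32 conditions: untreated, etoposide (E) alone, the five
targets A/B/C/W/N singly and in the 10 unordered pairs, each with and
without E.  The validation screen restricts to targets {B, W, N}: E alone
plus 3 singles, 3 pairs, and their E-combinations — 13 conditions.
Treatment labels are "E"-prefixed with letters in alphabetical order
(`E_N_W`).

R score = P·1 + A·2 + D·4 over basin ratios (weights 2⁰/2¹/2²,
configurable but ordered).  D score normalizes the R-score change by the
largest achievable change; its baseline is the untreated network with the
*same* etoposide status as the treatment, so the score isolates the
targeted drug's contribution rather than the DNA-damage response — the
same convention used for the critical-target comparison.  Effective
targets are conditions with D score > 0.5 whose major phenotype is death,
partitioned by whether the drugged nodes are altered, wild-type, or mixed
in the DWN.

S score uses the Bliss-independence expectation; the two algebraically
identical printed forms are both evaluated and asserted to agree.  For the
synergy screen, D_A, D_B, D_AB are the death basin ratios of single and
combined treatments on the same DWN with the same etoposide setting, and
z-scores are computed over the pooled set of all (DWN × pair × etoposide)
S scores in a run with the sample (n−1) standard deviation; |z| > 1.645
(the 5th/95th standard-normal percentiles) marks significant
synergy/antagonism.

Critical determinants are found by enumerating subsets of the DWN's
alterations in increasing size (≤ 2^k landscapes for k alterations, k ≤ 5
in practice) and keeping inclusion-minimal subsets that reproduce the
cancer network's major phenotype under the treatment, given that it
differs from the normal network's; minimality is brute-force audited in
the tests.  Response groups are the triples (major phenotype, critical
target present, critical determinant present) with a fixed 1–12 index;
group numbering is this package's own deterministic enumeration.

## Genomics mapping

Functional-alteration filtering keeps truncating mutations (nonsense,
frameshift) as inactivating; missense with high/medium functional impact
as activating on oncogenes and inactivating on tumor suppressors
(role-less functional missense is dropped with a warning, never guessed);
and copy-number calls only when concordant with expression (GAIN/AMP with
mRNA z ≥ +t, HOMDEL/LOSS with z ≤ −t; default t = 1, configurable — the
concordance criterion is a design choice surfaced in config and logs).
Silent/RNA/intron/UTR/flank/intergenic variants and DIPLOID or discordant
copy-number calls are excluded.  Functional-impact categories are consumed
as an input column, not recomputed.

Projection maps calls through a node → gene-set table to ternary node
statuses (A/I/N); mutation evidence outranks copy-number evidence on the
same node, and a mutation-level A/I conflict is a hard error.  Identical
profiles deduplicate into DWNs named `DWN_<k>_<i>` with k the alteration
count and i the 1-based lexicographic rank of the profile signature within
its k (the index assignment is deterministic but package-specific).
Topology subgroups follow the two marker rules — p14ARF inactivated →
subgroup 1, else AKT activated → subgroup 3, else 2 — which the tests show
do *not* predict response groups: dynamics, not topology, stratify.

## Validation statistics

Per cell line, RMSE = sqrt(mean((O_i − P_i)²)) over the 13 validation
conditions and Pearson r (scipy) compare observed and predicted death
fractions.  The null ensemble enumerates *all* profiles with the same
alteration count — locations and signs both randomized — giving
C(16,k)·2ᵏ networks (480 / 4480 for k = 2 / 3); the null RMSE is the mean
over networks of per-network RMSE (not the RMSE of the mean prediction).
The enumeration necessarily includes alterations on the DNA-damage input
node; when such a profile is simulated, the genotype clamp on the input
overrides the etoposide setting.  Model-vs-null error samples are compared
with the two-sided Wilcoxon rank-sum test (exact for small tie-free
samples, normal approximation with tie correction otherwise; identical
samples return p = 1).

## Synthetic fixtures

All inputs are generated in-package, bit-reproducibly under a seed.  The
genomics generator plants known functional alterations realized through a
random admissible evidence type plus decoys from every excluded class, so
the filter can be plant-and-recover tested.  The DWN panel generator draws
45 distinct profiles with 1–4 alterations (never on the input node) —
the panel scale of the reference study.  Observed responses are predicted
death ratios plus additive Gaussian noise clipped to [0, 1] with sd 0.05;
this crude error model exercises the validation statistics and does not
emulate imaging artifacts, dose–response saturation, or tissue-of-origin
structure, so passing recovery tests demonstrate statistical machinery,
not biological realism.

The parameter-recovery experiment uses a fixed true genotype
{Wip1: A, p14ARF: I} — two canonical p53-pathway alterations (PPM1D
amplification, CDKN2A/ARF loss) whose death-response signature over the
validation screen is informative; recovery is only meaningful for
genotypes that leave a signature in the observable death readout, since a
genotype predicting zero death everywhere is unidentifiable against the
null by construction.

## Problem sizes and numerical choices

Landscapes of the 16-node reference network (2^15 states with the input
clamped) take a few milliseconds via the vectorized solver; the test suite
runs the full 45-DWN × 32-treatment screen, the 480-network null with 13
conditions each, and a 100-replicate recovery experiment in well under a
minute combined.  Oracle cross-checks use random networks of 4–10 nodes
where the naive per-state oracle is affordable.  Exact enumeration refuses
networks with more than 24 free nodes (configurable) with an explicit
resource error rather than silent truncation.  Basin-ratio sums are
asserted to 1 within 1e-12; score identities to 1e-12; z-score
standardization to 1e-9.

## Known limitations

- The reference network is a reconstruction: per-node logic equals the
  standard published biology of the circuit, not any specific supplementary
  table; quantitative basin ratios depend on the exact logic, so
  instance-level agreement with any particular study's numbers is not
  claimed — swap in your own network file for that.
- Cancers with mutant p53 are out of scope: the model assumes the p53
  signaling core is intact and alterations act on its regulators.
- Boolean discretization cannot distinguish weak from strong activation or
  partial drug inhibition; asynchronous/probabilistic updating, ODE
  dynamics and multi-valued logic are out of scope.
- Synergy uses the Bliss model only; Loewe/dose–response models are not
  implemented.
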