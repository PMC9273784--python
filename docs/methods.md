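# Methods

`dimerlens` analyses coarse-grained (Calpha-trace) ensembles of
alpha-synuclein dimers: two 140-residue chains per snapshot, one
conformation per frame. This note records the definitions the package
implements, the numerical choices behind them, and what the synthetic
generator does and does not emulate.

## Contact and dimer definitions

A *contact* is a pair of Calpha atoms of different residues at a
distance strictly below 6 Å. Counting contacts of a two-chain snapshot
gives `n_inter` (interchain pairs) and `n_intra` (intrachain pairs,
pooled over both chains). By default intrachain pairs only need a
sequence separation of 1 — the literal "different residues" rule, which
includes bonded neighbours; `min_seq_sep=3` is available when
sheet-focused maps are wanted, and both modes are exposed everywhere the
cutoff is.

A snapshot is a *dimer* when more than 10 residue pairs have an
interchain Calpha distance below 5 Å (so the minimum close-pair count of
a dimer is 11). The 5 Å value is the in-register Calpha spacing of
fibril beta-sheets (≈4.8 Å) plus slack. Note the two cutoffs are
independent parameters: contact statistics use 6 Å, dimer membership
uses 5 Å.

## Effective free-energy landscapes

Order-parameter pairs (e.g. `(n_inter, n_intra)` or helix/sheet counts
`(alpha, beta)`) are histogrammed — 5-count bins for contact landscapes,
integer bins for secondary-structure counts — and converted to a
dimensionless effective free energy `F = -ln(P/Pmax)` (kT units). Empty
bins carry `F = +inf`; the most probable bin has `F = 0` by
construction, and differences between local minima are reported as
`-ln(Pi/P1)`.

For minimum detection the probability is first smoothed with a 3×3
*binomial* kernel (centre weight 1/4). A uniform 3×3 kernel — the more
common default — maps an isolated peak onto a 9-cell plateau in which no
cell is strictly below its neighbours, so the strict 8-neighbour minimum
rule would miss exactly the sharp minima it should find; the
centre-weighted kernel suppresses single-bin noise while preserving
strict extrema. Minima are reported when within 1 kT of the global
minimum (configurable), sorted by depth, ties broken lexicographically
on the bin centre.

## Secondary structure from the Calpha trace

Helices and strands are assigned from two pseudo-internal coordinates
per residue: the bond angle `theta_i` of the triplet `(i-1, i, i+1)` and
the signed dihedral `tau_i` of the quadruplet `(i-1, i, i+1, i+2)`.
An ideal alpha-helix trace (radius 2.3 Å, rise 1.5 Å/residue,
100°/residue) gives `theta ≈ 90.4°`, `tau ≈ +50.0°`; an extended
zig-zag with 3.8 Å virtual bonds gives `theta ≈ 120.6°`, `tau ≈ 180°`.
The windows calibrated on these ideals are

| element | theta | tau |
|---|---|---|
| helix candidate | 80–105° | +30 to +70° |
| strand candidate | 100–155° | \|tau\| ≥ 140° |

A maximal run of candidates `[a, b]` involves residues `a-1` through
`b+2`, and that full span is labelled. A single helix candidate
therefore yields a 4-residue helix — the minimum helix size — and a
3-residue helical stretch yields no candidate at all. Strand spans only
become sheet residues (`E`) through pairing: two extended residues on
any chains pair when closer than 5.5 Å, and a pairing is kept only if it
propagates over at least 2 consecutive residues with fixed register
(+1 = parallel, −1 = antiparallel), i.e. a sheet cannot be smaller than
two 2-residue strands. Intrachain pairs additionally require a sequence
separation of 5 — anything closer is within 5.5 Å on any trace, and 5
still admits the tightest hairpin the geometry allows. Pairs are tagged
intra/inter and parallel/antiparallel; a residue bridging two sheets
keeps all its pairs but counts once per orientation in the Table-style
percentages.

Helix/sheet state statistics (`alpha`, `beta` counts, B/HB split,
cumulative density-of-states curves) are computed over residues 1–95
(N-terminal 1–60 + NAC 61–95; the C-terminal 96–140 contributes no
variant-discriminating structure). State B is `alpha = 0`; the DOS
reference probability is the maximum on the `alpha = 0` axis, so the
curve is undefined (and raises) for ensembles with no helix-free
snapshot.

## Native fibril contacts and pre-fibrillar dimers

A *native fibril contact* (Nfc) is an interchain contact between
residues of the same sequence index at a distance strictly below 5 Å —
the geometry of in-register parallel fibril sheets. A dimer is
pre-fibrillar (*Dfncs*) when it carries at least 5 strictly consecutive
(gapless) Nfcs. Per-residue Nfc probabilities and the globally longest
run (with its snapshot) summarise an ensemble.

The AFM-style contour length of the stretchable tails is
`L = 2 (140 - r + 1) × 3.8 Å`, with `r` the first Nfc residue — twice
the C-terminal-to-interface backbone length — reported to the nearest Å
(e.g. r = 94 → 357 Å).

Fibril reference structures (multi-chain stacks) are handled by sorting
chains along the principal axis of their centroids, pairing neighbours,
and averaging same-index distances over residues that the trace
assignment marks as interchain sheet in both partners. Multi-model
references use model 1 (configurable): a fibril entry is treated as one
geometry.

## Observables

*Radius of gyration* is the unweighted RMS Calpha distance from the
Calpha centroid, for a single chain or the pooled dimer (both are
emitted; the dimer value is what a SAXS experiment on dimers would see).
Chain-level Rg samples are decomposed with Gaussian mixtures
(scikit-learn EM, 10 seeded restarts, component count 1–4 chosen by
BIC).

*FRET proxy*: the dye-to-dye distance is the residue-90 interchain
Calpha distance plus a 20 Å offset (twice the dye-centre-to-Calpha
distance; 7.5 and 15 Å variants are parameters), and
`E = 1/[1 + (d/R0)^6]` with `R0 = 60 Å`. This deliberately ignores dye
photophysics and orientation factors; it is exactly the stated
approximation, nothing more. `E = 0.5` at a Calpha distance of
`R0 - offset = 40 Å`; the 3.8 Å Nfc distance gives `E ≈ 0.996`.

*Chou–Fasman profile*: the 1978 beta-sheet conformational parameters,
averaged over a 15-residue window with weights falling linearly from 1.0
at the centre to 0.10 at the edges, normalised by the weight sum
(termini use truncated windows). On the wild-type sequence the profile
has local maxima at residues 39, 52, 71 and 94.

*Population partition*: with dimer fraction `p` (of conformers) and
pre-fibrillar share `q` (of dimers), `n` chains split as
`C = n/(1+p)` conformers, `round(pC)` dimers of which `round(qpC)` are
pre-fibrillar, and the rest free monomers (round = half-up). For 123
chains at `p = 0.23, q = 0.1404`: 20 disordered dimers, 3 pre-fibrillar,
77 free.

## The synthetic generator

Real dimer trajectories from millisecond-scale coarse-grained sampling
are not redistributable, so every stage is validated on generated
ensembles with exact ground truth. One snapshot is built from:

* ideal helix / strand segments (parametrised as above) planted at
  requested positions, connected by self-avoiding random-coil walks with
  3.8 Å bonds and a 4.0 Å non-bonded floor;
* a planted interchain sheet interface: chain B's paired residues are
  superposed rigidly onto chain A's interface translated 4.8 Å along the
  strand-plane normal, so paired distances equal the spacing exactly;
  in-register, register-shifted and antiparallel variants are supported.
  Interface-carrying chains grow their bulk into the half-space away
  from the partner (with a zig-zag phase flip selecting the side), and
  placements with any non-interface interchain distance ≤ 6 Å are
  rejected and resampled;
* a snapshot mixture: exactly `round(n·dimer_fraction)` dimers of which
  `round(·dfncs_fraction)` carry the in-register (Nfc) interface;
  disordered dimers use a register-shifted interface (≥11 close pairs
  but zero same-index contacts); monomers are placed ≥ 25 Å apart.

Two consistency mechanisms make planted labels exact rather than
statistical: coil steps that would complete a helix-window `(theta,
tau)` quadruplet are rejected during growth (checked in both growth
directions), and a finished chain is rebuilt if any helix candidate
appears outside a planted helix interior. Consequently the B/HB split,
dimer counts and Dfncs counts on generated data match ground truth
exactly, and planted helix/strand recovery is complete up to one
junction residue at segment boundaries.

Per-chain Rg follows a configurable Gaussian mixture (default: the
two-component wild-type dimer clustering, 0.6·N(33.5, 2.5²) +
0.4·N(42.2, 2.5²) Å; component standard deviations are a package choice
— only the component means and weights are constrained by the
emulated conditions; the 2.5 A widths are a package choice). The
drawn target is realised by a per-step growth bias: each coil step picks
the feasible candidate whose partial Rg best tracks
`target·(k/n)^0.55`. Bond lengths stay exactly 3.8 Å and coordinates
are never rescaled (trace-scale geometry is what the structure
assignment reads); realised chain Rg lands within ~0.1 Å of the target.
A fixed centripetal/centrifugal bias (`compactness`) is also available.

What the generator does *not* emulate: thermodynamically weighted
sampling (snapshots are independent, not a trajectory), force-field
energetics, side chains, sequence-dependent contact propensities, and
partially formed / frayed interfaces (planted sheets are ideal).
Passing tests therefore demonstrate that the *measurement* pipeline is
correct and exactly recovers known structure; they do not validate
claims about real alpha-synuclein ensembles.

## Numerical choices and degenerate inputs

* All cutoffs are strict inequalities (a pair at exactly 5.0 Å is not an
  Nfc; 6.0 Å is not a contact).
* Undefined pseudo-angles (chain termini, near-collinear triplets)
  become NaN flags, never exceptions; chains shorter than 4 residues are
  rejected for assignment.
* Landscape minima ties break lexicographically on bin centre;
  the longest-Nfc-run tie breaks on the first snapshot.
* Seeds: every stochastic component takes an integer seed and threads
  it through `numpy.random.default_rng` sequences; identically seeded
  pipeline runs are byte-identical (manifests record relative paths for
  this reason).
* Problem sizes: generator-based tests use 5–2000 snapshots (the
  mixture-recovery check uses 2000 chains ×2, the count checks 20–100);
  the acceptance script analyses a 400-snapshot ensemble under the
  wild-type study conditions.

## Known limitations

* The assignment thresholds are calibrated on ideal geometry, not
  transcribed from the original curvature/torsion implementation; on
  thermalised (noisy) traces the recovery rates will be lower than the
  ideal-geometry guarantees.
* A 3-residue helical turn and isolated beta-bridges are invisible by
  construction (minimum sizes 4 and 2+2).
* `fibril_reference_sheets` assumes a single-filament stack whose
  stacking order is resolved by the centroid principal axis; interleaved
  two-protofilament packings would need chain pre-selection.
* The FRET proxy uses one fixed `R0` and a rigid dye offset; measured
  efficiency histograms additionally convolve dye dynamics, shot noise
  and burst selection.
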