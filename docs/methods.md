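# Methods

This note records the models, conventions and deliberate design choices
behind astatools, and what the synthetic-fixture tests do and do not
demonstrate about real data.

## Structures and conventions

Coordinates are Å throughout; residue numbers are author numbers taken
verbatim from the PDB file (so the FAS1 tunnel positions quoted in reports
are directly comparable with published numbering). Alternate locations are
resolved to the highest-occupancy conformer, ties broken by file order — a
deterministic rule that never mixes conformers. Hydrogens are parsed but
excluded by default from SASA, clash and Debye computations: NMR ensembles
carry protons while predicted and crystallographic models usually do not,
and the heavy-atom convention keeps results comparable across model
sources. An `include_hydrogens` flag restores them; contact calls sitting
near the 10 Å² cutoff are the quantity most likely to move when it is used.
The van der Waals radii are an explicit Bondi-style table shipped in
`tables.py`; an element missing from the table is an error unless the
caller supplies a default, never a silent substitution.

## Solvent-accessible surface area and ΔSASA contacts

SASA uses the Shrake–Rupley construction with a deterministic golden-angle
(Fibonacci) spiral of test points, default 960 per atom, probe 1.4 Å. A
deterministic lattice was chosen over random sampling so that results are
bit-reproducible and a brute-force point-by-point oracle can check the
neighbour-search implementation exactly (the KD-tree pruning must not
change a single point decision, and the tests assert that on ≤50-atom
instances). The isolated-atom area is exact by construction; lattice
convergence is better than 1% at 960 points.

ΔSASA treats the ligand as a pure occluder: the protein's per-residue area
is computed alone and again with the ligand atoms shadowing the lattice but
contributing no area of their own. Negative differences can only arise from
floating-point noise and are clamped to zero. A residue is a contact when
its ensemble-mean ΔSASA is ≥ 10 Å² (inclusive — the threshold is "at least
10 Å²"). The mean over all ensemble models is the default aggregate; a
single-model mode exists for sensitivity checks. Because the radii set and
SASA implementation behind the originally published contact list are not
specified anywhere, the published 17-residue set should be treated as
reproducible to within a residue or two at the threshold, not bit-exactly.

## Conservation scoring and position classification

The two-group classification needs only conserved/variable calls per
group, so a transparent frequency score replaces phylogeny-aware
conservation grading: for a column, the score is the largest fraction of
non-gap sequences falling in one residue class, where classes are single
residues plus the similarity groups {ILVM}, {FWY}, {KR}, {DE}, {ST}, {NQ},
{AG}. The {N,Q} class is what lets a glutamine column with an asparagine
substitution still count as conserved. Gaps are excluded from the
denominator; an all-gap column scores 0. The conservation threshold
defaults to 0.8 of non-gap sequences and is exposed in the API and CLI
because no canonical value exists. Percent identity excludes columns gapped
in either sequence, matching common practice for domain alignments.
Positions are classified into four exhaustive, mutually exclusive cells
(both conserved / variable in both / group-specific / family-only); the
group-specific cell is the neofunctionalization signature.

## Superposition, ensemble RMSD and clashes

Kabsch superposition is solved by SVD with the determinant forced to +1
(no reflections); collinear or coincident point sets are rejected rather
than silently returning an arbitrary rotation. Motif-anchored alignment
fits only the paired anchor ranges (for FAS1 proteins, the H1/H2 motifs
and the YH dyad; shipped default ranges for AstaP are editable
approximations because the motifs are defined structurally, not by exact
residue bounds) and then transforms the whole mobile structure, reporting
RMSD both on the anchors and on all residues numbered alike in both
structures.

Ensemble precision uses the iterative mean-structure convention: every
model is superposed on the current mean, the mean is recomputed, and the
per-model RMSD to the converged mean is reported as mean ± SD. This is the
convention of the NMR-ensemble tooling ecosystem; a pairwise alternative
would give systematically larger numbers (≈√2 for large ensembles), which
is the main "convention tolerance" when comparing with published tables.

Clash detection reports every protein–ligand atom pair whose distance is
below r_a + r_b − 0.4 Å (the common steric criterion; the tolerance is a
parameter), sorted by overlap. Only the given coordinates are evaluated —
no rotamer sampling — so a reported clash means "this rotamer clashes",
not "every rotamer must".

## SAXS analysis

All internal analysis uses s = 4π sin θ/λ in nm⁻¹; input units are declared
by the caller (`--unit`), never guessed. The Guinier window expands from
the lowest usable angle until s·Rg reaches the limit (default 1.3),
iterating Rg to self-consistency (≤20 iterations, tolerance 1e-4); fits are
weighted by I/σ in log space. On an exact sphere the Guinier
approximation itself biases Rg upward by ~2% at s·Rg ≤ 1.3; closed-form
checks therefore use a tighter window (s·Rg ≤ 0.5–0.6), where the bias is
within 0.5%.

The Porod invariant integrates s²(I−b) with a flat background b fitted
jointly with a K·s⁻⁴ term on the high-angle tail, a Guinier extrapolation
to s = 0, and the analytic K/s_max tail beyond the data. A plateau flag
warns when s⁴(I−b) has not levelled off in the measured range — in that
case V_P (and the Porod mass V_P/1.6) is an upper estimate. The
volume-of-correlation estimator uses the protein calibration
Mw[kDa] = (Vc²/Rg)[nm³]/0.1231.

The dimensionless Kratky transform marks the conventional rigid-sphere
reference point (√3, 3e⁻¹). Note that this point is the maximum of the
Guinier Gaussian; the exact sphere transform peaks slightly lower, at
s·Rg ≈ 1.612 — the tests distinguish the two.

Theoretical curves use the explicit Debye double sum over point scatterers
with atomic-number form factors (models above ~2000 atoms are
coarse-grained to one pseudo-atom per residue at the Cα carrying the
residue's summed electron count; the pair sum switches to a fine distance
histogram, bin width 0.002 nm, above 1500 scatterers, accurate to well
under 1% over the usual s range). No hydration shell or excluded-volume
term is modeled. Consequently absolute χ² values against real,
hydrated-particle data are not comparable with hydration-aware fitting
programs; χ² is used comparatively, for model discrimination, where a
correct model beats a decoy differing by ΔRg > 0.2 nm on curves with
realistic (1–2%) noise. The reduced χ² divides by N−1 with scale and
optional flat offset fitted by weighted least squares, and theory is
interpolated onto the experimental grid linearly in log I.

## Synthetic fixtures: what they show and what they do not

The tunnel generator plants contacts geometrically: rings of three
carbon-radius spheres (radius 4 Å around the rod axis, 4 Å apart) enclose
an eight-atom rod, giving every ring residue ΔSASA ≥ ~16 Å² while all
distant residues sit beyond the occlusion distance and lose exactly
nothing. Ensemble variants add isotropic Gaussian jitter of 0.3 Å, small
enough never to flip a planted call at this geometry. An "open-jaw"
variant rotates the upper half of the rings about a hinge by a known
angle, which gives the superposition tests an exact oracle. These fixtures
prove the bookkeeping and the geometry engines; they say nothing about
chemistry — real side-chain packing produces near-threshold residues that
the synthetic margins deliberately avoid, which is why deposit-based
checks allow ±2 residues at the cutoff.

The MSA generator realizes planted categories by round-robin assignment
over five mutually dissimilar residues (L, K, D, S, F), capping any class
frequency in a "variable" column at ~0.2 — a ≥0.2 margin below the 0.8
threshold at any group size ≥5 — while conserved columns are invariant.
Recovery is therefore exact by construction; real alignments have
intermediate frequencies, gaps and phylogenetic correlation that the score
ignores by design.

Curve generation uses analytic bodies (sphere, Gaussian globule, Debye
polymer chain for the flexible reference) or the package's own Debye sum,
with Gaussian noise σ(s) = fraction·I(s) + floor that is also the stored
uncertainty — which is what makes the χ² ≈ 1 calibration test meaningful.
Default problem sizes (≈400-point curves, 300–4000-atom point clouds,
10–20-model ensembles of ≈40 atoms) were chosen as the smallest instances
on which the statistical assertions are stable; all generators are pure
functions of spec + seed.

## Known limitations

* No mmCIF input, bond perception, or biounit expansion.
* Conservation scoring is frequency-based; it does not down-weight
  phylogenetic redundancy, so dense clades inflate scores.
* No indirect Fourier transform: Dmax and P(r) are out of scope.
* Clash detection tests a single rotamer per side chain.
* Absolute χ² against experimental curves is not comparable with
  hydration-shell fitting programs (see above).
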