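# Methods

This note documents the models, the defaults that matter, the numerical
choices, what the synthetic fixtures do and do not emulate, and the known
limitations. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structure model and PDB I/O

Structures are ordered chains of residues keyed by
`(chain_id, res_seq, insertion_code)`. The PDB reader parses fixed-width
ATOM records, takes elements from columns 77–78 when present and otherwise
infers them from the atom name, assigns van der Waals radii from a packaged
element table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å; configurable), and
resolves alternate locations by keeping the highest-occupancy conformer
(first on tie). HETATM records and waters are skipped by default. The writer
guarantees a lossless round-trip for identifiers and coordinates to the
format's 3-decimal precision. All geometry downstream is defined on heavy
atoms only, since channel homology models generally lack hydrogens.

Residue numbering is taken verbatim from `res_seq`; mutation positions refer
to those numbers. Positions outside the modelled range carry no structural
annotation and are classed `outside_model` in reports.

Rigid superposition (used to assemble a dimer from two copies of a monomer
against a dimeric template) is closed-form least-squares over paired CA
coordinates, delegated to `scipy.spatial.transform.Rotation.align_vectors`,
which returns a proper rotation (det = +1). The returned RMSD is over all
paired points after the transform.

## Solvent accessibility and buriedness

SASA uses the classic test-point construction: `sphere_points` (default 960)
quasi-uniform points on each atom's solvent-expanded sphere
(radius + probe, probe default 1.4 Å); a point is accessible when outside
every other atom's expanded sphere. The point lattice is a deterministic
golden spiral, so results are exactly reproducible run to run and
delta-SASA on complexation is non-negative by construction (adding atoms can
only remove accessible points from a fixed lattice).

Discretization scale: with 960 points, per-atom SASA carries roughly 1–2%
lattice noise (visible when rotating a structure or doubling the point
count); whole-structure totals agree to ~0.3% under rotation. Property
tests assert at this scale; the analytic single-sphere and two-sphere
closed-form checks pass within 1%.

Relative accessibility (RSA) divides residue SASA by a maximal-exposure
reference. The packaged default is the Tien et al. theoretical Gly-X-Gly
set, with the Miller set available by name — the buried/exposed flag, not
the exact RSA value, is what drives downstream logic. Buried means strictly
RSA < 15%. Non-standard residues are reported without RSA rather than
rejected.

## Dimer interface

Two operationalizations of "forms the interface", selectable per call:

- `delta_sasa` (default): residue buried-surface on complexation > 1 Å².
- `distance`: any heavy atom within 4.5 Å of the other chain.

Membership is computed on the full structure; residues in configured
excluded ranges (e.g. regions disordered in a template) are filtered from
the *reported* sets only, so counts are reproducible under different
exclusion configs. `near_interface` (default cutoff 6 Å) classifies
pore-mouth residues that sit against the interface without buried surface of
their own; an interface residue is trivially near.

On the two-helix bundle fixture both methods recover the generator's
designated contact set exactly; in general the two definitions agree on the
large majority of residues but need not coincide at borderline sites, which
is why both are exposed and the method is recorded in the output.

## Ion pathway

The pore finder replaces an interactive tunnel server with a deterministic
grid search. A cubic grid (spacing 0.8 Å, anchored at the structure centroid
so runs are exactly repeatable) is scored by clearance — distance to the
nearest atom surface, evaluated over the 16 nearest atom centers to handle
mixed radii. Nodes with clearance ≤ `probe_min` (default 0.8 Å) are blocked.
Open nodes form a 26-connected graph with edge weight
mean(1/clearance²) × edge length; the cheapest path between the nodes
nearest the two user-supplied seeds is found by Dijkstra
(`scipy.sparse.csgraph`). The 1/clearance² cost pulls the path onto the
channel axis (wide, central regions are cheap); the bottleneck — the
minimum clearance along the path — is reported separately so the maximin
information is preserved. The path is smoothed with a 3-point moving
average and clearances are recomputed at the smoothed points.

Disconnected seeds yield an explicit "no tunnel" result (`found=False`),
not an exception; a seed inside an atom is an error. Seeds must be supplied
(CLI flags or fixture sidecars): for a real channel, sensible choices are
the centroid of the selectivity-filter residues and a point in the
extracellular vestibule. Whether the original analyses used a probe matched
to a chloride ion (1.81 Å) is not recorded anywhere authoritative, so
`probe_min` is configurable.

Pore-lining residues are those with any heavy atom within
(local clearance + cutoff, default 3 Å) of any path sample — the cutoff is
measured from the channel *wall*, not the centerline, so wide vestibules do
not over-collect.

## Side-chain contacts

Hydrogen bonds use a heavy-atom-only criterion because the structures lack
hydrogens: a side-chain N/O of the focus residue within 3.5 Å of any N/O of
another residue, with the angle at the focus atom (covalent antecedent →
focus atom → partner) ≥ 90° to reject geometrically impossible donors.
Aromatic contacts pair ring centroids within 7 Å whose plane normals are
within 60° of parallel (after sign-folding this covers both stacked and
tilted-T arrangements); His counts as aromatic.

A wild-type contact is *lost* under a substitution when the mutant residue
type has no side-chain atom of the focus atom's name (atom-template rule);
an aromatic contact is lost when the mutant is not aromatic. Chemically
similar substitutions (Glu/Asp, Gln/Asn, acid/amide, Tyr/Phe) are annotated
"possibly preserved" since a shorter or isosteric side chain may remake an
equivalent interaction. Steric-clash scoring is deliberately out of scope:
no usable criterion is recorded for it and guessing one would be arbitrary.

## Mutation-impact classification

Three residue-level properties, all from a packaged table:

- **ΔVolume**: Zamyatnin residue volumes (Gly 60.1 … Trp 227.8 Å³);
  |ΔV| ≥ 30 Å³ is destabilizing, boundary inclusive. Tabular output rounds
  half-away-from-zero (so +30.2 prints as +30), full precision internally.
- **Charge**: three classes — negative {Asp, Glu}, positive {Arg, Lys,
  His}, neutral otherwise; a change is any class change. The three-class
  form (rather than literal charged-vs-uncharged) is required to reproduce
  the published flags, e.g. Tyr→His = Yes.
- **Polarity**: the three-way partition nonpolar {Leu, Ile, Phe, Trp, Cys,
  Met, Val} / polar {Tyr, Pro, Ala, Thr, Gly, Ser} / very polar {His, Arg,
  Gln, Lys, Asn, Glu, Asp}; a change is any class change.

The per-mutation report composes these with buriedness, localization
(precedence: outside_model → interface → pore → near_interface →
buried_other → surface) and lost contacts. ΔV/charge/polarity are computed
for every position — including exposed ones, which are merely flagged,
since the buried-residue rationale (buried substitutions are likelier to
destabilize) is a heuristic, not a validity condition.

The packaged transcription of the published mutation tables carries 21 rows
with a printed ΔV/charge/polarity triple. The implementation reproduces 18;
the other three are asserted in tests as documented divergences — probable
errata in the source: a ΔV printed as −35 where His−Tyr is −40 under any
standard volume set, a ΔV printed +23 where Val−Met is −23 (sign slip), and
a charge flag printed Yes for a neutral→neutral substitution.

## Cohort statistics

Variant strings follow a deliberately small HGVS-like grammar:
substitutions `c.N[+/-M]X>Y`, deletions `c.N_Mdel[XX]`/`c.NdelX`, delins
`c.N_MdelinsXX`; protein strings classify the variant (`fs` → frameshift,
`*`/`Ter` → nonsense, Xxx→Yyy → missense) with intronic cDNA offsets →
splice. A hyphen between two coordinates is a range separator only when the
span exceeds 100 (else an intronic offset) — this resolves an inconsistent
spelling of one large deletion in the source table. Inversions, extensions
and genomic liftover are out of scope.

Allele counting: each proband contributes two disease alleles, except
probands with a single detected variant, who contribute one (the second
allele is unresolved — it may carry an undetected mutation). Cis variants
share one allele; homozygotes count twice. This convention uniquely
reproduces all three published frequencies from the packaged 51-proband
table (38/96 = 39.6%, 18/96 = 18.8%, 6/96 = 6.25% ≈ 6%). Percentages are
rounded half-away-from-zero to one decimal. Three-variant probands without
recorded phase default to the two most-5′ variants in cis, with a warning
(two probands in the packaged table).

Novel-mutation summaries count distinct mutation *types* (by cDNA string),
split truncating/splice (frameshift, splice, nonsense, large deletion)
versus missense. The distinct-type count over the packaged table is 35 by
raw counting; the source abstract says 34 without stating its merging rule,
so the summary reports the raw count and this note.

## Synthetic fixtures — what they do and do not show

All generators are seed-deterministic (byte-identical re-runs) and emit a
ground-truth sidecar sufficient for the downstream test:

- **Sphere sets**: carbon pseudo-atoms with closed-form SASA (isolated
  sphere, two-sphere spherical-cap lens). Exact for pairwise overlaps
  without triple intersections.
- **Bundle dimer**: two poly-Ala helices (rise 1.5 Å/residue, 120°/residue
  twist, i.e. a 3-residue repeat) facing each other across a configurable
  CB–CB gap (default 4 Å). The 120° twist makes the contact faces z-aligned
  between chains, so every third residue touches at exactly the gap and all
  others point away (> 7 Å); the designated contact set (CB within
  min(gap+2, 6) Å of the other chain, computed from raw coordinates) is
  then recovered exactly by both interface methods. A 100°/residue α-helical
  twist staggers the faces and leaves borderline residues at 4.6–6.2 Å on
  which the two interface definitions legitimately disagree — crisp ground
  truth requires the aligned geometry.
- **Barrel**: stacked 16-atom carbon rings (one residue per ring) forming a
  cylinder; analytic axial clearance = inner radius − r_C, optional
  constricted ring. Bottleneck, axis position and wall-residue recovery are
  tested against these values.
- **Contact micro-fixtures**: a Glu carboxylate hydrogen-bonding a backbone
  amide at exact distance/angle; parallel Phe rings at exact centroid
  separation.
- **Cohorts**: multinomial assignment over a configurable mutation pool
  with cis-pair, homozygote and single-variant fractions; exact expected
  counts tallied during generation.

These fixtures validate the geometry kernels and the counting rules, not
biological realism: poly-Ala helices have no rotamers or packing detail, the
barrel is not a protein fold, and the synthetic cohorts have no linkage or
phenotype structure. Passing tests therefore demonstrate correctness of the
*operations*, and say nothing about the quality of any particular homology
model the operations may be applied to. In particular, published
model-specific outputs (a 40-residue interface list, a 43-residue pathway
list, per-residue RSA values) depend on an unreleased homology model and are
not regression targets; the fixture-based suites stand in for them.

## Numerical choices and degenerate inputs

- Rounding of printed values is half-away-from-zero everywhere.
- SASA test points exactly on a neighbouring expanded sphere count as
  occluded (boundary of measure zero; only relevant for constructed ties).
- Superposition requires ≥ 3 non-collinear point pairs; collinear input is
  rejected rather than silently returning one of the degenerate optima.
- The pore grid covers the structure's bounding box plus the seeds with a
  2-node margin; seeds more than 5 Å outside the box are rejected.
- Empty structures, single-chain "dimers", unknown residues/elements and
  contradictory phase strings raise informative errors; Gly contact focus
  and incomplete aromatic rings degrade to warnings.

## Problem sizes

The test suite and acceptance script run on fixtures of 100–260 atoms
(bundle, barrel), 50-atom random clusters for the SASA cross-check, and the
51-proband cohort table; the full suite completes in well under a minute on
one CPU and the acceptance script in seconds.

## Known limitations

- mmCIF, NMR ensembles and ligand objects are not parsed; superimposed ion
  positions are handled as plain coordinate triples.
- Single-tunnel search only; no physico-chemical tunnel profiling.
- No ΔΔG prediction, secondary-structure assignment, clash scoring,
  shape-complementarity index or splice-site scoring.
- The H-bond criterion is heavy-atom geometric; without hydrogens,
  donor/acceptor roles are not disambiguated.
- Nearest-surface clearance is approximated over the 16 nearest atom
  centers; exact for uniform radii, and within the radius spread otherwise.
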