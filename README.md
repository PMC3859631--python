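# poremut

Structural and cohort-level analysis of missense mutations in dimeric ion
channels, built around the skeletal-muscle chloride channel ClC-1 and the
variant spectrum of myotonia congenita.

ClC-1 is a homodimer with one chloride pore per subunit. Whether a missense
mutation behaves dominantly or recessively tracks, to a first approximation,
with where it sits: substitutions at the dimer interface tend to impair the
wild-type partner subunit (a dominant-negative effect), while substitutions
lining the Cl⁻ pathway tend to spoil only the mutant subunit. `poremut`
implements the in-silico toolchain for asking that question of any dimeric
channel structure in PDB format, plus the allele-level bookkeeping for the
matching patient cohort.

## What it computes

**Structure side** (modules `structure`, `surface`, `interface`, `pore`,
`contacts`, `impact`):

- solvent-accessible surface area (Shrake–Rupley test points on a
  deterministic golden-spiral lattice), relative accessibility against a
  Gly-X-Gly reference, and the buriedness rule RSA < 15%;
- dimer-interface residues, by buried surface on complexation
  (ΔSASA > 1 Å²) or cross-chain proximity (any heavy atom ≤ 4.5 Å);
- the ion pathway through a subunit: clearance-scored grid + Dijkstra with
  1/clearance² edge costs, bottleneck radius, and pore-lining residues;
- side-chain contacts (heavy-atom H-bonds at ≤ 3.5 Å with an angular check;
  aromatic ring pairs ≤ 7 Å, stacked or tilted-T) and which of them a given
  substitution destroys;
- the mutation-impact triple ΔV / charge / polarity: side-chain volume
  change (|ΔV| ≥ 30 Å³ destabilizing), charge-class change
  (negative/neutral/positive, His positive) and polarity-class change
  (nonpolar / polar / very polar), composed with buriedness and
  localization (interface, pore, near-interface, surface, buried elsewhere,
  outside the modelled range) into a per-mutation report.

**Cohort side** (module `cohort`): an HGVS-style parser for cDNA/protein
variant pairs, phase-aware allele grouping (cis variants share one disease
allele; homozygotes count twice; probands with a single detected variant
contribute one allele), per-mutation allele frequencies, and novel-mutation
summaries. The package ships a transcription of a published 51-proband
myotonia cohort table as test data.

**Synthetic data** (module `synthetic`): deterministic generators with
analytically known ground truth — sphere sets with closed-form SASA,
two-helix bundles with a designated contact interface, ring-stacked barrel
cages with a cylindrical pore of known clearance, contact-geometry
micro-fixtures, and synthetic cohort tables with exact expected counts.

## Worked example

Generate a synthetic dimer and annotate three mutations on it:

```
poremut simulate --kind bundle_dimer --out-dir fixtures/
printf 'label\tposition\twt\tmut\np.(Ala4Val)\t4\tALA\tVAL\n' > muts.tsv
poremut annotate fixtures/bundle_dimer.pdb muts.tsv --out report.tsv
```

The report row for `p.(Ala4Val)` reads (columns abridged):

```
label         delta_volume_A3  triple      localization  rsa_pct    buried
p.(Ala4Val)   51.0             +51/No/Yes  interface     31.387419  False
```

meaning: the substitution adds 51 Å³ of side-chain volume (destabilizing by
the ≥ 30 Å³ rule), changes polarity class but not charge class, and the site
is a dimer-interface residue of the fixture.

Summarise the packaged cohort table:

```
poremut cohort --table1 --out summary.json
```

`summary.json` reports 51 patients, 96 disease alleles, and per-mutation
counts; the most frequent mutation, the nonsense variant `c.2680C>T`
/ `p.(Arg894*)`, occurs on 38 alleles (39.6%), followed by the frameshift
deletion `c.1437_1450del` on 18 (18.8%); 14 distinct mutation types are
flagged novel, 8 truncating/splice-affecting and 6 missense.

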