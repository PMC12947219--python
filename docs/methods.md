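# Methods

## The decomposition

The package estimates the interaction energy between a ligand L and each
receptor residue Rᵢ by molecular fractionation with conjugate caps. The
receptor is cut at its peptide bonds; each residue keeps its two flanking
residues as conjugate caps (Cᵢ₋₁, Cᵢ₊₁) so that its local bonding
environment is preserved, and every covalent bond severed at a fragment
boundary is terminated by one hydrogen placed along the cut bond. The
per-residue energy is the four-term combination

    E(L–Rᵢ) = E(L·Cᵢ₋₁RᵢCᵢ₊₁) − E(L·Cᵢ₋₁Cᵢ₊₁) − E(Cᵢ₋₁RᵢCᵢ₊₁) + E(Cᵢ₋₁Cᵢ₊₁)

in which the caps' self-energies and their interaction with the ligand
cancel. Two facts make this cancellation testable rather than approximate
in this package:

* cap atoms (and shared link hydrogens) are the *same objects* in the
  paired systems, so their coordinates agree bit-for-bit;
* the classical backend is strictly pairwise additive, so the combination
  reduces algebraically to `cross(L, Rᵢ) + cross(L, H_crc) − cross(L,
  H_cc)`, where `H_crc`/`H_cc` are the link-hydrogen sets of the
  capped-residue and caps-only systems. `synthetic.brute_force_reference`
  recomputes that quantity by direct pair enumeration with its own inline
  vector arithmetic, and the test suite requires agreement to 1e-9
  kcal·mol⁻¹ on every residue of every generated complex.

Terminal residues have a single cap; a residue with no neighbours has empty
caps and its energy reduces to the direct ligand–residue term. Disulfides
crossing a fragment boundary are cut and capped at sulfur by default
(`cut_disulfides=True`); with the option off such a cut is refused rather
than silently mangled.

### Capping choices

The caps are whole adjacent residues by default (`cap_extent =
"whole_adjacent_residue"`), cut at their distal peptide bonds; a
`backbone_only` variant keeps just the neighbour's backbone atoms. Link
hydrogens are placed on the fragment-side atom of each cut bond, along the
bond, at 1.01 Å (N–H), 1.09 Å (C–H) or 1.34 Å (S–H). In classical mode the
link hydrogen carries a generic aliphatic-hydrogen charge (+0.09 e) and LJ
parameters; these are explicit on `CapScheme` because the four-term
combination cancels cap terms but *not* the ligand–link-hydrogen terms, so
the link-H parameterisation is part of the model definition, not an
implementation detail.

## Energy backends

`ClassicalBackend` sums screened Coulomb plus 12-6 Lennard-Jones over atom
pairs:

    E = Σ 332.0637·qᵢqⱼ/(ε·rᵢⱼ) + εᵢⱼ[(rminᵢⱼ/rᵢⱼ)¹² − 2(rminᵢⱼ/rᵢⱼ)⁶]

with geometric-mean well depths, summed half-rmins, and 1-2/1-3 bonded
exclusions (no 1-4 scaling; the exclusion policy is configurable). The
uniform relative permittivity ε (package default 40; 10 and 40 are the two
standard operating points) screens only the Coulomb term, so energies at
ε = 10 are exactly 4x those at ε = 40 whenever LJ vanishes — a scaling the
acceptance suite asserts exactly, along with sign invariance of each
residue's contribution across ε. Uniform-ε screening is a desk-scale
stand-in for a continuum solvent model: it preserves the decomposition's
structure, not any particular solvation physics.

For a quantum-chemistry campaign the package writes one Gaussian-dialect
single-point deck per fragment system (route line with the
B97D/6-311+G(d,p) level and CPCM keywords, total formal charge, singlet
multiplicity, Cartesian coordinates in Å, dielectric in the appended
solvent block) and parses the last converged "SCF Done" energy from engine
logs, converting hartree → kcal·mol⁻¹ by 627.5095. `CachedQMBackend`
serves energies from a CSV cache keyed by (complex, fragment system, ε) and
writes decks for anything missing, so a campaign can be submitted, parsed
and resumed without the package ever executing the engine.

Unit conventions are pinned in `constants.py`: energies kcal·mol⁻¹, lengths
Å, charges e, Coulomb constant 332.0637 kcal·Å·mol⁻¹·e⁻². Pairs closer
than 0.1 Å raise a geometry error rather than returning astronomically
large numbers.

## Radius sweep, convergence, ranking, regions

A residue enters the cumulative total at the first radius r at least as
large as its nearest approach to the ligand — the minimum over all
atom–atom pairs, hydrogens included (configurable). Nearest-approach
inclusion, rather than centroid distance, is used because small radii are
meant to capture residues in direct contact. The schedule is r = step,
2·step, … (default 0.5 Å up to 10 Å). Each residue's energy is computed
once; cumulative sums over the nested inclusion sets are therefore
conserved exactly (tests assert to 1e-9, which in practice is float
accumulation noise).

Convergence is declared at the smallest radius from which the
consecutive-step change stays below 10% of the running total *through the
outer radius* — a one-off dip below threshold does not count. A step with
zero total is non-convergent unless the change is also zero. The detector
returns `None` when the criterion is never met persistently.

Ranking sorts by energy ascending (most attractive first, repulsive last —
repulsive contributions are kept in all sums), ties broken by residue
number. Regional aggregation assigns each residue to exactly one ligand
region: the region of the ligand heavy atom nearest to it, with a nearest
hydrogen delegating to its bonded heavy atom. Regional sums therefore
partition the total exactly. The published per-residue rankings for the
three α1A-adrenoceptor complexes ship in `pymfcc.datasets` as inputs for
this aggregation; the underlying DFT energies are external to the package.

## The synthetic generator

`generate_toy_complex` builds a deterministic toy pocket: an
ethanolamine-like ligand with a +1 protonated amine at the origin, and a
single peptide chain (GLY/ALA/SER/VAL/CYS plus ASP/LYS for the charged
fraction, default 50%) coiled around it so residue nearest approaches
sweep the requested window, 2–10 Å by default — the contact range a
receptor binding pocket spans. Anionic and cationic residues against the
+1 ligand guarantee energies of both signs.

Placement is a greedy self-avoiding walk: each residue's frame is chosen
from a grid of candidate headings scored by (i) squared error between its
nearest approach and that residue's target distance, (ii) a clash penalty
against everything already placed, with an element-aware hard bound at the
distance below which covalent-bond perception would misread the contact,
and (iii) a smoothness term. The pick is stochastic among the leading
candidates, and a walk that boxes itself in is abandoned and re-rolled
from the seeded generator (bounded retries; exhausting them raises
`GenerationError`). Peptide bonds are exact (1.33 Å) by construction;
backbone geometry is tetrahedral-plausible but deliberately unrelaxed — no
minimisation is performed because the classical backend only needs finite,
non-singular geometry. Chain termini keep plain backbone atoms (no
NH₃⁺/COO⁻ capping), and residue charge templates are the neutral-pH values
with ASP/GLU at −1 and LYS/ARG at +1.

What passing tests on these toys does and does not show: they verify the
*bookkeeping* of the method exactly — fragmentation topology, cap
cancellation, inclusion, conservation, aggregation — under a backend whose
additivity makes the expected answer computable independently. They say
nothing about DFT-level energetics, continuum-solvent physics, or the
conformational quality of real binding pockets.

The shipped parameter table (`pymfcc/data/default_params.csv`) is a
compact additive charge/LJ set in the CHARMM convention covering the
generator's residues and the toy ligand; per-residue charges sum exactly
to template formal charges, which `assign_parameters` enforces to 1e-6 e
for any user-supplied table as well. Production use on real complexes is
expected to bring its own table through the same CSV format.

## Numerical and policy details

* Bond perception: pairs within 1.3x the sum of covalent radii; hydrogens
  bond only to their nearest heavy atom; receptor–ligand contacts are
  never covalent. Alternate locations resolve to the highest-occupancy
  conformer; waters, ions and non-selected het groups are dropped with a
  log line.
* Minimum-distance ties resolve to the lowest atom ids (residue atom
  first), making reports deterministic.
* Machine outputs (CSV/JSON) carry full precision and re-sum to the
  in-memory totals; only the human-readable summary rounds to two
  decimals.
* The run manifest records structure source, ligand, backend, ε, cap
  scheme and schedule; re-running a classical sweep from a manifest
  reproduces the report files byte-identically.
* Protonation validation is template-based (hydrogens expected by the
  parameter table); inputs are expected to arrive pre-protonated, and
  unknown residues produce warnings, not failures.

## Known limitations

* The classical backend is not a solvation model; its ε-screened Coulomb
  is a structural stand-in. Absolute energies from it have no quantitative
  meaning for real complexes.
* Separation limits are Coulombic: a ±1 residue–ligand pair at 500 Å still
  contributes ~0.02 kcal·mol⁻¹ at ε = 40. Tests of the vanishing limit use
  10⁷ Å displacements.
* Fragmentation covers polypeptides (including cross-chain disulfides);
  nucleic acids and other polymers are out of scope. Proline's ring
  nitrogen receives a single link hydrogen like any other cut-bond
  terminus.
* The generator produces single-chain toys only, and its geometric realism
  ends at bond lengths and clash-freedom; do not use it as a
  conformational benchmark.
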