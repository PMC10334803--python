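# Methods

## The model

An unfolded polypeptide segment between two structurally resolved anchors
behaves as an entropic spring: stretching it reduces the number of
accessible backbone conformations, so a restoring force appears along the
end-to-end axis. The package uses the Marko–Siggia interpolation for the
force of a worm-like chain at extension *x* below its contour length
*L_C* = *n*·*l_p*:

F(x) = (k_BT / l_p) · [ ¼ (1 − x/L_C)⁻² + x/L_C − ¼ ]

The elastic energy between two extensions is the closed-form integral of
F (implemented via the antiderivative g(t) = ¼/(1−t) + t²/2 − t/4 of the
bracket, t = x/L_C), reported as a *positive* stored stretching energy in
k_BT; path works along the gating cycle are signed differences of stored
energy, negative when the spring relaxes. The local spring constant is
the analytic derivative dF/dx. Inverse force→extension lookups use
bracketed root finding (Brent), which the strict monotonicity of F makes
unambiguous.

Assumptions: the linker is fully unfolded between its anchors (it is
unresolved in open-state maps precisely because it is disordered), each
residue contributes one persistence length to the contour, the chain is
at thermal equilibrium, and anchor Cα positions are adequate proxies for
the chain endpoints.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| persistence length *l_p* | 0.38 | nm | consensus value for unfolded polypeptides from force-spectroscopy stretching experiments |
| thermal energy k_BT | 4.114 | pN·nm | room temperature; configurable via temperature in Kelvin (k_BT = 0.0138065·T) |
| chain units *n* | 16 | residues | the Cα(Ile99)→Cα(Ser115) span of the MthK linker; L_C = 6.08 nm |
| pore anchor / ring anchor | 99 / 115 | author residue numbers | last pore-side and first ring-side residues resolved in open-state maps |
| alignment selection | 20–83 | residues | transmembrane helix 1 through the glycine hinge: the part that is conformation-invariant across states |
| outlier threshold | 2.5 | × MAD | flags the one dramatically stretched linker without touching the normal spread |

Energies are reported in k_BT multiples, forces in pN, stiffness in
pN/nm; coordinates and extensions at the interface are in Å (with nm
accepted), internal spring math in nm.

## Structure handling and geometry

Structures are read with gemmi (model 1 only; altlocs resolved to the
highest-occupancy conformer, ties lexicographic; waters/heteroatoms
ignored; insertion codes rejected). Author residue numbering is
authoritative. When more than four protein chains are present, the four
longest are analyzed unless an explicit chain list is given.

The analysis frame puts the pore's fourfold axis on z. The axis is found
from the cyclic chain-permutation superposition of the pore-domain Cα
(the rotation mapping chain *i* onto chain *i+1* is a quarter-turn about
the symmetry axis); a principal-axis method is available as an
alternative (`axis_method="principal"`) and agrees to a fraction of a
degree on near-C4 inputs. The z-sign convention puts the selectivity
filter up, so the gating ring sits at negative z. Open structures are
Kabsch-superposed onto the aligned closed reference over residues 20–83
(uniform weights), which fixes the common frame needed for the
transition-state chimeras; linker lengths themselves are rigid-motion
invariant, and per-structure force statistics are unchanged if each
structure is instead aligned on its own pore axis.

Transition-state chimeras connect one state's ring anchors to the other
state's pore anchors (TS1: activated ring over closed pore; TS2: apo
ring over open pore). Chains are paired by minimal azimuthal offset;
because the closed state is C4-symmetric the per-structure statistics are
pairing-invariant (asserted in tests). Elastic energy is a state
function, so the four path works (closed→TS1→open→TS2→closed) must sum
to zero; the pipeline checks this to 1e-9 k_BT. Path 4 is reported as
its elastic component only, annotated with the ≥2.7 k_BT linker-folding
gain estimated from the outlier; the additional four-helix coiling
energy of the closed bundle is not computed.

Pooled statistics come in two named sets, mirroring the dual reporting
of the source data: *pooled* (all unfolded linkers, n = 23-style,
including the stretched outlier) and *normal* (outliers removed,
n = 22-style). Mean force is the mean of per-linker forces, not the
force at the mean length.

## What the synthetic generator emulates

The generator produces Cα-only C4 tetramers: residues 20–83 as a fixed
helical pore-body trace (identical across states, so superposition and
axis detection run on realistic input), 84–98 bridging to the pore
anchor, anchors at residues 99 and 115, and — for folded-linker chains —
ordered residues 100–114 along an arced path. Feasibility is enforced
(no unfolded linker may reach the 60.8 Å contour length), and iid
Gaussian coordinate noise (default 0.15 Å) with a seeded generator makes
every run reproducible; ground truth is recorded after noise.

The closed state uses the observed closed anchor-ring radii (pore 5.6 Å,
ring 30.7 Å) and a ring depth of 17.3 Å, chosen so the closed linker
geometry sits mildly loaded and the four path works order as in the
gating cycle (loading positive, the two relaxation paths negative). The
open-state family is calibrated, once, against the observed open-state
geometry, in this order:

1. anchor-ring radii fixed at the printed open values (pore 17.0 Å,
   ring 39.3 Å);
2. the ring's azimuthal offset relative to the pore — not a printed
   quantity — solved so the per-structure radial/total force ratio
   equals the observed decomposition (9.9/13.2 ≈ 0.75), giving ≈19.8°;
3. ring depth solved so the 22 normal linkers average exactly 29.1 Å;
4. five structures receive rigid-ring tilts solved so their stretched
   subunits sit at assigned deviations (1.8–3.6 Å), spreading the pooled
   lengths by ≈3 Å while staying well inside the outlier threshold;
5. a sixth structure carries one folded linker whose diagonal partner is
   tilted to exactly 36.2 Å — so the pooled n = 23 mean is 29.4 Å by
   construction, as in the source data.

Tilts of the freely tumbling structures pivot about the pore-anchor
plane on the symmetry axis ("dome" pivot): the ring anchors then move on
a dome, and the subunit rising toward the membrane plane swings radially
*outward* — which is what produces the observed diagonal-subunit
compensation (large F_z pairs with small F_xy across the diagonal). A
rigid rotation about the ring's own center moves the rising anchor
slightly inward and fails to reproduce that compensation, so it is kept
only for the pinned-corner outlier structure, where it leaves the two
bystander subunits at their canonical length and gives the stretched
linker a realistic radial component. In the real outlier structure the
folded and stretched linkers are adjacent rather than diagonal; the
rigid-ring emulation makes them diagonal, which leaves all pooled
statistics unchanged.

What passing the pipeline tests on this ensemble shows: the geometry,
alignment, exclusion bookkeeping (24 → 23 → 22), force decomposition and
outlier machinery recover a known ground truth through the full
PDB-write/parse path. What it does not show: agreement with real
cryo-EM coordinates — the generator has exact fourfold pore symmetry, a
rigid planar anchor ring, isotropic noise, and no model of the linker's
conformational ensemble beyond its endpoints. Analyses of deposited
structures should feed the actual files to `wlcgating analyze`.

## Numerical choices and edge cases

- Extensions within 2% of the contour length evaluate with a warning
  (`NearContourWarning`, surfaced as a `near_contour` flag on linker
  mechanics) rather than an error; genuine inputs stay below ~60% of
  L_C, so the guard only catches pathological geometry.
- x ≥ L_C, reversed energy bounds, probabilities outside (0,1) and
  non-positive dissociation constants raise `WLCDomainError`.
- Zero-length linkers yield zero force with zero components.
- The small-extension behaviour approaches Hooke's law
  F ≈ (3/2)(k_BT/l_p)(x/L_C) with a relative deviation of (x/L_C)/2,
  i.e. below 1e-3 only for x ≲ 0.002·L_C; tests assert the exact
  convergence rate.
- ΔG↔P_O uses the two-state Boltzmann relation
  ΔG = −k_BT·ln(P_O/(1−P_O)); it reproduces all five published
  conversions (−2.9, −3.2, −5.1, +9.2, +8.1 k_BT) to the printed digit.
- Binding energies use a 1 M standard state: |ΔG⁰| = ln(1 M/K_D) k_BT
  per site, summed over sites.
- Report JSON rounds to one decimal (forces pN, energies k_BT, lengths
  Å) and attaches a unit to every number; CSV tables keep full
  precision. Identical inputs give byte-identical outputs.

## Known limitations

- The entropic-spring treatment needs an *unfolded* linker with resolved
  endpoints; ordered linkers (the closed state, BK-like channels) are
  detected and excluded, not modelled.
- Per-structure averages assume exactly four analyzable chains; partial
  tetramers are rejected by the axis-alignment stage.
- The transition states are geometric constructs (chimeras of solved
  end states), not solved structures; their works are elastic bounds on
  the real pathway.
- The four-helix coiling contribution to closing is acknowledged but not
  estimated; path 4 is therefore a lower bound via its elastic term plus
  the outlier-derived folding gain.
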