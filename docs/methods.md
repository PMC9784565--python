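# Methods

## Model

A protein chain is reduced to one point per residue — the unweighted mean of
the residue's non-hydrogen atom coordinates (the *effective atom*) — carrying
an intrinsic hydrophobicity H^r ∈ [0, 1]. Hydrogens are excluded because
deposited crystal structures mostly lack them; including them only where
present would bias comparisons between structures. A side-chain-only
averaging mode exists behind a switch (`side_chain_only`), since both
conventions appear in the hydrophobicity-field literature; whole-residue
averaging is the default.

Three distributions over the N residues, each normalized to sum to 1:

- **T**: the chain is translated to its centroid and rotated onto the
  principal axes of the effective-atom covariance; a 3D Gaussian with
  σ_axis = (extent_axis + 2·pad)/6 (pad 0 by default, σ floored at 1e-3 Å)
  is evaluated at each effective atom. The ±3σ rule makes the Gaussian span
  the molecule; no formula for the envelope is canonical, so the pad is
  configurable (e.g. pad = cutoff).
- **O**: Õ_j = Σ_i (H_i + H_j)·w(r_ij, c) over all residues including
  i = j (weight 1, contributing 2H_j), where w is Levitt's contact
  polynomial, w(r) = 1 − ½(7x² − 9x⁴ + 5x⁶ − x⁸), x = r/c, zero beyond the
  cutoff c = 9 Å. The symmetric pair form with the self term is the default;
  normalization absorbs the constant self contribution. A neighbour-only
  form (`interaction="self"`) is available.
- **R**: uniform 1/N.

Divergences are base-2 Kullback–Leibler sums; RD = D_KL(O|T) /
(D_KL(O|T) + D_KL(O|R)). The membrane-modified expectation is
M ∝ T + K(T_MAX − T), normalized; K is fitted by exhaustive scan of
D_KL(O|M(K)) on the grid 0–10 by 0.1 (ties toward smaller K — the least
environmental modification). The grid step matches the one-decimal precision
K is conventionally reported at; no structure analyzed here drives K beyond
10, and the grid is configurable if one does.

Fragments are scored by restricting the chain-level T and O to the
fragment's residues, renormalizing both, rebuilding R as uniform over the
fragment, and refitting K with the fragment-local T maximum (a global-T_MAX
mode exists). Restricting rather than refitting a fragment-local Gaussian
keeps fragment statuses comparable across the chain. Residue sets (e.g.
ion-contact residues) are scored the same way after optional ±window
expansion in author numbering. Contact sets can be derived as residues with
any heavy atom within 3.5 Å of a named HET atom.

In/Out conformer comparison pairs fragment tables by label; fragments
present in only one form are reported unpaired, never dropped. The change
flag fires at |ΔK| ≥ 0.1 — one grid step. Per-form ΣRD and ΣK totals are
reported as sums over each form's scored fragments.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| cutoff c | 9.0 | Å | Levitt's value for the contact function |
| pad | 0.0 | Å | envelope margin; extent/6 alone spans the molecule at ±3σ |
| K grid | 0–10 step 0.1 | — | reporting precision of K; covers membrane regimes (K > 3 occurs) |
| ΔK change threshold | 0.1 | — | one grid step |
| divergence floor | 1e-12 | — | applied to O/M denominators only; T is analytically positive; floor events are logged |
| scale | normalized Kyte–Doolittle | — | min–max mapped to [0, 1]; user-overridable |

The intrinsic hydrophobicity scale is a free input of this model family and
published analyses do not always state theirs; absolute RD/K values on real
structures therefore depend on the scale chosen, while the qualitative
orderings (micelle vs membrane regime, In/Out differences) are robust to it.

## Numerical choices

- Orientation signs are fixed from the data: an axis flips if the third
  moment of the projections onto it is negative; sign-symmetric clouds fall
  back to making the eigenvector's largest-magnitude component positive, and
  the third axis is the cross product of the first two (proper rotation).
  This makes the oriented frame — not just T, which depends only on squared
  coordinates — invariant under rigid motion of the input.
- T is evaluated in log space and shifted by the maximum before
  exponentiation.
- M(K=0) returns T's values verbatim and M(K=1) returns exact 1/N (with a
  compensated tail element), so the algebraic identities hold to the bit;
  for other K the blend is renormalized, leaving an O(1/K) residual against
  the fully inverted limit.
- Degenerate inputs error explicitly: coincident points (orientation),
  all-zero hydrophobicity (observed profile), empty selections and
  sub-2-residue fragments. RD with both divergences zero returns 0 with a
  warning.
- Altloc conflicts keep the highest-occupancy conformer (ties: altloc 'A',
  then first); chain gaps are tolerated silently and only observed residues
  enter N; the first model of multi-model files is used; MSE/SEC/PYL map to
  their standard parents.

## Synthetic data

The generators emulate the two regimes the statistic is meant to separate,
not protein geometry (no bonds, no secondary structure):

- *micelle mode*: positions from an anisotropic Gaussian with sigmas
  (14, 11, 8) Å — a globular droplet of protein-like extent at n = 200 —
  and hydrophobicity rank-mapped to decrease with Mahalanobis distance from
  the centre, so O tracks T.
- *inverted mode*: the same droplet with hydrophobicity increasing outward
  and a 6 Å central cavity: points drawn inside the cavity are displaced
  radially to its shell, emulating the excluded volume of a transport
  channel while keeping cavity/no-cavity comparisons paired draw by draw.
  The cavity's RD effect is small but systematically positive.
- *known-K mode*: O = normalize(max(0, M(T, K_true) + Gaussian noise)) —
  noise on the probability scale, clipped and renormalized, the simplest
  model consistent with the profile invariants.

Passing tests on these inputs show the statistics behave as designed on
clouds with the intended hydrophobicity topology; they do not show that any
particular real structure reproduces published values, which additionally
depends on the hydrophobicity scale and envelope padding chosen (see the
network-dependent acceptance test for the real-structure check).

Test and acceptance problem sizes — n = 200 droplets, 10 seeds per regime,
100 noisy replicates for K recovery, N ≤ 50 for the quadratic brute-force
oracle — are chosen so each check exercises the full pipeline while the
whole suite stays fast.

## Limitations

- Fragment tables are inputs; no TM-helix detection or membrane-plane
  estimation is attempted.
- No structure repair, hydrogen addition, or assembly expansion.
- The Gaussian envelope assumes a roughly convex, singly-lobed molecule;
  multi-domain chains violate the idealization (this is a property of the
  model, not of the implementation).
- Absolute RD/K on real structures depend on the hydrophobicity scale; only
  a documented parameterization makes values comparable across studies.
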