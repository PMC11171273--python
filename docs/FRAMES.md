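# Canonical-frame contract

Every density-matrix prediction happens in a molecule-specific canonical
pose. This file is the normative statement of those conventions; the code
in `dmguess.geometry` implements exactly this and nothing else.

## Transform definition

A `FrameTransform` holds a translation `t` (angstrom) and a proper
rotation `R` (orthogonal, det +1). Canonicalization maps lab coordinates
`x` to `R (x - t)`. Vector quantities (forces, velocities) are covariant:
they transform with `R` alone, and `apply_inverse_frame` returns
`R^T v` — the translation is never applied to vectors.

## Triatomics (H2O, S2O)

* anchor atom at the origin: the oxygen for H2O, the **central** sulfur
  for S2O (identified as the S nearer to the O);
* of the two remaining atoms, the one with the **lower input index** is
  placed on the negative x axis (y = z = 0, x < 0);
* the last atom lies in the x-y plane with y >= 0. If y would be
  negative, the frame construction flips the in-plane axis (compensated
  through the third row so det R stays +1); the z reflection is a
  symmetry of a planar molecule, so this labeling is physically
  equivalent to its mirror.
* a triatomic with sin(bend angle) < 1e-6 is rejected
  (`DegenerateGeometryError`): the plane constraint is undefined.

Features: `(x_A, x_B, y_B)` with A the axis atom and B the in-plane atom.

## Hexaaqua iron(II)

* Fe at the origin;
* the six ligand oxygens lie on the Cartesian axes, ordered
  `(+x, -x, +y, -y, +z, -z)`;
* each rigid water (O-H 0.9751 angstrom, H-O-H 104.14 degrees) lies in
  the plane spanned by its own axis and a fixed partner axis
  (x -> y, y -> z, z -> x), H atoms symmetric about the Fe-O axis and
  pointing away from Fe.

Features: the six Fe-O distances in the axis order above.

## Verification

`features()` *verifies* the pose (anchor at origin, axis/plane
constraints within 1e-6 angstrom, scaled with the coordinate magnitude)
and raises `FrameViolationError` rather than silently accepting a
non-canonical geometry.

Transforms serialize to YAML via `FrameTransform.to_yaml` /
`from_yaml`.
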