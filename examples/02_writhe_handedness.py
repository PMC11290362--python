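"""Writhe as a signed, handedness-aware descriptor.

Computes the five-residue-window writhing number for a right-handed helix,
its left-handed mirror image, and a planar zigzag, showing that writhe
carries sign information the (always non-negative) Frenet curvature cannot.
"""

from curvatrace import FixtureSpec, curvature_torsion_at, fit_backbone_curve, writhe_at

right = FixtureSpec.helix(30).coordinates()
left = FixtureSpec.helix(30, handedness=-1).coordinates()
zigzag = FixtureSpec.zigzag(9).coordinates()

for name, xyz, centre in (("right-handed helix", right, 10),
                          ("left-handed helix", left, 10),
                          ("planar zigzag", zigzag, 4)):
    wr = writhe_at(xyz, centre)
    curve = fit_backbone_curve(xyz, range(1, len(xyz) + 1))
    kappa, _ = curvature_torsion_at(curve, float(centre))
    print(f"{name:20s}  Wr = {wr:+.5f}   kappa = {kappa:.4f} 1/A")

print(
    "\nMirror-image helices have writhe of equal magnitude and opposite "
    "sign, while their\ncurvature is identical; a planar curve has exactly "
    "zero writhe."
)
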