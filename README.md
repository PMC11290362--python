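# curvatrace

Differential-geometry and knot-theory descriptors for protein backbones.

Comparing protein backbone shapes through superposition-based measures such
as RMSD is fragile: RMSD depends on the superposition, is insensitive to
small local changes, and violates the triangle inequality, which breaks the
assumptions of most clustering algorithms. `curvatrace` instead treats the
Cα trace as a smooth space curve **r**(t) — a cubic spline through the Cα
positions with the residue position as parameter — and describes each
residue by local differential-geometric and knot-theoretic quantities:

- **curvature** κ = |ṙ × r̈| / |ṙ|³ (Å⁻¹, always ≥ 0),
- **torsion** τ = (ṙ × r̈) · r⃛ / |ṙ × r̈|² (Å⁻¹, signed; negated by mirror
  reflection),
- **arc length** ∫|ṙ| dt (Å, cumulative along each contiguous segment),
- **writhing number** Wr of the five-residue window around each residue
  (unitless, signed; the polygonal Gauss linking double sum, positive for
  right-handed coiling).

These descriptors are invariant under rotation and translation, sensitive to
small conformational changes, and the weighted Euclidean distance between
descriptor vectors is a true metric, so aligned residues can be clustered
into blocks of equivalent geometry across a protein family.

Because a cubic spline's third derivative is discontinuous at every knot,
derivatives are never read off the spline directly: the spline is resampled
over a window around each residue, fitted with a Chebyshev series (50
Chebyshev-node samples, degree 10 over ±3 residues by default), and the
series is differentiated analytically. This is exact for cubics and stable
against knot artefacts; the accuracy trade-offs are analysed in
[docs/methods.md](docs/methods.md).

The package is intended for structural bioinformaticians who need fast,
reproducible shape descriptors for structure comparison, family analysis,
or as input features for machine-learning models.

## Quick start

```python
from curvatrace import FixtureSpec, describe_trace, read_calpha_trace

spec = FixtureSpec.helix(30)          # ideal alpha-helix Calpha trace
trace = read_calpha_trace(spec.to_pdb())
table = describe_trace(trace)         # per-residue descriptors
print(table.to_dataframe().iloc[10:13])
```

Running `python examples/01_describe_helix.py` prints (abridged):

```
closed form:  kappa = 0.3815 1/A   tau = 0.1426 1/A
res  kappa    tau      arc(A)   writhe
 11  0.3850   0.1488     42.26  0.2349
 12  0.3849   0.1488     46.45  0.2349
 13  0.3849   0.1488     50.65  0.2349
```

A circular helix of radius a and rise c per radian has κ = a/(a²+c²) and
τ = c/(a²+c²); for the ideal α-helix (a = 2.3 Å, 1.5 Å rise per 100° of
turn) that is (0.3815, 0.1426) Å⁻¹. The pipeline recovers curvature to
within ~1%; torsion runs ~4% high because the interpolating spline slightly
shrinks the effective helix radius at α-helical sampling density. The
writhe +0.235 is positive for the right-handed helix and would be −0.235
for its mirror image.

The other examples cover the writhe sign convention
(`02_writhe_handedness.py`), alignment-column clustering with matching text
and PyMOL colouring (`03_annotate_family.py`), and environment
classification plus per-class (κ, τ) kernel densities
(`04_propensity_density.py`).

## Command line

A thin CLI wraps the same library calls:

```sh
curvatrace fixture helix -n 30 -o helix.pdb       # synthetic test trace
curvatrace describe helix.pdb -o geometry.csv     # descriptor table
curvatrace describe helix.pdb --bfactor curvature -O coloured.pdb
curvatrace annotate family.fasta --structures map.cfg -o report.txt --pml family.pml
curvatrace propensity build helix.pdb -o pdfs.json
```

`describe --bfactor` writes the chosen descriptor into the b-factor columns
(61–66) of every atom, leaving every other byte of the file untouched, so
any molecular viewer can colour the structure by local geometry.
Exit codes: 0 success, 1 usage error, 2 data error.

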