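"""Deterministic synthetic C-alpha fixtures with analytic descriptor truth.

Generates idealized backbone traces — circular helices (alpha-helix, twisted
beta-strand), straight lines, planar circles and zigzags, the twisted cubic —
as coordinate arrays, minimal CA-only PDB files, and truth tables carrying
the closed-form curvature/torsion where one exists.  The same spec (including
the seed, for perturbed traces) always produces byte-identical output.

Closed forms used
-----------------
Circular helix of radius ``a`` and rise ``c`` per radian:
``kappa = a / (a^2 + c^2)``, ``tau = c / (a^2 + c^2)`` (tau < 0 for a
left-handed helix).  The alpha-helix default (a = 2.3 A, 1.5 A rise and 100
degrees of twist per residue) gives kappa = 0.3815, tau = 0.1426 per A.
Twisted cubic (t, t^2, t^3): ``kappa = 2 sqrt(9t^4+9t^2+1)/(1+4t^2+9t^4)^1.5``,
``tau = 3/(9t^4+9t^2+1)``.

The beta-strand fixture is a near-2-residue-repeat helix (radius 0.9 A, rise
3.3 A/residue, 185 degrees/residue, i.e. an effective -175 degrees/residue
left-handed rotation: an exact 180-degree repeat would be a planar zigzag
with zero torsion, whereas real strands carry a few degrees of twist per
residue).  Its descriptor truth is numeric, not closed form — at ~2 samples
per turn the spline through the points differs strongly from the generating
helix, deliberately so, since the same is true of real strand C-alpha
traces: the pipeline reports high curvature (~0.6-0.7/A) and near-zero
torsion for strands, matching its behaviour on backbones built from ideal
beta dihedrals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidFixtureSpecError

__all__ = ["FixtureSpec", "generate_fixture"]

KINDS = ("helix", "strand", "line", "circle", "zigzag", "twisted_cubic", "perturbed")

#: ideal alpha-helix C-alpha parameters
HELIX_RADIUS = 2.3  # angstrom
HELIX_RISE = 1.5  # angstrom / residue
HELIX_TWIST = 100.0  # degrees / residue

#: twisted beta-strand parameters (see module docstring)
STRAND_RADIUS = 0.9
STRAND_RISE = 3.3
STRAND_TWIST = 185.0

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one synthetic trace; equal specs give identical bytes."""

    kind: str
    n_residues: int = 30
    radius: float = HELIX_RADIUS  # angstrom (helix, strand, circle)
    rise: float = HELIX_RISE  # angstrom / residue (helix, strand)
    twist: float = HELIX_TWIST  # degrees / residue (helix, strand)
    spacing: float = 3.8  # angstrom between residues (line, zigzag)
    step: float = 0.5  # radians / residue (circle)
    amplitude: float = 0.9  # zigzag out-of-axis offset, angstrom
    scale: float = 0.25  # twisted-cubic parameter step per residue
    handedness: int = 1  # +1 right-handed, -1 left-handed (helix, strand)
    noise_sd: float = 0.0  # angstrom, isotropic Gaussian (perturbed)
    base_kind: str = "helix"  # perturbed: which ideal trace to perturb
    seed: int = 0
    sequence: str = ""  # one-letter codes; empty -> poly-alanine
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidFixtureSpecError(f"invalid fixture spec: unknown kind {self.kind!r}")
        if self.n_residues < 5:
            raise InvalidFixtureSpecError("invalid fixture spec: n_residues must be >= 5")
        if self.kind in ("helix", "strand", "circle") and self.radius <= 0:
            raise InvalidFixtureSpecError("invalid fixture spec: radius must be > 0")
        if self.handedness not in (1, -1):
            raise InvalidFixtureSpecError("invalid fixture spec: handedness must be +1 or -1")
        if self.kind == "perturbed":
            if self.base_kind in ("perturbed",) or self.base_kind not in KINDS:
                raise InvalidFixtureSpecError("invalid fixture spec: bad base_kind")
            if self.noise_sd < 0:
                raise InvalidFixtureSpecError("invalid fixture spec: noise_sd must be >= 0")
        if self.sequence and len(self.sequence) != self.n_residues:
            raise InvalidFixtureSpecError(
                "invalid fixture spec: sequence length must equal n_residues"
            )

    # ---- convenience constructors --------------------------------------
    @classmethod
    def helix(cls, n_residues: int = 30, **kw) -> "FixtureSpec":
        return cls("helix", n_residues, **kw)

    @classmethod
    def strand(cls, n_residues: int = 30, **kw) -> "FixtureSpec":
        kw.setdefault("radius", STRAND_RADIUS)
        kw.setdefault("rise", STRAND_RISE)
        kw.setdefault("twist", STRAND_TWIST)
        return cls("strand", n_residues, **kw)

    @classmethod
    def line(cls, n_residues: int = 10, **kw) -> "FixtureSpec":
        return cls("line", n_residues, **kw)

    @classmethod
    def circle(cls, n_residues: int = 12, radius: float = 10.0, **kw) -> "FixtureSpec":
        return cls("circle", n_residues, radius=radius, **kw)

    @classmethod
    def zigzag(cls, n_residues: int = 10, **kw) -> "FixtureSpec":
        return cls("zigzag", n_residues, **kw)

    @classmethod
    def twisted_cubic(cls, n_residues: int = 21, **kw) -> "FixtureSpec":
        return cls("twisted_cubic", n_residues, **kw)

    @classmethod
    def perturbed(cls, base_kind: str = "helix", n_residues: int = 30,
                  noise_sd: float = 0.1, seed: int = 0, **kw) -> "FixtureSpec":
        return cls("perturbed", n_residues, base_kind=base_kind,
                   noise_sd=noise_sd, seed=seed, **kw)

    # ---- geometry ------------------------------------------------------
    def coordinates(self) -> np.ndarray:
        """(n, 3) C-alpha coordinates in angstrom."""
        n = self.n_residues
        i = np.arange(n, dtype=float)
        kind = self.base_kind if self.kind == "perturbed" else self.kind
        if kind in ("helix", "strand"):
            theta = np.deg2rad(self.twist) * i
            xyz = np.column_stack(
                [
                    self.radius * np.cos(theta),
                    self.handedness * self.radius * np.sin(theta),
                    self.rise * i,
                ]
            )
        elif kind == "line":
            xyz = np.column_stack([self.spacing * i, np.zeros(n), np.zeros(n)])
        elif kind == "circle":
            theta = self.step * i
            xyz = np.column_stack(
                [self.radius * np.cos(theta), self.radius * np.sin(theta), np.zeros(n)]
            )
        elif kind == "zigzag":
            xyz = np.column_stack(
                [self.spacing * i, self.amplitude * (-1.0) ** i, np.zeros(n)]
            )
        elif kind == "twisted_cubic":
            s = self.scale * (i - (n - 1) / 2.0)
            xyz = np.column_stack([s, s**2, s**3])
        else:  # pragma: no cover
            raise InvalidFixtureSpecError(f"invalid fixture spec: {kind}")
        if self.kind == "perturbed" and self.noise_sd > 0:
            rng = np.random.default_rng(self.seed)
            xyz = xyz + rng.normal(0.0, self.noise_sd, xyz.shape)
        return xyz

    def truth(self) -> pd.DataFrame:
        """Per-residue analytic curvature/torsion where a closed form exists.

        Columns: resseq, curvature, torsion (NaN where no closed form / the
        descriptor is undefined, e.g. torsion of a straight line).
        """
        n = self.n_residues
        resseq = np.arange(1, n + 1)
        kappa = np.full(n, np.nan)
        tau = np.full(n, np.nan)
        if self.kind == "helix":
            a = self.radius
            c = self.rise / np.deg2rad(self.twist)  # rise per radian
            kappa[:] = a / (a**2 + c**2)
            tau[:] = self.handedness * c / (a**2 + c**2)
        elif self.kind == "line":
            kappa[:] = 0.0
        elif self.kind == "circle":
            kappa[:] = 1.0 / self.radius
            tau[:] = 0.0
        elif self.kind == "zigzag":
            tau[:] = 0.0  # planar
        elif self.kind == "twisted_cubic":
            s = self.scale * (np.arange(n) - (n - 1) / 2.0)
            kappa = 2.0 * np.sqrt(9 * s**4 + 9 * s**2 + 1) / (1 + 4 * s**2 + 9 * s**4) ** 1.5
            tau = 3.0 / (9 * s**4 + 9 * s**2 + 1)
        return pd.DataFrame({"resseq": resseq, "curvature": kappa, "torsion": tau})

    # ---- serialization -------------------------------------------------
    def residue_names(self) -> list[str]:
        if self.sequence:
            return [_AA3.get(c.upper(), "UNK") for c in self.sequence]
        return ["ALA"] * self.n_residues

    def to_pdb(self) -> str:
        """Minimal valid CA-only PDB text (deterministic)."""
        lines = []
        names = self.residue_names()
        for idx, (x, y, z) in enumerate(self.coordinates()):
            lines.append(
                f"ATOM  {idx + 1:5d}  CA  {names[idx]:>3s} {self.chain_id}{idx + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C  "
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


def generate_fixture(spec: FixtureSpec) -> tuple[str, pd.DataFrame]:
    """PDB-format content plus the analytic truth table for ``spec``."""
    return spec.to_pdb(), spec.truth()


def helix_closed_form(radius: float = HELIX_RADIUS, rise: float = HELIX_RISE,
                      twist: float = HELIX_TWIST, handedness: int = 1) -> tuple[float, float]:
    """Closed-form (kappa, tau) of a circular helix given per-residue parameters."""
    c = rise / math.radians(twist)
    return radius / (radius**2 + c**2), handedness * c / (radius**2 + c**2)
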