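"""Environment-specific propensity tables and descriptor probability densities.

A propensity table scores each of the 20 amino acids in a set of local
structural environment classes (here: helix / strand / other, assigned from
backbone geometry).  From a family of described structures, a 2D probability
density over (curvature, torsion) can be estimated per class — usable as a
restraint or as a feature distribution for learning applications.

Environment classification is a simple rectangle rule in (kappa, tau) space,
with boxes anchored to the values this pipeline measures on ideal
secondary-structure traces: an alpha-helix maps to (0.38, 0.15) per
angstrom, a twisted beta-strand to high curvature (~0.6/A) with near-zero
torsion (the spline through the ~2-residue strand repeat bends sharply at
every residue but stays nearly planar).  All boundaries are configurable.

The density estimator is a Gaussian kernel density with a diagonal
Scott's-rule bandwidth per dimension; degenerate samples (zero variance) get
a floor bandwidth so the density concentrates at the sample point instead of
failing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .errors import MalformedTableError, UndefinedDescriptorError
from .geometry import GeometryTable

__all__ = [
    "ClassificationRules",
    "DescriptorPDF",
    "PropensityTable",
    "build_descriptor_pdfs",
    "classify_geometry",
    "dump_propensity_table",
    "load_propensity_table",
]

AMINO_ACIDS = tuple("ARNDCQEGHILKMFPSTWYV")

#: minimum residues per class for density estimation
MIN_CLASS_SAMPLES = 20

#: floor bandwidth (1/angstrom) for zero-variance sample sets
BANDWIDTH_FLOOR = 1e-8


@dataclass(frozen=True)
class ClassificationRules:
    """Rectangle rules in (kappa, tau) space for environment classes.

    helix: |kappa - helix_kappa| <= helix_kappa_tol and
           |tau - helix_tau| <= helix_tau_tol
    strand: kappa >= strand_kappa_min and |tau| <= strand_tau_max
    otherwise: other.  The defaults keep the two boxes disjoint.
    """

    helix_kappa: float = 0.38
    helix_kappa_tol: float = 0.08
    helix_tau: float = 0.14
    helix_tau_tol: float = 0.08
    strand_kappa_min: float = 0.48
    strand_tau_max: float = 0.12


DEFAULT_RULES = ClassificationRules()


def classify_geometry(
    kappa: float | None,
    tau: float | None,
    rules: ClassificationRules = DEFAULT_RULES,
) -> str:
    """Environment class ("helix" | "strand" | "other") from curvature/torsion.

    A pure function of its inputs.  Undefined descriptors raise
    :class:`UndefinedDescriptorError` (e.g. the torsion of a locally straight
    trace is undefined, so a straight stretch cannot be classified).
    """
    if kappa is None or tau is None or not (math.isfinite(kappa) and math.isfinite(tau)):
        raise UndefinedDescriptorError(
            "undefined descriptor: classification needs defined curvature and torsion"
        )
    if (
        abs(kappa - rules.helix_kappa) <= rules.helix_kappa_tol
        and abs(tau - rules.helix_tau) <= rules.helix_tau_tol
    ):
        return "helix"
    if kappa >= rules.strand_kappa_min and abs(tau) <= rules.strand_tau_max:
        return "strand"
    return "other"


@dataclass
class PropensityTable:
    """Environment-class x amino-acid score matrix.

    Plain-text format: comment lines start with ``#``; the header row lists
    the 20 one-letter amino-acid codes; each following row is a class id
    followed by 20 numbers (whitespace-separated).
    """

    environment_classes: list[str]
    scores: np.ndarray  # (n_classes, 20)
    metadata: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.environment_classes), len(AMINO_ACIDS)):
            raise MalformedTableError(
                f"malformed table: scores shape {self.scores.shape} does not "
                f"match {len(self.environment_classes)} classes x 20 amino acids"
            )
        if not np.all(np.isfinite(self.scores)):
            raise MalformedTableError("malformed table: non-finite score")

    def row(self, environment_class: str) -> np.ndarray:
        return self.scores[self.environment_classes.index(environment_class)]

    def score(self, environment_class: str, amino_acid: str) -> float:
        return float(self.row(environment_class)[AMINO_ACIDS.index(amino_acid.upper())])

    def normalized(self) -> "PropensityTable":
        """Rows rescaled to probabilities (each row sums to 1)."""
        sums = self.scores.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise MalformedTableError("malformed table: non-positive row sum")
        return PropensityTable(
            list(self.environment_classes), self.scores / sums, self.metadata
        )


def load_propensity_table(text: str, *, normalize: bool = False) -> PropensityTable:
    """Parse a plain-text propensity table (see :class:`PropensityTable`)."""
    meta_lines = []
    rows = []
    header: list[str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            meta_lines.append(line.lstrip("# "))
            continue
        fields = line.split()
        if header is None:
            header = [f.upper() for f in fields]
            if len(header) != 20 or sorted(header) != sorted(AMINO_ACIDS):
                raise MalformedTableError(
                    "malformed table: header must list the 20 amino-acid codes"
                )
            continue
        if len(fields) != 21:
            raise MalformedTableError(
                f"malformed table: row {fields[0]!r} has {len(fields) - 1} "
                "values (expected 20)"
            )
        try:
            values = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise MalformedTableError(f"parse error: non-numeric value in row {fields[0]!r}") from exc
        rows.append((fields[0], values))
    if header is None or not rows:
        raise MalformedTableError("malformed table: missing header or class rows")
    # reorder columns to canonical amino-acid order
    perm = [header.index(aa) for aa in AMINO_ACIDS]
    classes = [name for name, _ in rows]
    scores = np.array([[vals[j] for j in perm] for _, vals in rows])
    table = PropensityTable(classes, scores, "; ".join(meta_lines))
    return table.normalized() if normalize else table


def dump_propensity_table(table: PropensityTable) -> str:
    """Serialize a table back to the plain-text format (round-trips)."""
    lines = []
    if table.metadata:
        lines.append(f"# {table.metadata}")
    lines.append(" ".join(AMINO_ACIDS))
    for cls, row in zip(table.environment_classes, table.scores):
        lines.append(cls + " " + " ".join(f"{v:.6g}" for v in row))
    return "\n".join(lines) + "\n"


@dataclass
class DescriptorPDF:
    """Gaussian-kernel density over (curvature, torsion) for one class.

    Diagonal bandwidth, Scott's rule per dimension
    (``h_j = sigma_j * n**(-1/6)`` for 2D data) with a small floor so that
    degenerate sample sets (all points identical) yield a density sharply
    concentrated at that point.  Evaluation is deterministic; sampling is
    reproducible given a seed.
    """

    environment_class: str
    samples: np.ndarray  # (n, 2): (kappa, tau)
    bandwidth: np.ndarray = field(default=None)  # (2,), set in __post_init__

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[1] != 2:
            raise ValueError("samples must be (n, 2)")
        if self.bandwidth is None:
            n = len(self.samples)
            sigma = self.samples.std(axis=0, ddof=1) if n > 1 else np.zeros(2)
            h = sigma * n ** (-1.0 / 6.0)
            self.bandwidth = np.maximum(h, BANDWIDTH_FLOOR)
        else:
            self.bandwidth = np.asarray(self.bandwidth, dtype=float)
            if np.any(self.bandwidth <= 0):
                raise ValueError("bandwidth must be positive")

    def evaluate(self, points) -> np.ndarray:
        """Density at (m, 2) points; non-negative, integrates to 1."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = self.bandwidth
        norm = 1.0 / (len(self.samples) * 2.0 * np.pi * h[0] * h[1])
        out = np.empty(len(pts))
        for i in range(0, len(pts), 1024):  # chunked to bound memory
            block = pts[i : i + 1024]
            z = (block[:, None, :] - self.samples[None, :, :]) / h
            out[i : i + 1024] = norm * np.exp(-0.5 * np.sum(z * z, axis=2)).sum(axis=1)
        return out

    def sample(self, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
        """Draw ``n`` (kappa, tau) points; bit-reproducible for a fixed seed."""
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        idx = rng.integers(0, len(self.samples), size=n)
        return self.samples[idx] + rng.standard_normal((n, 2)) * self.bandwidth

    def bounding_box(self, k: float = 6.0) -> tuple[tuple[float, float], tuple[float, float]]:
        """((kappa_lo, kappa_hi), (tau_lo, tau_hi)) covering all kernels to k bandwidths."""
        lo = self.samples.min(axis=0) - k * self.bandwidth
        hi = self.samples.max(axis=0) + k * self.bandwidth
        return ((float(lo[0]), float(hi[0])), (float(lo[1]), float(hi[1])))

    def box_mass(self, box=None) -> float:
        """Exact probability mass inside a box (analytic, via the normal CDF)."""
        from scipy.stats import norm as _norm

        if box is None:
            box = self.bounding_box()
        (x0, x1), (y0, y1) = box
        h = self.bandwidth
        px = _norm.cdf((x1 - self.samples[:, 0]) / h[0]) - _norm.cdf(
            (x0 - self.samples[:, 0]) / h[0]
        )
        py = _norm.cdf((y1 - self.samples[:, 1]) / h[1]) - _norm.cdf(
            (y0 - self.samples[:, 1]) / h[1]
        )
        return float(np.mean(px * py))

    def mode(self, grid: int = 201) -> tuple[float, float]:
        """Grid-search mode of the density over the bounding box."""
        (x0, x1), (y0, y1) = self.bounding_box(k=1.0)
        xs = np.linspace(x0, x1, grid)
        ys = np.linspace(y0, y1, grid)
        gx, gy = np.meshgrid(xs, ys)
        dens = self.evaluate(np.column_stack([gx.ravel(), gy.ravel()]))
        i = int(np.argmax(dens))
        return float(gx.ravel()[i]), float(gy.ravel()[i])


def build_descriptor_pdfs(
    tables: Iterable[GeometryTable],
    classify: Callable[[float, float], str] = classify_geometry,
    *,
    min_samples: int = MIN_CLASS_SAMPLES,
) -> dict[str, DescriptorPDF]:
    """Kernel density over (kappa, tau) per environment class.

    Residues with undefined curvature or torsion are skipped; classes with
    fewer than ``min_samples`` residues are skipped with a warning.
    """
    by_class: dict[str, list[tuple[float, float]]] = {}
    for table in tables:
        for rec in table:
            if rec.curvature is None or rec.torsion is None:
                continue
            cls = classify(rec.curvature, rec.torsion)
            by_class.setdefault(cls, []).append((rec.curvature, rec.torsion))
    pdfs = {}
    for cls, pts in sorted(by_class.items()):
        if len(pts) < min_samples:
            warnings.warn(
                f"class {cls!r} has only {len(pts)} residues (< {min_samples}); skipped",
                stacklevel=2,
            )
            continue
        pdfs[cls] = DescriptorPDF(cls, np.asarray(pts))
    return pdfs
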