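"""Differential-geometry and knot-theory descriptors for protein C-alpha traces.

The package fits interpolating cubic splines through backbone C-alpha
positions, computes Frenet curvature and torsion per residue via Chebyshev
differentiation, evaluates the five-residue writhing number, and uses those
descriptors for metric comparison, geometry-based classification,
alignment-column clustering and annotated structure output.
"""

from .errors import CurvatraceError
from .fixtures import FixtureSpec, generate_fixture
from .geometry import (
    BackboneCurve,
    GeometryTable,
    ResidueGeometry,
    arc_length_at,
    chebyshev_derivatives,
    curvature_torsion_at,
    describe_structure,
    fit_backbone_curve,
)
from .pdbio import (
    StructureTrace,
    read_calpha_trace,
    write_bfactor_pdb,
    write_pymol_script,
)
from .writhe import WritheWindow, segment_pair_writhe, writhe_at

__version__ = "0.1.0"


def describe_trace(trace: StructureTrace, **kwargs) -> GeometryTable:
    """Per-residue geometric descriptors for a parsed structure trace.

    Convenience wrapper: unpacks the trace's chains and runs
    :func:`describe_structure` with the structure's id and insertion codes.
    """
    chains, icodes = trace.to_chain_inputs()
    return describe_structure(
        chains,
        structure_id=trace.structure_id,
        insertion_codes=icodes,
        **kwargs,
    )

__all__ = [
    "BackboneCurve",
    "CurvatraceError",
    "FixtureSpec",
    "GeometryTable",
    "ResidueGeometry",
    "StructureTrace",
    "WritheWindow",
    "arc_length_at",
    "chebyshev_derivatives",
    "curvature_torsion_at",
    "describe_structure",
    "describe_trace",
    "fit_backbone_curve",
    "generate_fixture",
    "read_calpha_trace",
    "segment_pair_writhe",
    "write_bfactor_pdb",
    "write_pymol_script",
    "writhe_at",
]
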