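"""Cluster alignment columns of a small family by local backbone geometry.

Builds a three-member family — two all-helical structures and one whose
second half mirrors to a left-handed helix — maps a gapless alignment onto
them, clusters each column's (curvature, torsion, writhe) vectors, and
prints the annotated alignment plus the first lines of the companion PyMOL
script.  Identical colours in both outputs mark geometrically equivalent
blocks.
"""

import numpy as np

from curvatrace import FixtureSpec, describe_trace
from curvatrace.alignment import (
    cluster_alignment_columns,
    load_alignment,
    map_alignment_to_structures,
    render_annotated_alignment,
)
from curvatrace.pdbio import Residue, StructureTrace


def make_trace(sid, coords):
    residues = [
        Residue(i + 1, "", "ALA", tuple(map(float, p)), 0.0, 1.0)
        for i, p in enumerate(coords)
    ]
    return StructureTrace(sid, [("A", residues)])


n = 30
helix = FixtureSpec.helix(n).coordinates()
kinked = helix.copy()
kinked[12:] = helix[11] + (helix[12:] - helix[11]) * np.array([1.0, 1.0, -1.0])

traces = {
    "helA": make_trace("helA", helix),
    "helB": make_trace("helB", helix),
    "kink": make_trace("kink", kinked),
}
seq = "A" * n
alignment = load_alignment("".join(f">{s}\n{seq}\n" for s in traces))
mapping = map_alignment_to_structures(alignment, traces)
geometry = {s: describe_trace(traces[s]) for s in traces}

annotation = cluster_alignment_columns(
    mapping, geometry, cutoff=1.0, alignment_rows=[str(rec.seq) for rec in alignment]
)
report, pml = render_annotated_alignment(annotation)
print(report)
print("PyMOL script head:")
print("\n".join(pml.splitlines()[:10]))
print(
    "\nLabel 1 (red) marks geometry shared by all three chains; label 2 "
    "(blue) marks the\nmirrored tail of 'kink', which separates from the "
    "helical pair.  Unlabelled columns\n('.') have undefined descriptors "
    "(chain termini) or fall in blocks shorter than 3."
)
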