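"""Descriptor-based annotation of multiple sequence alignments.

Each aligned sequence is backed by a structure; per-residue descriptors
(curvature, torsion, writhe) are mapped onto alignment columns, compared
with a weighted Euclidean distance — a true metric, unlike RMSD, so
agglomerative clustering is well behaved — and each column's residues are
grouped into clusters of equivalent local geometry.  Runs of consecutive
columns with an identical partition form "blocks"; short runs are treated as
noise and unlabelled.  Cluster labels map to a fixed colour palette so that
the plain-text alignment report and the PyMOL script colour the same
residues identically.

Descriptors are standardized (pooled mean/SD over the whole family, per
descriptor) before distances are computed, so the clustering cutoff is
comparable across families; the cutoff, weights, linkage and block length
are all configurable — local similarity is a user-adjustable criterion.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import AlignIO

from .errors import (
    AlignmentMismatchError,
    NothingToClusterError,
    UndefinedDescriptorError,
)
from .geometry import GeometryTable
from .pdbio import StructureTrace, write_pymol_script
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "AlignmentAnnotation",
    "AlignmentMapping",
    "DescriptorVector",
    "cluster_alignment_columns",
    "descriptor_distance",
    "load_alignment",
    "map_alignment_to_structures",
    "render_annotated_alignment",
]

GAP_CHARS = "-."

#: deterministic cluster palette (PyMOL colour names); cycles if exhausted
PALETTE = (
    "red", "blue", "green", "yellow", "magenta", "cyan", "orange",
    "salmon", "purple", "teal", "wheat", "pink", "limegreen", "slate",
)

DEFAULT_CUTOFF = 1.0  # in pooled-standardized descriptor units
DEFAULT_MIN_BLOCK_LEN = 3
DEFAULT_WEIGHTS = (1.0, 1.0, 1.0)  # (curvature, torsion, writhe)


@dataclass(frozen=True)
class DescriptorVector:
    """(curvature, torsion, writhe) of one residue, with distance weights."""

    curvature: float
    torsion: float
    writhe: float
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS

    def as_array(self) -> np.ndarray:
        return np.array([self.curvature, self.torsion, self.writhe], dtype=float)


def descriptor_distance(a: DescriptorVector, b: DescriptorVector) -> float:
    """Weighted Euclidean distance ``sqrt(sum w_k (a_k - b_k)^2)``.

    A metric: non-negative, zero iff componentwise equal (positive weights),
    symmetric, and satisfying the triangle inequality — which RMSD does not,
    and which clustering algorithms rely on.
    """
    for v in (a, b):
        for comp in (v.curvature, v.torsion, v.writhe):
            if comp is None or not math.isfinite(comp):
                raise UndefinedDescriptorError(
                    "undefined descriptor: distance requires all components defined"
                )
    w = np.asarray(a.weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    d = a.as_array() - b.as_array()
    return float(np.sqrt(np.sum(w * d * d)))


def load_alignment(text: str, fmt: str | None = None):
    """Read an MSA from FASTA or Clustal text (auto-detected by default)."""
    if fmt is None:
        stripped = text.lstrip()
        fmt = "clustal" if stripped.upper().startswith("CLUSTAL") else "fasta"
    return AlignIO.read(io.StringIO(text), fmt)


@dataclass
class AlignmentMapping:
    """Bijection between non-gap alignment cells and trace residues.

    ``index[s, c]`` is the 0-based residue position (file order over all
    chains) of sequence ``s`` at column ``c``, or -1 at a gap.
    """

    seq_ids: list[str]
    traces: dict[str, StructureTrace]
    index: np.ndarray  # (n_seqs, n_cols) int

    @property
    def n_columns(self) -> int:
        return self.index.shape[1]

    def residue_ref(self, seq_id: str, column: int):
        """(chain, resseq, icode) at a cell, or None at a gap."""
        s = self.seq_ids.index(seq_id)
        pos = int(self.index[s, column])
        if pos < 0:
            return None
        chain_id, res = self.traces[seq_id].residues[pos]
        return (chain_id, res.author_seq, res.insertion_code)


def map_alignment_to_structures(
    alignment,
    traces: Mapping[str, StructureTrace],
) -> AlignmentMapping:
    """Map every non-gap alignment cell to its structure residue.

    Each sequence's ungapped letters must equal the one-letter sequence of
    its trace (nonstandard residues compare as X, MSE as M); any discrepancy
    raises :class:`AlignmentMismatchError` naming the sequence and the first
    differing position.
    """
    seq_ids = [rec.id for rec in alignment]
    missing = [sid for sid in seq_ids if sid not in traces]
    if missing:
        raise AlignmentMismatchError(
            f"alignment/structure mismatch: no structure for sequence(s) {missing}"
        )
    n_cols = alignment.get_alignment_length()
    index = np.full((len(seq_ids), n_cols), -1, dtype=int)
    for s, rec in enumerate(alignment):
        trace_seq = traces[rec.id].one_letter_sequence()
        ungapped = str(rec.seq).replace("-", "").replace(".", "").upper()
        if len(ungapped) != len(trace_seq):
            raise AlignmentMismatchError(
                f"alignment/structure mismatch: sequence {rec.id} has "
                f"{len(ungapped)} residues, structure has {len(trace_seq)}"
            )
        for k, (a, b) in enumerate(zip(ungapped, trace_seq)):
            if a != b and a != "X" and b != "X":
                raise AlignmentMismatchError(
                    f"alignment/structure mismatch: sequence {rec.id} differs "
                    f"from structure at ungapped position {k + 1} ({a} vs {b})"
                )
        pos = 0
        for c, letter in enumerate(str(rec.seq)):
            if letter in GAP_CHARS:
                continue
            index[s, c] = pos
            pos += 1
    return AlignmentMapping(seq_ids, dict(traces), index)


@dataclass
class ColumnAnnotation:
    """One alignment column: residue refs, cluster labels and colours per sequence."""

    residues: list[tuple | None]  # (chain, resseq, icode) or None at gaps
    labels: list[int | None]  # cluster label per sequence, None if unlabelled


@dataclass
class AlignmentAnnotation:
    """Cluster labels and colours mapping aligned residues to geometric blocks."""

    seq_ids: list[str]
    columns: list[ColumnAnnotation]
    alignment_rows: list[str]  # aligned sequence strings, for rendering
    palette: tuple[str, ...] = PALETTE

    def colour_of(self, label: int | None) -> str | None:
        """Colour name for a cluster label; pure function of the label."""
        if label is None:
            return None
        return self.palette[(label - 1) % len(self.palette)]


def _descriptor_rows(mapping: AlignmentMapping, geometry: Mapping[str, GeometryTable]):
    """Per sequence: array (n_residues, 3) of (kappa, tau, Wr), NaN if undefined."""
    rows = {}
    for sid in mapping.seq_ids:
        table = geometry[sid]
        n_res = len(mapping.traces[sid].residues)
        if len(table) != n_res:
            raise ValueError(
                f"geometry table for {sid} has {len(table)} rows, trace has {n_res}"
            )
        arr = np.full((n_res, 3), np.nan)
        for i, rec in enumerate(table):
            arr[i] = [
                np.nan if rec.curvature is None else rec.curvature,
                np.nan if rec.torsion is None else rec.torsion,
                np.nan if rec.writhe is None else rec.writhe,
            ]
        rows[sid] = arr
    return rows


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters so the cluster containing the first member is 1, etc."""
    out = np.zeros_like(raw)
    next_label = 1
    seen: dict[int, int] = {}
    for v in raw:
        if v not in seen:
            seen[v] = next_label
            next_label += 1
    for i, v in enumerate(raw):
        out[i] = seen[v]
    return out


def cluster_alignment_columns(
    mapping: AlignmentMapping,
    geometry: Mapping[str, GeometryTable],
    cutoff: float = DEFAULT_CUTOFF,
    *,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    min_block_len: int = DEFAULT_MIN_BLOCK_LEN,
    standardize: bool = True,
    alignment_rows: Sequence[str] | None = None,
) -> AlignmentAnnotation:
    """Cluster each column's residues into groups of equivalent geometry.

    Per column, the present sequences' descriptor vectors are clustered by
    complete-linkage agglomerative clustering cut at ``cutoff`` (distances in
    pooled-standardized units when ``standardize``).  Labels are assigned
    deterministically: the cluster containing the earliest sequence gets
    label 1, and so on.  Runs of at least ``min_block_len`` consecutive
    columns with an identical partition keep their labels; shorter runs are
    relabelled unclustered.  Columns where any mapped descriptor is
    undefined, or with fewer than two present sequences, carry no label.
    """
    n_seq = len(mapping.seq_ids)
    n_col = mapping.n_columns
    desc = _descriptor_rows(mapping, geometry)

    if standardize:
        pooled = np.vstack([a for a in desc.values()])
        mean = np.nanmean(pooled, axis=0)
        sd = np.nanstd(pooled, axis=0)
        sd[~np.isfinite(sd) | (sd < 1e-12)] = 1.0
        mean[~np.isfinite(mean)] = 0.0
    else:
        mean, sd = np.zeros(3), np.ones(3)
    w = np.sqrt(np.asarray(weights, dtype=float))

    per_column_labels: list[list[int | None]] = []
    partition_keys: list[tuple] = []
    any_clustered = False
    for c in range(n_col):
        labels: list[int | None] = [None] * n_seq
        present = []
        vectors = []
        undefined_present = False
        for s in range(n_seq):
            pos = int(mapping.index[s, c])
            if pos < 0:
                continue
            v = desc[mapping.seq_ids[s]][pos]
            if np.any(~np.isfinite(v)):
                undefined_present = True
                continue
            present.append(s)
            vectors.append((v - mean) / sd * w)
        if not undefined_present and len(present) >= 2:
            x = np.asarray(vectors)
            if len(present) == 2:
                raw = (
                    np.array([1, 1])
                    if np.linalg.norm(x[0] - x[1]) <= cutoff
                    else np.array([1, 2])
                )
            else:
                z = linkage(pdist(x), method="complete")
                raw = fcluster(z, t=cutoff, criterion="distance")
            canon = _canonical_labels(raw)
            for s, lab in zip(present, canon):
                labels[s] = int(lab)
            any_clustered = True
        per_column_labels.append(labels)
        partition_keys.append(tuple(labels))

    if not any_clustered:
        raise NothingToClusterError(
            "nothing to cluster: every column has undefined descriptors or "
            "fewer than two mapped sequences"
        )

    # block smoothing: short runs of identical partitions lose their labels
    c = 0
    while c < n_col:
        run_start = c
        while c < n_col and partition_keys[c] == partition_keys[run_start]:
            c += 1
        run_len = c - run_start
        labelled = any(lab is not None for lab in partition_keys[run_start])
        if labelled and run_len < min_block_len:
            for cc in range(run_start, c):
                per_column_labels[cc] = [None] * n_seq

    columns = []
    for c in range(n_col):
        refs = [mapping.residue_ref(sid, c) for sid in mapping.seq_ids]
        columns.append(ColumnAnnotation(refs, per_column_labels[c]))
    if alignment_rows is None:
        rows = []
        for s, sid in enumerate(mapping.seq_ids):
            chars = []
            for c in range(n_col):
                chars.append("-" if mapping.index[s, c] < 0 else "x")
            rows.append("".join(chars))
    else:
        rows = [str(r) for r in alignment_rows]
    return AlignmentAnnotation(list(mapping.seq_ids), columns, rows)


def _label_char(label: int | None, is_gap: bool) -> str:
    if is_gap:
        return " "
    if label is None:
        return "."
    if label <= 9:
        return str(label)
    return chr(ord("a") + (label - 10) % 26)


def render_annotated_alignment(
    annotation: AlignmentAnnotation,
    *,
    width: int = 60,
    structure_paths: Mapping[str, str] | None = None,
) -> tuple[str, str]:
    """Plain-text report plus companion PyMOL script.

    The report prints the alignment in fixed-width blocks with a label line
    under each sequence (digit = cluster label, ``.`` = unlabelled residue,
    space = gap).  The PyMOL script colours each structure's residues with
    the colour of their column's cluster label, so text and 3D views use one
    palette.
    """
    n_col = len(annotation.columns)
    name_w = max((len(s) for s in annotation.seq_ids), default=0) + 2
    lines = []
    for start in range(0, n_col, width):
        stop = min(start + width, n_col)
        for s, sid in enumerate(annotation.seq_ids):
            seq_line = annotation.alignment_rows[s][start:stop]
            lab_line = "".join(
                _label_char(
                    annotation.columns[c].labels[s],
                    annotation.columns[c].residues[s] is None,
                )
                for c in range(start, stop)
            )
            lines.append(f"{sid:<{name_w}}{seq_line}")
            lines.append(f"{'':<{name_w}}{lab_line}")
        lines.append("")
    header = f"# geometric-equivalence annotation: {len(annotation.seq_ids)} sequences, {n_col} columns\n"
    text = header + "\n".join(lines)

    structures = {
        sid: (structure_paths or {}).get(sid, f"{sid}.pdb")
        for sid in annotation.seq_ids
    }
    residue_colours: dict[str, list[tuple[str, int, str, str]]] = {
        sid: [] for sid in annotation.seq_ids
    }
    for col in annotation.columns:
        for s, sid in enumerate(annotation.seq_ids):
            ref = col.residues[s]
            colour = annotation.colour_of(col.labels[s])
            if ref is not None and colour is not None:
                residue_colours[sid].append((ref[0], ref[1], ref[2], colour))
    for sid in residue_colours:
        residue_colours[sid].sort(key=lambda t: (t[0], t[1], t[2]))
    pml = write_pymol_script(structures, residue_colours)
    return text, pml
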