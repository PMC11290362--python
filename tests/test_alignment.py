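"""Alignment mapping, descriptor metric, column clustering and rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from curvatrace import FixtureSpec, describe_trace
from curvatrace.alignment import (
    DescriptorVector,
    cluster_alignment_columns,
    descriptor_distance,
    load_alignment,
    map_alignment_to_structures,
    render_annotated_alignment,
)
from curvatrace.errors import AlignmentMismatchError, UndefinedDescriptorError
from curvatrace.pdbio import Residue, StructureTrace

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def make_trace(sid, coords, sequence):
    residues = [
        Residue(i + 1, "", AA3[letter], tuple(map(float, xyz)), 0.0, 1.0)
        for i, (letter, xyz) in enumerate(zip(sequence, coords))
    ]
    return StructureTrace(sid, [("A", residues)])


def fasta(rows):
    return "".join(f">{sid}\n{seq}\n" for sid, seq in rows)


def mirrored_tail_helix(n=30, kink=12):
    """Right-handed helix whose tail is mirrored (left-handed) after ``kink``.

    The reflection is applied to displacement vectors from the kink residue,
    so consecutive distances are preserved and the trace stays one segment.
    """
    h = FixtureSpec.helix(n).coordinates()
    out = h.copy()
    m = np.array([1.0, 1.0, -1.0])
    out[kink:] = h[kink - 1] + (h[kink:] - h[kink - 1]) * m
    return out


@pytest.fixture(scope="module")
def divergent_family():
    """s1, s2 helical throughout; s3 switches handedness mid-chain."""
    n = 30
    seq = "A" * n
    helix = FixtureSpec.helix(n).coordinates()
    traces = {
        "s1": make_trace("s1", helix, seq),
        "s2": make_trace("s2", helix, seq),
        "s3": make_trace("s3", mirrored_tail_helix(n), seq),
    }
    alignment = load_alignment(fasta([(sid, seq) for sid in ("s1", "s2", "s3")]))
    mapping = map_alignment_to_structures(alignment, traces)
    geometry = {sid: describe_trace(traces[sid]) for sid in traces}
    return alignment, mapping, geometry


# ------------------------------------------------------------------ mapping
class TestMapping:
    def test_gapless_identity_mapping(self):
        seq = "ACDEFGHIKL"
        coords = FixtureSpec.line(10).coordinates()
        traces = {s: make_trace(s, coords, seq) for s in ("a", "b")}
        mapping = map_alignment_to_structures(
            load_alignment(fasta([("a", seq), ("b", seq)])), traces
        )
        assert np.array_equal(mapping.index, np.tile(np.arange(10), (2, 1)))

    def test_gap_shifts_downstream_residues(self):
        coords10 = FixtureSpec.line(10).coordinates()
        coords9 = FixtureSpec.line(9).coordinates()
        traces = {
            "a": make_trace("a", coords10, "ACDEFGHIKL"),
            "b": make_trace("b", coords9, "ACDFGHIKL"),  # E missing
        }
        mapping = map_alignment_to_structures(
            load_alignment(fasta([("a", "ACDEFGHIKL"), ("b", "ACD-FGHIKL")])), traces
        )
        assert mapping.index[1].tolist() == [0, 1, 2, -1, 3, 4, 5, 6, 7, 8]

    def test_staggered_gap_family_mapping_matches_constructed_truth(self):
        rows = [("x", "ACDEF--GHIKL"), ("y", "-CDEFMNGHIKL"), ("z", "ACDEFMNGHIK-")]
        traces = {}
        for sid, row in rows:
            ungapped = row.replace("-", "")
            coords = FixtureSpec.line(len(ungapped)).coordinates()
            traces[sid] = make_trace(sid, coords, ungapped)
        mapping = map_alignment_to_structures(load_alignment(fasta(rows)), traces)
        for s, (sid, row) in enumerate(rows):
            pos = 0
            for c, letter in enumerate(row):
                expected = -1 if letter == "-" else pos
                assert mapping.index[s, c] == expected
                if letter != "-":
                    pos += 1

    def test_sequence_mismatch_names_sequence_and_position(self):
        coords = FixtureSpec.line(10).coordinates()
        traces = {"a": make_trace("a", coords, "ACDEFGHIKL")}
        with pytest.raises(AlignmentMismatchError, match="sequence a.*position 4"):
            map_alignment_to_structures(
                load_alignment(fasta([("a", "ACDWFGHIKL")])), traces
            )

    def test_clustal_dialect_accepted(self):
        seq = "ACDEFGHIKL"
        text = (
            "CLUSTAL W (1.2) multiple sequence alignment\n\n"
            f"a   {seq}\nb   {seq}\n"
        )
        traces = {
            s: make_trace(s, FixtureSpec.line(10).coordinates(), seq) for s in "ab"
        }
        mapping = map_alignment_to_structures(load_alignment(text), traces)
        assert mapping.n_columns == 10


# ------------------------------------------------------------------- metric
class TestDescriptorDistance:
    def test_identity_symmetry_and_triangle_on_random_triples(self):
        rng = np.random.default_rng(123)
        for _ in range(10_000):
            a, b, c = (
                DescriptorVector(*rng.uniform(-1.0, 1.0, 3)) for _ in range(3)
            )
            dab = descriptor_distance(a, b)
            assert dab >= 0
            assert dab == descriptor_distance(b, a)
            assert descriptor_distance(a, a) == 0.0
            assert descriptor_distance(a, c) <= dab + descriptor_distance(b, c) + 1e-12

    @given(
        st.lists(
            st.floats(-10, 10, allow_nan=False, allow_infinity=False),
            min_size=6,
            max_size=6,
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_zero_iff_equal_with_positive_weights(self, vals):
        a = DescriptorVector(*vals[:3])
        b = DescriptorVector(*vals[3:])
        d = descriptor_distance(a, b)
        if vals[:3] == vals[3:]:
            assert d == 0.0
        else:
            assert d > 0.0

    def test_undefined_component_rejected(self):
        a = DescriptorVector(0.1, float("nan"), 0.0)
        with pytest.raises(UndefinedDescriptorError, match="undefined descriptor"):
            descriptor_distance(a, a)


# --------------------------------------------------------------- clustering
class TestClusterAlignmentColumns:
    def test_identical_family_single_cluster(self):
        n = 30
        seq = "A" * n
        helix = FixtureSpec.helix(n).coordinates()
        traces = {s: make_trace(s, helix, seq) for s in ("s1", "s2", "s3")}
        mapping = map_alignment_to_structures(
            load_alignment(fasta([(s, seq) for s in traces])), traces
        )
        geometry = {s: describe_trace(traces[s]) for s in traces}
        ann = cluster_alignment_columns(mapping, geometry)
        labelled = [c for c in ann.columns if any(l is not None for l in c.labels)]
        assert labelled, "helical family should produce labelled columns"
        for col in labelled:
            assert set(col.labels) == {1}

    def test_divergent_block_splits_into_two_clusters(self, divergent_family):
        _, mapping, geometry = divergent_family
        ann = cluster_alignment_columns(mapping, geometry)
        # deep in the mirrored tail: s1+s2 vs s3
        for c in range(18, 26):
            assert ann.columns[c].labels == [1, 1, 2]
        # early region: all three identical helices
        for c in range(4, 9):
            assert ann.columns[c].labels == [1, 1, 1]

    def test_terminal_columns_with_undefined_descriptors_unlabelled(
        self, divergent_family
    ):
        _, mapping, geometry = divergent_family
        ann = cluster_alignment_columns(mapping, geometry)
        for c in (0, 1, 28, 29):  # writhe undefined at each chain end
            assert ann.columns[c].labels == [None, None, None]

    def test_cutoff_limits(self, divergent_family):
        _, mapping, geometry = divergent_family
        huge = cluster_alignment_columns(mapping, geometry, cutoff=1e9)
        for col in huge.columns:
            defined = [l for l in col.labels if l is not None]
            assert set(defined) <= {1}
        tiny = cluster_alignment_columns(
            mapping, geometry, cutoff=1e-12, min_block_len=1
        )
        tail = tiny.columns[20]
        # identical helices stay together even at tiny cutoff; s3 separates
        assert tail.labels == [1, 1, 2]

    def test_order_invariant_up_to_renaming(self, divergent_family):
        alignment, mapping, geometry = divergent_family
        ann = cluster_alignment_columns(mapping, geometry)
        reordered = load_alignment(
            fasta([("s3", "A" * 30), ("s1", "A" * 30), ("s2", "A" * 30)])
        )
        mapping2 = map_alignment_to_structures(reordered, mapping.traces)
        ann2 = cluster_alignment_columns(mapping2, geometry)
        perm = [mapping2.seq_ids.index(s) for s in mapping.seq_ids]
        for c in range(30):
            l1 = ann.columns[c].labels
            l2 = [ann2.columns[c].labels[p] for p in perm]
            # same partition: equal label <-> equal label
            for i in range(3):
                for j in range(3):
                    assert (l1[i] == l1[j]) == (l2[i] == l2[j])

    def test_short_runs_relabelled_unclustered(self, divergent_family):
        _, mapping, geometry = divergent_family
        ann3 = cluster_alignment_columns(mapping, geometry, min_block_len=3)
        ann_big = cluster_alignment_columns(mapping, geometry, min_block_len=50)
        # with an impossibly long block requirement everything is unlabelled
        for col in ann_big.columns:
            assert col.labels == [None, None, None]
        assert any(any(l is not None for l in c.labels) for c in ann3.columns)


# ---------------------------------------------------------------- rendering
class TestRenderAnnotatedAlignment:
    def test_text_and_pymol_script_agree_label_for_label(self, divergent_family):
        _, mapping, geometry = divergent_family
        ann = cluster_alignment_columns(mapping, geometry)
        text, pml = render_annotated_alignment(ann)
        # every coloured residue in the script carries its column's colour
        expected = set()
        for col in ann.columns:
            for s, sid in enumerate(ann.seq_ids):
                colour = ann.colour_of(col.labels[s])
                if col.residues[s] is not None and colour is not None:
                    expected.add((sid, col.residues[s][1], colour))
        seen = set()
        for line in pml.splitlines():
            if line.startswith("color ") and " and resi " in line:
                colour = line.split()[1].rstrip(",")
                sid = line.split(" and ")[0].split(", ")[1]
                resi = line.rsplit("resi ", 1)[1]
                if "-" in resi:
                    lo, hi = resi.split("-")
                    for r in range(int(lo), int(hi) + 1):
                        seen.add((sid, r, colour))
                else:
                    seen.add((sid, int(resi), colour))
        assert seen == expected

    def test_deterministic_palette_and_output(self, divergent_family):
        _, mapping, geometry = divergent_family
        ann = cluster_alignment_columns(mapping, geometry)
        assert ann.colour_of(1) == "red" and ann.colour_of(2) == "blue"
        assert render_annotated_alignment(ann) == render_annotated_alignment(ann)

    def test_single_cluster_single_colour(self):
        n = 30
        seq = "A" * n
        helix = FixtureSpec.helix(n).coordinates()
        traces = {s: make_trace(s, helix, seq) for s in ("s1", "s2")}
        mapping = map_alignment_to_structures(
            load_alignment(fasta([(s, seq) for s in traces])), traces
        )
        geometry = {s: describe_trace(traces[s]) for s in traces}
        ann = cluster_alignment_columns(mapping, geometry)
        _, pml = render_annotated_alignment(ann)
        colours = {
            line.split()[1].rstrip(",")
            for line in pml.splitlines()
            if line.startswith("color ") and " and resi " in line
        }
        assert colours == {"red"}
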