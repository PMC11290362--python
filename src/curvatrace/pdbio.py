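"""PDB-format C-alpha trace reading and descriptor-annotated output.

Reading and writing operate directly on the fixed-width text records rather
than through a structure-object library: the annotation contract is that a
descriptor value is written into the b-factor columns (61-66) of every atom
of a residue while *every other byte of the file is preserved*, which
requires column-level control.  An independent parser (Biopython) is used in
the test suite to cross-check residue counts and coordinates.

Only C-alpha atoms are retained.  HETATM records are ignored except
selenomethionine (MSE), which is optionally kept as methionine.  Alternate
locations are resolved per residue (default: highest occupancy, ties broken
alphabetically); for multi-model files only the first model is read by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptyTraceError, PDBParseError

__all__ = [
    "Residue",
    "StructureTrace",
    "read_calpha_trace",
    "write_bfactor_pdb",
    "write_pymol_script",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine
}

#: b-factor writing limits: %6.2f fixed-width field
BFACTOR_MIN = -99.99
BFACTOR_MAX = 999.99
DEFAULT_SENTINEL = 0.0


@dataclass(frozen=True)
class Residue:
    """One residue's retained C-alpha record."""

    author_seq: int
    insertion_code: str  # "" when blank
    name: str  # 3-letter code
    calpha: tuple[float, float, float]  # angstrom
    bfactor: float
    occupancy: float

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class StructureTrace:
    """C-alpha trace of one structure: chains in file order, residues in author order."""

    structure_id: str
    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def get_chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(chain_id)

    @property
    def residues(self) -> list[tuple[str, Residue]]:
        """All (chain_id, residue) pairs in file order."""
        return [(cid, r) for cid, rs in self.chains for r in rs]

    def one_letter_sequence(self) -> str:
        """Concatenated one-letter sequence over all chains (X for nonstandard)."""
        return "".join(r.one_letter for _, r in self.residues)

    def to_chain_inputs(self):
        """``(chain_id, coords, residue_ids, residue_names)`` per chain,
        ready for :func:`curvatrace.geometry.describe_structure` (plus an
        insertion-code map under the same chain ids)."""
        chains = []
        icodes: dict[str, list[str]] = {}
        for cid, residues in self.chains:
            coords = np.array([r.calpha for r in residues], dtype=float)
            ids = [r.author_seq for r in residues]
            names = [r.name for r in residues]
            icodes[cid] = [r.insertion_code for r in residues]
            chains.append((cid, coords, ids, names))
        return chains, icodes


def _parse_atom_line(line: str, lineno: int):
    """Fields of an ATOM/HETATM record needed for trace building."""
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(f"parse error at line {lineno}: record shorter than 54 columns")
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if len(line) >= 66 and line[60:66].strip() else 0.0
    except ValueError as exc:
        raise PDBParseError(f"parse error at line {lineno}: {exc}") from exc
    return name, altloc, resname, chain, resseq, icode, (x, y, z), occ, bfac


def read_calpha_trace(
    pdb_text: str,
    *,
    structure_id: str = "structure",
    model_policy: str = "first",
    altloc_policy: str = "occupancy",
    include_mse: bool = True,
) -> StructureTrace:
    """Parse PDB-format text into a :class:`StructureTrace`.

    Parameters
    ----------
    model_policy : ``"first"`` (default) keeps only the first MODEL block;
        ``"all"`` merges every model (rarely wanted).
    altloc_policy : ``"occupancy"`` keeps the highest-occupancy alternate
        location (ties -> first alphabetically, blank before 'A');
        ``"A"`` keeps only blank or 'A' altlocs.
    include_mse : treat HETATM MSE (selenomethionine) as a residue.

    Raises
    ------
    EmptyTraceError
        no C-alpha atom passed the policies.
    PDBParseError
        malformed fixed-width record (message carries the line number).
    """
    if altloc_policy not in ("occupancy", "A"):
        raise ValueError("altloc_policy must be 'occupancy' or 'A'")
    # candidates[(chain, resseq, icode)] -> list of (altloc, occ, residue)
    candidates: dict[tuple[str, int, str], list[tuple[str, float, Residue]]] = {}
    order: list[tuple[str, int, str]] = []
    model_no = 0
    seen_first_model_end = False
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            model_no += 1
            if model_no > 1:
                seen_first_model_end = True
            continue
        if rec.startswith("ENDMDL"):
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if model_policy == "first" and seen_first_model_end:
            continue
        name, altloc, resname, chain, resseq, icode, xyz, occ, bfac = _parse_atom_line(
            line, lineno
        )
        if name != "CA":
            continue
        if rec == "HETATM" and not (include_mse and resname == "MSE"):
            continue
        if altloc_policy == "A" and altloc not in ("", "A"):
            continue
        key = (chain, resseq, icode)
        if key not in candidates:
            candidates[key] = []
            order.append(key)
        candidates[key].append(
            (altloc, occ, Residue(resseq, icode, resname, xyz, bfac, occ))
        )
    if not candidates:
        raise EmptyTraceError(f"empty trace: no C-alpha atoms in {structure_id}")

    trace = StructureTrace(structure_id)
    current_chain: str | None = None
    for key in order:
        chain = key[0]
        # highest occupancy; ties -> lexicographically smallest altloc
        best = min(candidates[key], key=lambda t: (-t[1], t[0]))
        if chain != current_chain:
            trace.chains.append((chain, []))
            current_chain = chain
        trace.chains[-1][1].append(best[2])
    return trace


def write_bfactor_pdb(
    pdb_text: str,
    per_residue_values: Mapping[tuple, float | None],
    *,
    sentinel: float = DEFAULT_SENTINEL,
) -> str:
    """Write per-residue values into the b-factor columns of a PDB file.

    Keys of ``per_residue_values`` are ``(chain, resseq)`` or
    ``(chain, resseq, icode)``; every atom of a keyed residue gets the value
    in columns 61-66 (%6.2f, clamped to [-99.99, 999.99]).  A ``None`` value
    (descriptor flagged undefined) writes the ``sentinel`` instead.  Residues
    not present as keys — and every other column of the file — are
    byte-identical to the input.  Keys matching no residue produce a warning
    and are skipped.
    """
    values: dict[tuple[str, int, str], float | None] = {}
    for key, val in per_residue_values.items():
        if len(key) == 2:
            key = (key[0], key[1], "")
        values[(key[0], int(key[1]), key[2])] = val
    used: set[tuple[str, int, str]] = set()

    out_lines = []
    for lineno, line in enumerate(pdb_text.splitlines(keepends=True), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            _, _, _, chain, resseq, icode, _, _, _ = _parse_atom_line(line, lineno)
            key = (chain, resseq, icode)
            if key in values:
                used.add(key)
                val = values[key]
                val = sentinel if val is None else val
                val = min(max(val, BFACTOR_MIN), BFACTOR_MAX)
                body = line.rstrip("\n")
                eol = line[len(body):]
                body = body.ljust(60)
                tail = body[66:] if len(body) > 66 else ""
                line = f"{body[:60]}{val:6.2f}{tail}{eol}"
        out_lines.append(line)
    unknown = set(values) - used
    if unknown:
        warnings.warn(
            f"b-factor values for {len(unknown)} unknown residue(s) skipped: "
            f"{sorted(unknown)[:5]}",
            stacklevel=2,
        )
    return "".join(out_lines)


def _resi_token(resseq: int, icode: str) -> str:
    return f"{resseq}{icode}" if icode else str(resseq)


def _colour_ranges(residues: Sequence[tuple[str, int, str, str]]):
    """Group (chain, resseq, icode, colour) runs into PyMOL resi selections.

    Consecutive residues (same chain, same colour, increasing resseq with no
    insertion codes) are merged into ``resi a-b`` ranges for compact scripts.
    """
    runs: list[tuple[str, str, list[tuple[int, str]]]] = []  # (chain, colour, members)
    for chain, resseq, icode, colour in residues:
        if (
            runs
            and runs[-1][0] == chain
            and runs[-1][1] == colour
            and not icode
            and not runs[-1][2][-1][1]
            and resseq == runs[-1][2][-1][0] + 1
        ):
            runs[-1][2].append((resseq, icode))
        else:
            runs.append((chain, colour, [(resseq, icode)]))
    for chain, colour, members in runs:
        first, last = members[0], members[-1]
        if len(members) == 1:
            resi = _resi_token(*first)
        else:
            resi = f"{_resi_token(*first)}-{_resi_token(*last)}"
        yield chain, colour, resi


def write_pymol_script(
    structures: Mapping[str, str | None],
    residue_colours: Mapping[str, Iterable[tuple[str, int, str, str]]] | None = None,
    *,
    spectrum: bool = False,
    base_colour: str = "grey80",
) -> str:
    """Deterministic PyMOL (.pml) colouring script.

    Parameters
    ----------
    structures : ordered mapping of object name -> PDB path (``None`` skips
        the load command, for scripts applied to already-loaded objects).
    residue_colours : per structure, ``(chain, resseq, icode, colour_name)``
        tuples; equivalent residues across structures should carry the same
        colour name so sequence-level and 3D views agree.
    spectrum : additionally colour each object by its b-factor spectrum
        (used when values rather than cluster colours were written).

    Identical inputs always produce byte-identical script text.  Empty
    colour lists emit no dangling selections.
    """
    lines = ["# PyMOL colouring script", "bg_color white"]
    for name, path in structures.items():
        if path is not None:
            lines.append(f"load {path}, {name}")
    lines.append("hide everything")
    lines.append("show cartoon")
    lines.append("set cartoon_tube_radius, 0.5")
    for name in structures:
        lines.append(f"color {base_colour}, {name}")
    if residue_colours:
        for name in structures:
            entries = list(residue_colours.get(name, ()))
            for chain, colour, resi in _colour_ranges(entries):
                lines.append(f"color {colour}, {name} and chain {chain} and resi {resi}")
    if spectrum:
        for name in structures:
            lines.append(f"spectrum b, rainbow, {name}")
    lines.append("zoom")
    return "\n".join(lines) + "\n"
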