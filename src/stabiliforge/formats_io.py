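"""File formats and the canonical mutation / numbering conventions.

Everything downstream speaks in terms of the types defined here:

* :class:`StructureModel` — a flat, array-backed view of the standard
  amino-acid ATOM records of a PDB file (author numbering, B-factors kept);
* :class:`Msa` — an aligned FASTA with a designated query row and the
  column <-> query-position map used to translate alignment columns into
  mutation positions;
* :class:`Mutation` — a single substitution ``<wt><position><mut>`` with an
  optional ``<chain>/`` prefix, e.g. ``A/123G`` -> ``A123G`` on chain A;
* :class:`DdgTable` — a mutation -> ddG map (kcal/mol, negative =
  stabilizing) read from FoldX-PSSM-like, Rosetta-report-like or plain TSV
  exports.
"""

from __future__ import annotations

import io
import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._data import (
    AA_SET,
    GAP_CHARS,
    NONSTANDARD_PARENT,
    THREE_TO_ONE,
)


class FormatError(ValueError):
    """A file violates the expectations of its declared format."""


class MutationSyntaxError(ValueError):
    """A mutation string cannot be parsed or is semantically invalid."""


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ResidueId:
    """Author-numbered residue identifier: (chain, number, insertion code)."""

    chain: str
    number: int
    icode: str = ""

    def __post_init__(self) -> None:
        if not self.chain:
            raise ValueError("chain identifier must be non-empty")

    def __str__(self) -> str:
        return f"{self.chain}/{self.number}{self.icode}"


class StructureModel:
    """Array-backed protein structure restricted to standard amino acids.

    Parallel per-atom arrays (biotite-style): chain id, residue number,
    insertion code, residue name (3-letter), atom name, element, xyz
    coordinates in Angstrom, occupancy and B-factor.
    """

    def __init__(
        self,
        chain_id: np.ndarray,
        res_number: np.ndarray,
        icode: np.ndarray,
        res_name: np.ndarray,
        atom_name: np.ndarray,
        element: np.ndarray,
        coord: np.ndarray,
        occupancy: np.ndarray,
        bfactor: np.ndarray,
    ) -> None:
        n = len(chain_id)
        for arr in (res_number, icode, res_name, atom_name, element,
                    occupancy, bfactor):
            if len(arr) != n:
                raise ValueError("annotation arrays must have equal length")
        if coord.shape != (n, 3):
            raise ValueError("coord must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(coord)):
            raise ValueError("coordinates must be finite")
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.res_number = np.asarray(res_number, dtype=int)
        self.icode = np.asarray(icode, dtype="U1")
        self.res_name = np.asarray(res_name, dtype="U3")
        self.atom_name = np.asarray(atom_name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.coord = np.asarray(coord, dtype=float)
        self.occupancy = np.asarray(occupancy, dtype=float)
        self.bfactor = np.asarray(bfactor, dtype=float)
        self._index_residues()

    def _index_residues(self) -> None:
        self._residue_ids: list[ResidueId] = []
        self._residue_names: list[str] = []
        self._residue_atoms: dict[ResidueId, np.ndarray] = {}
        order: dict[ResidueId, list[int]] = {}
        names: dict[ResidueId, str] = {}
        for i in range(len(self.chain_id)):
            rid = ResidueId(str(self.chain_id[i]), int(self.res_number[i]),
                            str(self.icode[i]))
            if rid not in order:
                order[rid] = []
                names[rid] = str(self.res_name[i])
            order[rid].append(i)
        for rid, idx in order.items():
            self._residue_ids.append(rid)
            self._residue_names.append(names[rid])
            self._residue_atoms[rid] = np.asarray(idx, dtype=int)

    # -- basic views --------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.chain_id)

    @property
    def n_residues(self) -> int:
        return len(self._residue_ids)

    @property
    def residue_ids(self) -> list[ResidueId]:
        return list(self._residue_ids)

    @property
    def residue_names(self) -> list[str]:
        return list(self._residue_names)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for rid in self._residue_ids:
            if rid.chain not in seen:
                seen.append(rid.chain)
        return seen

    def residue_atom_indices(self, rid: ResidueId) -> np.ndarray:
        return self._residue_atoms[rid]

    def residue_name(self, rid: ResidueId) -> str:
        i = self._residue_ids.index(rid)
        return self._residue_names[i]

    def sequence(self, chain: str | None = None) -> str:
        """One-letter sequence of the given chain (or the single chain)."""
        if chain is None:
            cs = self.chains
            if len(cs) != 1:
                raise ValueError("chain must be given for multi-chain models")
            chain = cs[0]
        letters = []
        for rid, name in zip(self._residue_ids, self._residue_names):
            if rid.chain == chain:
                letters.append(THREE_TO_ONE.get(name, "X"))
        return "".join(letters)

    def chain_positions(self, chain: str | None = None) -> list[int]:
        """Author residue numbers of a chain, in file order."""
        if chain is None:
            chain = self.chains[0]
        return [rid.number for rid in self._residue_ids if rid.chain == chain]

    def subset(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.chain_id[mask], self.res_number[mask], self.icode[mask],
            self.res_name[mask], self.atom_name[mask], self.element[mask],
            self.coord[mask], self.occupancy[mask], self.bfactor[mask],
        )

    # -- biotite interop ----------------------------------------------------

    def to_atom_array(self):
        import biotite.structure as struc

        arr = struc.AtomArray(self.n_atoms)
        arr.coord = self.coord.astype(np.float32)
        arr.chain_id = self.chain_id.astype("U4")
        arr.res_id = self.res_number.copy()
        arr.ins_code = self.icode.astype("U1")
        arr.res_name = self.res_name.astype("U3")
        arr.atom_name = self.atom_name.astype("U6")
        arr.element = self.element.astype("U2")
        arr.set_annotation("b_factor", self.bfactor.copy())
        arr.set_annotation("occupancy", self.occupancy.copy())
        return arr

    @classmethod
    def from_atom_array(cls, arr) -> "StructureModel":
        bf = (arr.b_factor if "b_factor" in arr.get_annotation_categories()
              else np.zeros(arr.array_length()))
        occ = (arr.occupancy if "occupancy" in arr.get_annotation_categories()
               else np.ones(arr.array_length()))
        ins = (arr.ins_code if "ins_code" in arr.get_annotation_categories()
               else np.full(arr.array_length(), "", dtype="U1"))
        return cls(arr.chain_id, arr.res_id, ins, arr.res_name,
                   arr.atom_name, arr.element, np.asarray(arr.coord, float),
                   occ, bf)


def read_pdb(path: str | Path, chains: Iterable[str] | None = None) -> StructureModel:
    """Read the standard-amino-acid ATOM content of a PDB file.

    HETATM records, waters and non-standard residues are dropped
    (selenomethionine is renamed to MET and kept); for alternate locations
    only the highest-occupancy conformer is retained.  ``chains`` limits the
    model to the given chain identifiers.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(
            model=1, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
        )
    except Exception as exc:  # biotite raises various error types
        raise FormatError(f"cannot parse PDB file {path.name}: {exc}") from exc

    names = arr.res_name
    for alias, parent in NONSTANDARD_PARENT.items():
        names[names == alias] = parent
    standard = np.isin(names, list(THREE_TO_ONE))
    dropped = set(np.unique(names[~standard])) - {"HOH"}
    if dropped:
        warnings.warn(
            f"dropping non-standard residues: {sorted(dropped)}", stacklevel=2
        )
    arr = arr[standard]
    if chains is not None:
        wanted = {str(c) for c in chains}
        arr = arr[np.isin(arr.chain_id, list(wanted))]
    if arr.array_length() == 0:
        raise FormatError(
            f"{path.name}: no standard amino-acid ATOM records"
            + (" in the selected chains" if chains is not None else "")
        )
    if np.any(arr.b_factor < 0):
        warnings.warn("negative B-factors set to 0", stacklevel=2)
        arr.b_factor[arr.b_factor < 0] = 0.0
    return StructureModel.from_atom_array(arr)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` back to PDB ATOM records."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(model.to_atom_array())
    Path(path).write_text("\n".join(pdb.lines) + "\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class Msa:
    """Aligned sequences with a designated query row.

    ``col_to_pos`` maps alignment columns to 1-based query positions,
    skipping columns gapped in the query; ``pos_to_col`` is its inverse.
    """

    ids: list[str]
    rows: list[str]
    query_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment contains no sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        try:
            self.query_index = self.ids.index(self.query_id)
        except ValueError:
            raise KeyError(
                f"query id {self.query_id!r} not present in the alignment"
            ) from None
        self.rows = [r.upper() for r in self.rows]
        self.col_to_pos: dict[int, int] = {}
        pos = 0
        for c, ch in enumerate(self.rows[self.query_index]):
            if ch not in GAP_CHARS:
                pos += 1
                self.col_to_pos[c] = pos
        self.pos_to_col = {p: c for c, p in self.col_to_pos.items()}

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def query_row(self) -> str:
        return self.rows[self.query_index]

    @property
    def query_sequence(self) -> str:
        return "".join(
            ch for ch in self.query_row if ch not in GAP_CHARS
        )

    def column(self, c: int) -> str:
        return "".join(row[c] for row in self.rows)

    @property
    def matrix(self) -> np.ndarray:
        m = getattr(self, "_matrix", None)
        if m is None:
            m = np.array([list(r) for r in self.rows], dtype="U1")
            self._matrix = m
        return m


def read_aligned_fasta(path: str | Path, query_id: str) -> Msa:
    """Read a precomputed multiple-sequence alignment in aligned FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return Msa(
        ids=[r.id for r in records],
        rows=[str(r.seq) for r in records],
        query_id=query_id,
    )


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read plain (unaligned) FASTA as an ordered id -> sequence map."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Mutation:
    """Single substitution in query numbering: wild type -> mutant."""

    chain: str
    position: int
    wt: str
    mut: str

    def __post_init__(self) -> None:
        if self.wt not in AA_SET or self.mut not in AA_SET:
            raise MutationSyntaxError(
                f"{self.wt}{self.position}{self.mut}: amino acids must be "
                "one of the 20 standard one-letter codes"
            )
        if self.wt == self.mut:
            raise MutationSyntaxError(
                f"{self.wt}{self.position}{self.mut}: silent mutation"
            )

    def __str__(self) -> str:
        return format_mutation(self)


_MUTATION_RE = re.compile(r"^(?:(?P<chain>[A-Za-z0-9]+)/)?"
                          r"(?P<wt>[A-Z])(?P<pos>\d+)(?P<mut>[A-Z])$")


def format_mutation(m: Mutation, with_chain: bool = True) -> str:
    core = f"{m.wt}{m.position}{m.mut}"
    return f"{m.chain}/{core}" if with_chain else core


def parse_mutation(text: str, chains: Sequence[str] | None = None) -> Mutation:
    """Parse ``<chain>/<wt><pos><mut>`` or ``<wt><pos><mut>``.

    Without an explicit chain prefix the chain is inferred only when
    ``chains`` holds exactly one chain id.
    """
    match = _MUTATION_RE.match(text.strip())
    if match is None:
        raise MutationSyntaxError(
            f"{text!r}: expected '<wt><position><mut>' with optional "
            "'<chain>/' prefix, e.g. 'A/123G' or 'A123G'"
        )
    chain = match.group("chain")
    if chain is None:
        if chains is None or len(chains) != 1:
            raise MutationSyntaxError(
                f"{text!r}: chain omitted and not inferable"
            )
        chain = chains[0]
    return Mutation(chain=chain, position=int(match.group("pos")),
                    wt=match.group("wt"), mut=match.group("mut"))


# ---------------------------------------------------------------------------
# ddG tables
# ---------------------------------------------------------------------------

DDG_DIALECTS = ("tsv", "foldx-like", "rosetta-like")


@dataclass
class DdgTable:
    """Mutation -> ddG (kcal/mol; negative = stabilizing)."""

    values: dict[Mutation, float]
    provenance: str = "tsv"

    def __getitem__(self, m: Mutation) -> float:
        return self.values[m]

    def __contains__(self, m: Mutation) -> bool:
        return m in self.values

    def __len__(self) -> int:
        return len(self.values)


def _collect(entries: list[tuple[Mutation, float]], provenance: str) -> DdgTable:
    grouped: dict[Mutation, list[float]] = {}
    for m, v in entries:
        if not np.isfinite(v):
            raise FormatError(f"non-finite ddG for {m}")
        grouped.setdefault(m, []).append(v)
    dupes = [m for m, vs in grouped.items() if len(vs) > 1]
    if dupes:
        warnings.warn(
            f"averaging duplicate ddG entries for {len(dupes)} mutation(s)",
            stacklevel=3,
        )
    return DdgTable(
        values={m: float(np.mean(vs)) for m, vs in grouped.items()},
        provenance=provenance,
    )


def read_ddg_table(path: str | Path, dialect: str, chain: str = "A") -> DdgTable:
    """Read an exported ddG table.

    Dialects:

    * ``tsv`` — two whitespace/tab-separated columns ``<mutation> <ddG>``;
    * ``foldx-like`` — a PSSM grid: header of 20 mutant amino acids, one row
      per position labelled ``<wt><position>``, cells in kcal/mol;
    * ``rosetta-like`` — report lines ``[ddG:] <mutation> <ddG>``.

    Duplicate entries for a mutation are averaged with a warning.
    """
    if dialect not in DDG_DIALECTS:
        raise ValueError(
            f"unknown ddG dialect {dialect!r}; expected one of {DDG_DIALECTS}"
        )
    lines = Path(path).read_text().splitlines()
    entries: list[tuple[Mutation, float]] = []

    def fail(lineno: int, line: str) -> None:
        raise FormatError(f"{path}, line {lineno}: cannot parse {line!r}")

    if dialect in ("tsv", "rosetta-like"):
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if dialect == "rosetta-like" and fields and fields[0] in ("ddG:", "ddg:"):
                fields = fields[1:]
            if len(fields) < 2:
                fail(lineno, raw)
            try:
                m = parse_mutation(fields[0], chains=[chain])
                v = float(fields[1])
            except (MutationSyntaxError, ValueError):
                # tolerate a single header line
                if lineno == 1:
                    continue
                fail(lineno, raw)
                raise  # unreachable; quiets linters
            entries.append((m, v))
    else:  # foldx-like PSSM grid
        header: list[str] | None = None
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if header is None:
                if not all(f in AA_SET for f in fields):
                    fail(lineno, raw)
                header = fields
                continue
            label, *cells = fields
            lm = re.match(r"^([A-Z])(\d+)$", label)
            if lm is None or len(cells) != len(header):
                fail(lineno, raw)
            wt, pos = lm.group(1), int(lm.group(2))
            for aa, cell in zip(header, cells):
                if aa == wt:
                    continue
                try:
                    v = float(cell)
                except ValueError:
                    fail(lineno, raw)
                entries.append(
                    (Mutation(chain=chain, position=pos, wt=wt, mut=aa), v)
                )
    return _collect(entries, provenance=dialect)


# ---------------------------------------------------------------------------
# Design reports
# ---------------------------------------------------------------------------

def write_designs(designs, out_dir: str | Path) -> dict[str, Path]:
    """Write designs as mutant FASTA, a per-mutation CSV and a JSON report.

    ``designs`` is any iterable of objects exposing ``scenario`` (used as
    the design id), ``mutations`` (iterable of :class:`Mutation`),
    ``single_ddgs`` (mutation -> ddG), ``total_score`` and
    ``mutant_sequence``.  Output ordering is deterministic: designs by id,
    mutations by position.
    """
    designs = list(designs)
    if not designs:
        raise ValueError("no designs to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    designs = sorted(designs, key=lambda d: str(d.scenario))
    fasta = io.StringIO()
    csv_lines = ["design,mutation,ddg,source"]
    report = []
    for d in designs:
        muts = sorted(d.mutations, key=lambda m: (m.chain, m.position, m.mut))
        fasta.write(f">{d.scenario} mutations={len(muts)}"
                    f" total_ddg={d.total_score:.3f}\n")
        seq = d.mutant_sequence
        for i in range(0, len(seq), 60):
            fasta.write(seq[i:i + 60] + "\n")
        sources = getattr(d, "metadata", {}).get("sources", {})
        for m in muts:
            csv_lines.append(
                f"{d.scenario},{format_mutation(m)},"
                f"{d.single_ddgs[m]:.4f},{sources.get(m, '')}"
            )
        report.append({
            "design": str(d.scenario),
            "total_ddg": d.total_score,
            "mutations": [
                {
                    "mutation": format_mutation(m),
                    "ddg": d.single_ddgs[m],
                    "source": sources.get(m, ""),
                }
                for m in muts
            ],
            "sequence": seq,
            "metadata": {
                k: v for k, v in getattr(d, "metadata", {}).items()
                if k != "sources"
            },
        })

    paths = {
        "fasta": out_dir / "designs.fasta",
        "csv": out_dir / "designs.csv",
        "json": out_dir / "designs.json",
    }
    paths["fasta"].write_text(fasta.getvalue())
    paths["csv"].write_text("\n".join(csv_lines) + "\n")
    paths["json"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return paths
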