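"""Reading and writing C-alpha traces.

A protein domain enters the pipeline as the ordered sequence of its
C-alpha coordinates.  Two on-disk forms are supported: standard PDB
files (ATOM records, parsed with gemmi) and a plain tabular trace
format (one ``residue_id x y z`` row per residue, tab separated) that
round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from pathlib import Path
from typing import NamedTuple, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

PDB_EXTENSIONS = {".pdb", ".ent"}


class StructureInputError(ValueError):
    """The file cannot be read or is not in a supported format."""


class EmptyTraceError(StructureInputError):
    """No C-alpha atoms remain after filtering."""


class TraceFormatError(StructureInputError):
    """The file parsed but violates the trace contract (e.g. duplicate residues)."""


class ResidueId(NamedTuple):
    chain: str
    seq: int
    icode: str

    def __str__(self) -> str:
        return f"{self.chain}:{self.seq}:{self.icode}"

    @classmethod
    def parse(cls, text: str) -> "ResidueId":
        parts = text.split(":")
        if len(parts) != 3:
            raise TraceFormatError(f"malformed residue id {text!r} (expected chain:seq:icode)")
        return cls(parts[0], int(parts[1]), parts[2])


@dataclasses.dataclass(frozen=True)
class CaTrace:
    """Ordered C-alpha trace of one domain.

    coords are in Angstroms, shape (n_residues, 3); residue_ids has the
    same length and preserves file order.
    """

    residue_ids: tuple[ResidueId, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must have shape (N, 3), got {coords.shape}")
        if len(self.residue_ids) != coords.shape[0]:
            raise ValueError("residue_ids and coords length mismatch")
        if coords.shape[0] < 1:
            raise EmptyTraceError("a trace needs at least one residue")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_residues


def _trace_from_atoms(
    atoms: Sequence[tuple[ResidueId, float, np.ndarray]],
) -> CaTrace:
    """Resolve altlocs (keep highest occupancy, ties -> first seen) and build the trace."""
    best: dict[ResidueId, tuple[float, int, np.ndarray]] = {}
    order: list[ResidueId] = []
    counts: dict[ResidueId, int] = {}
    for idx, (rid, occ, xyz) in enumerate(atoms):
        if rid not in best:
            order.append(rid)
            best[rid] = (occ, idx, xyz)
            counts[rid] = 1
        else:
            counts[rid] += 1
            if occ > best[rid][0]:
                best[rid] = (occ, idx, xyz)
    if not order:
        raise EmptyTraceError("no C-alpha atoms found after filtering")
    coords = np.array([best[rid][2] for rid in order], dtype=float)
    return CaTrace(tuple(order), coords)


def _read_pdb(path: Path, chain: str | None, residue_range: tuple[int, int] | None) -> CaTrace:
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureInputError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(structure) == 0:
        raise EmptyTraceError(f"{path}: no models")
    model = structure[0]
    chain_names = [ch.name for ch in model]
    if chain is None:
        if len(chain_names) > 1:
            logger.warning(
                "%s has %d chains; using first chain %r", path, len(chain_names), chain_names[0]
            )
        selected = chain_names[:1]
    else:
        if chain not in chain_names:
            raise StructureInputError(f"{path}: chain {chain!r} not found (have {chain_names})")
        selected = [chain]

    atoms: list[tuple[ResidueId, float, np.ndarray]] = []
    seen_dup: set[ResidueId] = set()
    altloc_groups: dict[ResidueId, set[str]] = {}
    for ch in model:
        if ch.name not in selected:
            continue
        for res in ch:
            if res.het_flag != "A":  # skip HETATM
                continue
            seq = res.seqid.num
            if residue_range is not None and not (residue_range[0] <= seq <= residue_range[1]):
                continue
            icode = res.seqid.icode.strip()
            rid = ResidueId(ch.name, seq, icode)
            for atom in res:
                if atom.name != "CA" or atom.element.name != "C":
                    continue
                altloc_groups.setdefault(rid, set()).add(atom.altloc or "")
                atoms.append(
                    (rid, atom.occ, np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                )
    # Two CA atoms sharing the same altloc id within one residue are a real
    # duplicate, not an alternate conformation.
    counts = Counter(rid for rid, _, _ in atoms)
    for rid, n in counts.items():
        if n > len(altloc_groups.get(rid, {""})):
            seen_dup.add(rid)
    if seen_dup:
        raise TraceFormatError(f"{path}: duplicate CA records for residues {sorted(map(str, seen_dup))}")
    trace = _trace_from_atoms(atoms)
    _warn_on_gaps(trace, path)
    return trace


def _warn_on_gaps(trace: CaTrace, path: Path) -> None:
    seqs = [rid.seq for rid in trace.residue_ids]
    gaps = [
        (a, b)
        for a, b in zip(seqs, seqs[1:])
        if b - a > 1
    ]
    if gaps:
        logger.warning("%s: %d chain break(s)/missing residue(s): %s", path, len(gaps), gaps[:5])


def _read_table(path: Path, residue_range: tuple[int, int] | None) -> CaTrace:
    try:
        lines = Path(path).read_text().splitlines()
    except OSError as exc:
        raise StructureInputError(f"cannot read {path}: {exc}") from exc
    if not lines or lines[0].split() != ["residue_id", "x", "y", "z"]:
        raise StructureInputError(f"{path}: missing 'residue_id x y z' header")
    ids: list[ResidueId] = []
    coords: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise TraceFormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        rid = ResidueId.parse(parts[0])
        if residue_range is not None and not (residue_range[0] <= rid.seq <= residue_range[1]):
            continue
        try:
            xyz = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise TraceFormatError(f"{path}:{lineno}: non-numeric coordinate") from exc
        if rid in ids:
            raise TraceFormatError(f"{path}:{lineno}: duplicate residue {rid}")
        ids.append(rid)
        coords.append(xyz)
    if not ids:
        raise EmptyTraceError(f"{path}: no residues in range")
    return CaTrace(tuple(ids), np.array(coords))


def read_ca_trace(
    path: str | Path,
    chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
) -> CaTrace:
    """Read the C-alpha trace of one domain.

    Format is chosen by extension: ``.pdb``/``.ent`` are parsed as PDB
    (ATOM records only; one CA per residue is kept, resolving alternate
    locations by highest occupancy, ties to the first in file), anything
    else as the tabular trace format.  ``residue_range`` is an inclusive
    (start, end) filter on residue sequence numbers.
    """
    path = Path(path)
    if not path.exists():
        raise StructureInputError(f"no such file: {path}")
    if path.suffix.lower() in PDB_EXTENSIONS:
        return _read_pdb(path, chain, residue_range)
    if chain is not None:
        raise StructureInputError("chain selection only applies to PDB input")
    return _read_table(path, residue_range)


def write_trace_table(trace: CaTrace, path: str | Path) -> None:
    """Write a trace in the tabular format; read_ca_trace inverts this exactly."""
    path = Path(path)
    rows = ["residue_id\tx\ty\tz"]
    for rid, (x, y, z) in zip(trace.residue_ids, trace.coords):
        rows.append(f"{rid}\t{float(x)!r}\t{float(y)!r}\t{float(z)!r}")
    try:
        path.write_text("\n".join(rows) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write trace to {path}: {exc}") from exc


def write_pdb(trace: CaTrace, path: str | Path) -> None:
    """Write a minimal CA-only PDB file (for interoperability testing)."""
    structure = gemmi.Structure()
    structure.name = "synthetic"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for rid, (x, y, z) in zip(trace.residue_ids, trace.coords):
        chain = chains.get(rid.chain)
        if chain is None:
            chain = gemmi.Chain(rid.chain or "A")
            chains[rid.chain] = chain
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(rid.seq, rid.icode or " ")
        res.het_flag = "A"
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(x, y, z)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))
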