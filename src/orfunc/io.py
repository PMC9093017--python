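"""Domain types and readers/writers for the pipeline's standard formats.

The pipeline works on three inputs: a protein multiple sequence alignment of
orthologous receptors (aligned FASTA, one record per species), a receptor x
odorant response matrix (CSV, responses in spikes from single-sensillum
recordings, empty cell = missing), and a structural model of the reference
receptor (PDB).  All residue and column indices are 1-based; positions are
reported in the numbering of the designated reference sequence (e.g. R166,
F265 of *D. melanogaster* Or22a).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser

from .errors import AlignmentFormatError, ResponseFormatError

GAP = "-"
UNKNOWN = "X"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "OrthologAlignment",
    "ReferencePositionMap",
    "ResponseMatrix",
    "StructureModel",
    "read_alignment",
    "write_alignment",
    "build_reference_map",
    "read_response_matrix",
    "read_structure",
    "write_pdb",
    "pairwise_identity_matrix",
    "round_sig",
    "write_json",
]


def round_sig(x: float, digits: int = 6) -> float:
    """Round to ``digits`` significant figures (deterministic output contract)."""
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.{digits}g}")


def _round_tree(obj):
    if isinstance(obj, dict):
        return {k: _round_tree(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round_sig(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(obj, path) -> None:
    """Write JSON deterministically: sorted keys, floats at 6 significant digits."""
    Path(path).write_text(json.dumps(_round_tree(obj), sort_keys=True, indent=2) + "\n")


@dataclass(frozen=True)
class OrthologAlignment:
    """An aligned set of orthologous receptor sequences with a reference record.

    Sequences are over the 20 amino-acid letters plus ``X`` (unknown) and the
    gap character ``-``; all records have identical aligned length.
    """

    records: tuple[tuple[str, str], ...]
    reference_id: str

    def __post_init__(self):
        if not self.records:
            raise AlignmentFormatError("alignment has no records")
        ids = [rid for rid, _ in self.records]
        if any(not rid for rid in ids):
            raise AlignmentFormatError("empty receptor id")
        if len(set(ids)) != len(ids):
            raise AlignmentFormatError("duplicate receptor ids")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"records have unequal lengths: {sorted(lengths)}")
        if self.reference_id not in ids:
            raise KeyError(f"reference_id {self.reference_id!r} not among records")
        for rid, seq in self.records:
            if len(seq) - seq.count(GAP) < 1:
                raise AlignmentFormatError(f"record {rid!r} is all gaps")

    @property
    def receptor_ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    @property
    def alignment_length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_receptors(self) -> int:
        return len(self.records)

    def sequence(self, receptor_id: str) -> str:
        for rid, seq in self.records:
            if rid == receptor_id:
                return seq
        raise KeyError(receptor_id)

    @property
    def reference_sequence(self) -> str:
        return self.sequence(self.reference_id)

    def drop(self, receptor_id: str) -> "OrthologAlignment":
        """Alignment without one receptor (columns kept; reference must remain)."""
        if receptor_id == self.reference_id:
            raise ValueError("cannot drop the reference record")
        if receptor_id not in self.receptor_ids:
            raise KeyError(receptor_id)
        kept = tuple(r for r in self.records if r[0] != receptor_id)
        return OrthologAlignment(kept, self.reference_id)

    def reorder(self, receptor_ids) -> "OrthologAlignment":
        by_id = dict(self.records)
        return OrthologAlignment(
            tuple((rid, by_id[rid]) for rid in receptor_ids), self.reference_id
        )

    def as_array(self) -> np.ndarray:
        """(n_receptors, alignment_length) array of residue byte codes."""
        return np.frombuffer(
            "".join(seq for _, seq in self.records).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_receptors, self.alignment_length)


def read_alignment(path, reference_id: str) -> OrthologAlignment:
    """Parse an aligned FASTA file; letters upper-cased, ``.`` normalised to ``-``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(".", GAP)
        records.append((rec.id, seq))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    return OrthologAlignment(tuple(records), reference_id)


def write_alignment(aln: OrthologAlignment, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in aln.records:
            fh.write(f">{rid}\n{seq}\n")


@dataclass(frozen=True)
class ReferencePositionMap:
    """Mapping between alignment columns and reference residue numbering.

    ``column_to_ref[c-1]`` is the 1-based reference residue index at alignment
    column ``c``, or ``None`` where the reference is gapped.
    """

    column_to_ref: tuple
    ref_length: int

    def ref_of(self, column: int):
        return self.column_to_ref[column - 1]

    def column_of(self, ref_index: int) -> int:
        for c, r in enumerate(self.column_to_ref, start=1):
            if r == ref_index:
                return c
        raise KeyError(f"reference index {ref_index} not mapped")

    def columns_to_ref(self, columns) -> list:
        return [self.ref_of(c) for c in columns]


def build_reference_map(aln: OrthologAlignment) -> ReferencePositionMap:
    """Assign consecutive reference indices to columns where the reference is non-gap."""
    mapping = []
    ref_index = 0
    for ch in aln.reference_sequence:
        if ch == GAP:
            mapping.append(None)
        else:
            ref_index += 1
            mapping.append(ref_index)
    return ReferencePositionMap(tuple(mapping), ref_index)


@dataclass(frozen=True)
class ResponseMatrix:
    """Receptor x odorant responses in spikes; NaN marks a missing measurement."""

    data: pd.DataFrame  # index: receptor ids, columns: odorant ids, dtype float

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            raise ResponseFormatError("duplicate receptor labels")
        if df.columns.has_duplicates:
            raise ResponseFormatError("duplicate odorant labels")
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ResponseFormatError("response matrix has no receptor rows or odorant columns")
        if df.notna().sum(axis=1).min() < 1:
            empty = df.index[df.notna().sum(axis=1) == 0].tolist()
            raise ResponseFormatError(f"receptor rows with no responses: {empty}")

    @property
    def receptor_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def odorant_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def row(self, receptor_id: str) -> pd.Series:
        return self.data.loc[receptor_id]

    def drop(self, receptor_id: str) -> "ResponseMatrix":
        if receptor_id not in self.data.index:
            raise KeyError(receptor_id)
        return ResponseMatrix(self.data.drop(index=receptor_id))

    def reorder(self, receptor_ids=None, odorant_ids=None) -> "ResponseMatrix":
        df = self.data
        if receptor_ids is not None:
            df = df.loc[list(receptor_ids)]
        if odorant_ids is not None:
            df = df[list(odorant_ids)]
        return ResponseMatrix(df)

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df.index.name = "receptor_id"
        df.to_csv(path, float_format="%.6g")


def read_response_matrix(path) -> ResponseMatrix:
    """Read a response CSV: header ``receptor_id,<odorant>,...``; empty cell = missing."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    odorants = header[1:]
    if len(set(odorants)) != len(odorants):
        raise ResponseFormatError(f"duplicate odorant labels in {path}")
    try:
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise ResponseFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] == 0:
        raise ResponseFormatError(f"{path} has a header but no receptor rows")
    try:
        values = df.replace("", np.nan).astype(float)
    except ValueError as exc:
        raise ResponseFormatError(f"non-numeric cell in {path}: {exc}") from exc
    values.index = df.index.astype(str)
    values.index.name = "receptor_id"
    return ResponseMatrix(values)


@dataclass(frozen=True)
class StructureModel:
    """Alpha-carbon coordinates of the reference receptor, in reference numbering."""

    ref_indices: np.ndarray  # (n,) int, unique, 1-based
    coords: np.ndarray  # (n, 3) float, angstrom
    chain_id: str = "A"

    def __post_init__(self):
        idx = np.asarray(self.ref_indices)
        if idx.size != np.unique(idx).size:
            raise ValueError("duplicate residue indices in structure")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.coords.shape != (idx.size, 3):
            raise ValueError("coordinate array shape mismatch")

    @property
    def n_residues(self) -> int:
        return int(self.ref_indices.size)

    def coord(self, ref_index: int) -> np.ndarray:
        pos = np.nonzero(self.ref_indices == ref_index)[0]
        if pos.size == 0:
            raise KeyError(f"residue {ref_index} not in structure")
        return self.coords[pos[0]]


def read_structure(path, chain_id: str = "A", aln_ref_length: int | None = None) -> StructureModel:
    """Read one chain from a PDB file, one alpha-carbon coordinate per residue.

    Residue numbers in the file are taken as reference numbering.  Residues
    lacking an alpha-carbon are skipped with a warning.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise KeyError(f"chain {chain_id!r} not found in {path}")
    chain = model[chain_id]
    indices, coords = [], []
    for res in chain:
        if res.id[0] != " ":
            continue  # heteroatoms / waters
        if "CA" not in res:
            warnings.warn(f"residue {res.id[1]} lacks an alpha-carbon; skipped")
            continue
        indices.append(res.id[1])
        coords.append(res["CA"].coord)
    indices = np.asarray(indices, dtype=int)
    coords = np.asarray(coords, dtype=float).reshape(len(indices), 3)
    if aln_ref_length is not None and indices.size:
        if indices.min() < 1 or indices.max() > aln_ref_length:
            raise ValueError(
                f"structure residue numbers outside [1, {aln_ref_length}]: "
                f"range {indices.min()}..{indices.max()}"
            )
    return StructureModel(indices, coords, chain_id)


def write_pdb(s: StructureModel, path) -> None:
    """Write alpha-carbon-only ATOM records (poly-alanine trace)."""
    with open(path, "w") as fh:
        for serial, (ref_index, (x, y, z)) in enumerate(zip(s.ref_indices, s.coords), start=1):
            fh.write(
                f"ATOM  {serial:>5d}  CA  ALA {s.chain_id}{int(ref_index):>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{'C':>2s}\n"
            )
        fh.write("TER\nEND\n")


def pairwise_identity_matrix(aln: OrthologAlignment) -> pd.DataFrame:
    """Percent pairwise identity between all receptor pairs.

    Identity = 100 x matches / columns where at least one of the pair is
    non-gap; columns gapped in both sequences are excluded.  ``X`` matches
    nothing, itself included.  Symmetric with 100 on the diagonal.
    """
    if aln.n_receptors < 2:
        raise ValueError("need at least 2 records for pairwise identity")
    arr = aln.as_array()
    gap = ord(GAP)
    unknown = ord(UNKNOWN)
    n = aln.n_receptors
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[i], arr[j]
            denom = (a != gap) | (b != gap)
            match = (a == b) & (a != gap) & (b != gap) & (a != unknown)
            out[i, j] = out[j, i] = 100.0 * match.sum() / denom.sum()
    ids = list(aln.receptor_ids)
    return pd.DataFrame(out, index=ids, columns=ids)
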