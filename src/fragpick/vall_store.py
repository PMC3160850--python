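"""The structure database ("vall"): gap-free chunks of known protein chains.

The database is a whitespace-delimited text file, one residue per line::

    pdb_id chain resi aa ss phi psi omega n_x n_y n_z ca_x ca_y ca_z \
        c_x c_y c_z o_x o_y o_z cb_x cb_y cb_z [p_A ... p_Y]

'#' starts a comment line.  CB columns hold ``NaN NaN NaN`` for glycine and
the 20 optional trailing columns are a per-residue amino-acid profile in
alphabetical one-letter order.  Files may be gzip-compressed (transparent on
read).  Torsions undefined at chunk termini are stored as NaN.

A *chunk* is a maximal stretch of one chain with no breaks: the reader splits
at pdb/chain changes, at CA-CA distances above a threshold and at undefined
torsions appearing mid-chain.  Chunks shorter than the shortest requested
fragment never yield candidates, so they can be dropped up front.
"""
from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import AA_ALPHABET, DEFAULT_BREAK_THRESHOLD, SS_LETTERS
from .errors import ParseError

_N_FIXED_COLS = 23  # id cols + torsions + 5 atoms x 3 coords
_ATOM_ORDER = ("N", "CA", "C", "O", "CB")


@dataclass
class VallResidue:
    """One database residue: identity, DSSP-reduced SS, torsions, backbone."""

    aa: str
    ss: str
    phi: float
    psi: float
    omega: float
    resi: int
    line_id: int
    bb_coords: dict = field(default_factory=dict)
    profile: np.ndarray | None = None

    def has_atom(self, name: str) -> bool:
        return name in self.bb_coords

    @property
    def has_defined_torsions(self) -> bool:
        return not (math.isnan(self.phi) or math.isnan(self.psi) or math.isnan(self.omega))


@dataclass
class VallChunk:
    """A gap-free stretch of one chain; the unit of fragment scanning."""

    pdb_id: str
    chain_id: str
    residues: list[VallResidue]

    @property
    def L_C(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chunk_id(self) -> str:
        return self.pdb_id + self.chain_id

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def ss_string(self) -> str:
        return "".join(r.ss for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.bb_coords["CA"] for r in self.residues])

    def profile_matrix(self) -> np.ndarray | None:
        if any(r.profile is None for r in self.residues):
            return None
        return np.array([r.profile for r in self.residues])


@dataclass
class ChunkFilterSpec:
    """Allow- or deny-list of source structures by pdb id (or pdb id + chain)."""

    kind: str  # "deny_pdb_id" | "allow_pdb_id"
    ids: set[str]

    def __post_init__(self):
        if self.kind not in ("deny_pdb_id", "allow_pdb_id"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if not self.ids:
            raise ValueError("filter id set must be non-empty")

    def matches(self, chunk: VallChunk) -> bool:
        return chunk.pdb_id in self.ids or chunk.pdb_id + chunk.chain_id in self.ids


def _open_maybe_gzip(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_line(line_no: int, tokens: list[str]) -> tuple[str, str, VallResidue]:
    if len(tokens) not in (_N_FIXED_COLS, _N_FIXED_COLS + 20):
        raise ParseError(
            f"vall line {line_no}: expected {_N_FIXED_COLS} or {_N_FIXED_COLS + 20} "
            f"columns, got {len(tokens)}"
        )
    pdb_id, chain, resi_s, aa, ss = tokens[:5]
    if aa not in AA_ALPHABET:
        raise ParseError(f"vall line {line_no}: unknown amino acid {aa!r}")
    if ss not in SS_LETTERS:
        raise ParseError(f"vall line {line_no}: secondary structure {ss!r} not in H/E/L")
    try:
        resi = int(resi_s)
        nums = [float(t) for t in tokens[5:]]
    except ValueError as exc:
        raise ParseError(f"vall line {line_no}: {exc}") from None
    phi, psi, omega = nums[0:3]
    coords = {}
    for i, atom in enumerate(_ATOM_ORDER):
        xyz = np.array(nums[3 + 3 * i: 6 + 3 * i])
        if not np.any(np.isnan(xyz)):
            coords[atom] = xyz
    profile = None
    if len(tokens) == _N_FIXED_COLS + 20:
        profile = np.array(nums[18:38])
    res = VallResidue(aa=aa, ss=ss, phi=phi, psi=psi, omega=omega,
                      resi=resi, line_id=line_no, bb_coords=coords, profile=profile)
    return pdb_id, chain, res


def _split_runs(pdb_id: str, chain: str, residues: list[VallResidue],
                break_threshold: float) -> Iterable[VallChunk]:
    """Split one (pdb, chain) run of residues at chain breaks."""
    start = 0
    n = len(residues)
    for i in range(n - 1):
        cur, nxt = residues[i], residues[i + 1]
        broke = False
        if cur.has_atom("CA") and nxt.has_atom("CA"):
            if np.linalg.norm(cur.bb_coords["CA"] - nxt.bb_coords["CA"]) > break_threshold:
                broke = True
        # undefined torsions mid-run flag a break: psi/omega of the residue
        # before the gap and phi of the residue after it are unassignable
        if math.isnan(cur.psi) or math.isnan(cur.omega) or math.isnan(nxt.phi):
            broke = True
        if broke:
            yield VallChunk(pdb_id, chain, residues[start:i + 1])
            start = i + 1
    yield VallChunk(pdb_id, chain, residues[start:])


def read_vall(path, min_chunk_len: int = 1,
              break_threshold: float = DEFAULT_BREAK_THRESHOLD) -> list[VallChunk]:
    """Read a vall file into chunks of at least ``min_chunk_len`` residues.

    Chunks are split at pdb/chain changes and at chain breaks; residues keep
    their original 1-based line numbers so fragments remain traceable to the
    source file.
    """
    if min_chunk_len < 1:
        raise ValueError("min_chunk_len must be >= 1")
    chunks: list[VallChunk] = []
    key: tuple[str, str] | None = None
    run: list[VallResidue] = []

    def flush():
        if key is not None and run:
            chunks.extend(_split_runs(key[0], key[1], run, break_threshold))

    n_residues = 0
    with _open_maybe_gzip(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped or stripped.startswith("#"):
                continue
            pdb_id, chain, res = _parse_line(line_no, stripped.split())
            n_residues += 1
            if key != (pdb_id, chain):
                flush()
                key = (pdb_id, chain)
                run = []
            run.append(res)
    flush()
    if n_residues == 0:
        raise ParseError(f"vall file {path} contains no residues")
    return [c for c in chunks if c.L_C >= min_chunk_len]


def write_vall(chunks: Sequence[VallChunk], path) -> None:
    """Write chunks in the vall dialect, reassigning residue line numbers so
    that a re-read reproduces the chunk set field-by-field."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("# fragpick vall\n")
        line_no = 1
        for chunk in chunks:
            for res in chunk.residues:
                line_no += 1
                res.line_id = line_no
                cols = [chunk.pdb_id, chunk.chain_id, str(res.resi), res.aa, res.ss,
                        f"{res.phi:.3f}", f"{res.psi:.3f}", f"{res.omega:.3f}"]
                for atom in _ATOM_ORDER:
                    if res.has_atom(atom):
                        cols.extend(f"{v:.3f}" for v in res.bb_coords[atom])
                    else:
                        cols.extend(["NaN"] * 3)
                if res.profile is not None:
                    cols.extend(f"{p:.6f}" for p in res.profile)
                fh.write(" ".join(cols) + "\n")


def apply_chunk_filters(chunks: Sequence[VallChunk],
                        filters: Sequence[ChunkFilterSpec]) -> list[VallChunk]:
    """Apply deny/allow pdb-id filters, preserving chunk order."""
    out = list(chunks)
    for f in filters:
        if f.kind == "deny_pdb_id":
            out = [c for c in out if not f.matches(c)]
        else:
            out = [c for c in out if f.matches(c)]
    return out


def read_denied_pdb_list(path) -> ChunkFilterSpec:
    """Read a one-id-per-line deny list file."""
    with open(path) as fh:
        ids = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
    if not ids:
        raise ParseError(f"denied-pdb file {path} lists no ids")
    return ChunkFilterSpec("deny_pdb_id", ids)


def chunk_windows(chunk: VallChunk, L_F: int) -> list[int]:
    """All complete window start offsets of length ``L_F`` inside a chunk
    (empty when the chunk is shorter than the fragment)."""
    if L_F < 1:
        raise ValueError("fragment length must be >= 1")
    return list(range(0, chunk.L_C - L_F + 1))
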