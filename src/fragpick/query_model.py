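"""Everything that describes the query protein.

The query is defined by an amino-acid sequence, which may come from a FASTA
file, a plain-text sequence profile, or a PDB structure (any combination, as
long as the sequences agree).  On top of the sequence the query carries
tagged secondary-structure predictions (PSIPRED SS2 files), optional
torsion-bin probabilities, distance/dihedral restraints and, when a PDB was
given, reference backbone coordinates used by the fragment-RMSD metric.

Residue indices are 1-based in every file and message; internal arrays are
0-based.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .constants import AA_ALPHABET, AA3_TO_AA1, BACKBONE_ATOMS, SS_LETTERS
from .errors import InputError, ParseError

logger = logging.getLogger("fragpick")


@dataclass
class SSPrediction:
    """A tagged secondary-structure prediction: L_Q x 3 probabilities in
    internal (H, E, L) column order."""

    tag: str
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise InputError(f"SS prediction {self.tag!r}: probs must be L x 3")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def argmax_letters(self) -> str:
        return "".join(SS_LETTERS[i] for i in np.argmax(self.probs, axis=1))


@dataclass
class Restraint:
    """A distance (atom_pair) or dihedral restraint on query atoms."""

    kind: str  # "atom_pair" | "dihedral"
    atoms: list  # [(resi 1-based, atom name)], length 2 or 4
    func: object  # scoring.FuncSpec

    def __post_init__(self):
        n = {"atom_pair": 2, "dihedral": 4}.get(self.kind)
        if n is None:
            raise InputError(f"unknown restraint kind {self.kind!r}")
        if len(self.atoms) != n:
            raise InputError(f"{self.kind} restraint needs {n} atoms, got {len(self.atoms)}")

    @property
    def span(self) -> int:
        resis = [r for r, _ in self.atoms]
        return max(resis) - min(resis)


@dataclass
class Query:
    """The target sequence plus all tagged auxiliary inputs."""

    sequence: str
    profile: np.ndarray | None = None
    ss_predictions: dict = field(default_factory=dict)
    torsion_bin_probs: np.ndarray | None = None
    restraints: list = field(default_factory=list)
    reference_coords: dict | None = None  # atom name -> (L_Q, 3), NaN = absent

    def __post_init__(self):
        bad = [a for a in self.sequence if a not in AA_ALPHABET]
        if bad:
            raise InputError(f"non-canonical residue {bad[0]!r} in query sequence")

    @property
    def L_Q(self) -> int:
        return len(self.sequence)

    def add_ss_prediction(self, pred: SSPrediction) -> None:
        if pred.length != self.L_Q:
            raise InputError(
                f"SS prediction {pred.tag!r} has {pred.length} rows, query length is {self.L_Q}")
        self.ss_predictions[pred.tag] = pred

    def set_torsion_bin_probs(self, probs: np.ndarray) -> None:
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (self.L_Q, 5):
            raise InputError(
                f"torsion-bin table shape {probs.shape} does not match (L_Q={self.L_Q}, 5)")
        self.torsion_bin_probs = probs

    def reference_ca(self) -> np.ndarray:
        if self.reference_coords is None:
            raise InputError("query has no reference structure")
        return self.reference_coords["CA"]


# ---------------------------------------------------------------------------
# loaders

def _read_data_lines(path):
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if stripped and not stripped.startswith("#"):
                yield line_no, stripped


def load_fasta(path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA record in {path}")
    return str(records[0].seq).upper()


def load_profile(path) -> np.ndarray:
    """Read the plain-text L_Q x 20 profile dialect: a header line naming the
    20 amino-acid column order, then one row of probabilities per residue.
    Columns are re-ordered to the canonical alphabet on load."""
    lines = list(_read_data_lines(path))
    if not lines:
        raise ParseError(f"profile file {path} is empty")
    header = lines[0][1].split()
    if sorted(header) != sorted(AA_ALPHABET):
        raise ParseError(
            f"profile file {path}: header must name the 20 amino-acid letters")
    order = [header.index(a) for a in AA_ALPHABET]
    rows = []
    for line_no, text in lines[1:]:
        vals = text.split()
        if len(vals) != 20:
            raise ParseError(f"profile line {line_no}: expected 20 columns, got {len(vals)}")
        rows.append([float(v) for v in vals])
    profile = np.array(rows)[:, order]
    sums = profile.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise InputError(f"profile row {bad + 1} sums to {sums[bad]:.6f}, expected 1")
    return profile


def load_pdb(path):
    """Read the first model / first polymer chain of a PDB file.

    Returns ``(sequence, coords)`` where coords maps each backbone atom name
    to an (L, 3) array (NaN rows where the atom is absent, e.g. glycine CB).
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    if len(structure) == 0 or len(structure[0]) == 0:
        raise ParseError(f"PDB file {path} has no chains")
    chain = structure[0][0]
    seq = []
    residues = []
    for res in chain:
        one = AA3_TO_AA1.get(res.name)
        if one is None:
            if res.het_flag == "H":
                continue
            raise InputError(f"non-canonical residue {res.name} in {path}")
        seq.append(one)
        residues.append(res)
    if not seq:
        raise ParseError(f"PDB file {path} has no amino-acid residues")
    coords = {atom: np.full((len(seq), 3), np.nan) for atom in BACKBONE_ATOMS}
    for i, res in enumerate(residues):
        for atom in BACKBONE_ATOMS:
            a = res.find_atom(atom, "*")
            if a is not None:
                coords[atom][i] = [a.pos.x, a.pos.y, a.pos.z]
    return "".join(seq), coords


def load_query(fasta_path=None, profile_path=None, pdb_path=None) -> Query:
    """Build a Query from any combination of sequence sources.

    At least one source is required; when several are given their sequences
    must agree (the profile contributes only a length constraint).
    """
    if fasta_path is None and profile_path is None and pdb_path is None:
        raise InputError("at least one of FASTA, profile or PDB must be given")
    sequences = {}
    if fasta_path is not None:
        sequences["fasta"] = load_fasta(fasta_path)
    profile = load_profile(profile_path) if profile_path is not None else None
    coords = None
    if pdb_path is not None:
        sequences["pdb"], coords = load_pdb(pdb_path)
    if not sequences and profile is None:
        raise InputError("no sequence source given")
    if len(sequences) == 2:
        s1, s2 = sequences["fasta"], sequences["pdb"]
        if len(s1) != len(s2):
            raise InputError(
                f"FASTA sequence length {len(s1)} disagrees with PDB length {len(s2)}")
        for i, (a, b) in enumerate(zip(s1, s2)):
            if a != b:
                raise InputError(
                    f"FASTA and PDB sequences disagree at position {i + 1}: {a} vs {b}")
    if sequences:
        sequence = next(iter(sequences.values()))
    else:
        raise InputError("a profile alone does not define a sequence; add FASTA or PDB")
    if profile is not None and profile.shape[0] != len(sequence):
        raise InputError(
            f"profile has {profile.shape[0]} rows, sequence length is {len(sequence)}")
    return Query(sequence=sequence, profile=profile, reference_coords=coords)


def load_ss2(path, tag: str) -> SSPrediction:
    """Read a PSIPRED VFORMAT SS2 file.

    Input rows are ``idx aa letter pC pH pE``; probabilities are stored in
    internal (H, E, L) order and renormalized to sum exactly 1 (SS2 files are
    rounded to three decimals).
    """
    rows = []
    for line_no, text in _read_data_lines(path):
        tokens = text.split()
        if len(tokens) != 6:
            raise ParseError(f"SS2 line {line_no}: expected 6 columns, got {len(tokens)}")
        try:
            p_c, p_h, p_e = (float(t) for t in tokens[3:6])
        except ValueError as exc:
            raise ParseError(f"SS2 line {line_no}: {exc}") from None
        total = p_h + p_e + p_c
        if total <= 0:
            raise ParseError(f"SS2 line {line_no}: probabilities sum to zero")
        rows.append([p_h / total, p_e / total, p_c / total])
    if not rows:
        raise ParseError(f"SS2 file {path} has no data rows")
    return SSPrediction(tag=tag, probs=np.array(rows))


def load_torsion_bin_probs(path) -> np.ndarray:
    """Read the 7-column torsion-bin probability file: residue number, bin
    class id, then five probabilities in A,B,E,G,O order.  Values are stored
    raw (NOT renormalized): an all-1.0 row means "no constraint here"."""
    rows = {}
    for line_no, text in _read_data_lines(path):
        tokens = text.split()
        if len(tokens) != 7:
            raise ParseError(
                f"torsion-bin line {line_no}: expected 7 columns, got {len(tokens)}")
        resi = int(tokens[0])
        probs = [float(t) for t in tokens[2:7]]
        if any(p < 0.0 or p > 1.0 for p in probs):
            raise InputError(
                f"torsion-bin line {line_no}: probability outside [0, 1]")
        rows[resi] = probs
    if not rows:
        raise ParseError(f"torsion-bin file {path} has no data rows")
    n = max(rows)
    if sorted(rows) != list(range(1, n + 1)):
        raise ParseError(f"torsion-bin file {path}: residue numbers must run 1..{n}")
    return np.array([rows[i] for i in range(1, n + 1)])


def parse_restraints(path) -> list[Restraint]:
    """Parse the supported subset of the Rosetta restraint ("cst") dialect:

    ``AtomPair  a1 r1 a2 r2  FUNC params`` and
    ``Dihedral  a1 r1 a2 r2 a3 r3 a4 r4  FUNC params`` with FUNC one of
    HARMONIC x0 sd / BOUNDED lb ub sd / CIRCULARHARMONIC x0 sd.
    """
    from .scoring import FuncSpec

    def parse_func(tokens, line_no):
        name = tokens[0].upper()
        vals = [float(t) for t in tokens[1:]]
        if name == "HARMONIC" and len(vals) == 2:
            return FuncSpec("harmonic", x0=vals[0], sd=vals[1])
        if name == "BOUNDED" and len(vals) == 3:
            return FuncSpec("bounded", lb=vals[0], ub=vals[1], sd=vals[2])
        if name == "CIRCULARHARMONIC" and len(vals) == 2:
            return FuncSpec("circular_harmonic", x0=vals[0], sd=vals[1])
        raise ParseError(f"restraint line {line_no}: unsupported function {tokens!r}")

    restraints = []
    for line_no, text in _read_data_lines(path):
        tokens = text.split()
        head = tokens[0].lower()
        if head == "atompair":
            if len(tokens) < 7:
                raise ParseError(f"restraint line {line_no}: AtomPair needs 4 atom fields")
            atoms = [(int(tokens[2]), tokens[1].upper()), (int(tokens[4]), tokens[3].upper())]
            restraints.append(Restraint("atom_pair", atoms, parse_func(tokens[5:], line_no)))
        elif head == "dihedral":
            if len(tokens) < 11:
                raise ParseError(f"restraint line {line_no}: Dihedral needs 8 atom fields")
            atoms = [(int(tokens[2 * i + 2]), tokens[2 * i + 1].upper()) for i in range(4)]
            restraints.append(Restraint("dihedral", atoms, parse_func(tokens[9:], line_no)))
        else:
            raise ParseError(f"restraint line {line_no}: unknown restraint type {tokens[0]!r}")
    return restraints


def validate_restraints(restraints, L_F: int, sequence: str | None = None):
    """Split restraints into (valid, ignored) for fragment length ``L_F``.

    A restraint is usable only if it fits inside one fragment (span < L_F)
    and references atoms the database can provide: backbone atoms and CB,
    where CB of a glycine position does not exist.  Rejected restraints are
    logged with a warning, never raised.
    """
    valid, ignored = [], []
    for r in restraints:
        reason = None
        if r.span >= L_F:
            reason = f"span {r.span} does not fit inside a {L_F}-residue fragment"
        for resi, atom in r.atoms:
            if reason:
                break
            if atom not in BACKBONE_ATOMS:
                reason = f"atom {atom} is not a backbone/CB atom"
            elif sequence is not None:
                if resi < 1 or resi > len(sequence):
                    reason = f"residue {resi} outside query 1..{len(sequence)}"
                elif atom == "CB" and sequence[resi - 1] == "G":
                    reason = f"residue {resi} is glycine and has no CB"
        if reason is None:
            valid.append(r)
        else:
            logger.warning("ignoring %s restraint %s: %s", r.kind, r.atoms, reason)
            ignored.append(r)
    return valid, ignored


def profile_from_submatrix(sequence: str, matrix, scale: float = 0.5) -> np.ndarray:
    """Derive an L_Q x 20 profile by convolving a sequence with a
    substitution matrix: row for residue ``a`` is softmax over ``b`` of
    ``scale * M[a, b]``.

    ``matrix`` is a Bio.Align.substitution_matrices Array (or any mapping
    supporting ``matrix[a, b]``).  ``scale`` -> 0 gives uniform rows;
    large ``scale`` approaches a one-hot at the matrix-row argmax.
    """
    rows = []
    for a in sequence:
        try:
            logits = np.array([scale * float(matrix[a, b]) for b in AA_ALPHABET])
        except (KeyError, IndexError):
            raise InputError(f"residue {a!r} absent from the substitution matrix") from None
        logits -= logits.max()
        w = np.exp(logits)
        rows.append(w / w.sum())
    return np.array(rows)
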