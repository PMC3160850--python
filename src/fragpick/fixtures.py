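"""Deterministic synthetic-data generator.

Builds small structure databases with known planted content so the whole
picking pipeline is testable without downloading anything: chunks are
assembled from idealized secondary-structure segments (helix phi/psi near
(-60, -45), strand near (-120, 130), loops from a small fixed torsion
library) with Gaussian torsion noise, backbone coordinates are reconstructed
from the torsions by sequential internal-coordinate chain building with
ideal bond geometry, and per-residue profile columns come from a
substitution-matrix softmax of the residue identity.

Everything is a pure function of (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import (AA1_TO_AA3, AA_ALPHABET, ANGLE_CA_C_N, ANGLE_CA_C_O,
                        ANGLE_C_N_CA, ANGLE_N_CA_C, BOND_CA_C, BOND_C_N,
                        BOND_C_O, BOND_CA_CB, BOND_N_CA, ANGLE_N_CA_CB)
from .geometry import place_atom
from .query_model import Query, SSPrediction
from .vall_store import VallChunk, VallResidue, write_vall

# idealized torsion means per secondary-structure type
HELIX_TORSIONS = (-60.0, -45.0)
STRAND_TORSIONS = (-120.0, 130.0)
# a fixed small library of allowed loop (phi, psi) pairs
LOOP_TORSIONS = ((-80.0, 80.0), (-140.0, 70.0), (-70.0, 150.0), (-100.0, -10.0),
                 (60.0, 30.0))

_SEGMENT_LENGTHS = {"H": (6, 12), "E": (4, 8), "L": (2, 5)}


@dataclass
class PlantedQuery:
    """A chunk deliberately planted in the database to serve as a query with
    known ground truth."""

    length: int = 40
    sequence: str | None = None
    noise: float = 0.0  # torsion noise (degrees, sd) applied to the planted chunk


@dataclass
class FixtureSpec:
    """What to generate: decoy count and sizes, SS composition, planted
    queries, and the mandatory seed."""

    seed: int
    n_chunks: int = 50
    chunk_length_range: tuple = (30, 60)
    ss_composition: dict = field(default_factory=lambda: {"H": 0.4, "E": 0.3, "L": 0.3})
    torsion_noise: float = 8.0  # degrees, sd, applied to decoy chunks
    planted_queries: list = field(default_factory=list)

    def __post_init__(self):
        total = sum(self.ss_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ss_composition fractions sum to {total}, expected 1")


# ---------------------------------------------------------------------------
# backbone construction


def build_backbone(phis, psis, omegas, glycine_mask=None):
    """Reconstruct N/CA/C/O/CB coordinates from torsions with ideal bond
    lengths and angles (NeRF chain building).  ``glycine_mask[i]`` True
    suppresses the CB of residue i."""
    n = len(phis)
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    CA[0] = [BOND_N_CA, 0.0, 0.0]
    alpha = np.radians(180.0 - ANGLE_N_CA_C)  # direction of CA->C from the +x axis
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(alpha), np.sin(alpha), 0.0])
    for i in range(n - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psis[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, omegas[i])
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C,
                              phis[i + 1])
    coords = []
    for i in range(n):
        res = {"N": N[i], "CA": CA[i], "C": C[i]}
        psi_eff = psis[i] if not np.isnan(psis[i]) else 120.0
        res["O"] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi_eff + 180.0)
        if glycine_mask is None or not glycine_mask[i]:
            res["CB"] = place_atom(C[i], N[i], CA[i], BOND_CA_CB, ANGLE_N_CA_CB, 122.55)
        coords.append(res)
    return coords


_PROFILE_BASE = None
PROFILE_JITTER_SD = 0.3  # log-scale per-entry jitter making profiles position-specific


def _profile_row(aa: str, rng) -> np.ndarray:
    """Per-residue profile row: softmax of half-scaled BLOSUM62 around the
    residue identity, with seeded log-normal jitter.

    The jitter makes rows position-specific, as real alignment-derived
    profiles are: two occurrences of the same residue type get similar but
    not identical probability rows, so sequence-duplicate windows do not
    collapse onto exactly equal profile scores.
    """
    global _PROFILE_BASE
    if _PROFILE_BASE is None:
        from .query_model import profile_from_submatrix
        from .scoring import load_substitution_matrix
        matrix = load_substitution_matrix("BLOSUM62")
        _PROFILE_BASE = {a: row for a, row in
                         zip(AA_ALPHABET, profile_from_submatrix(AA_ALPHABET, matrix, 0.5))}
    row = _PROFILE_BASE[aa] * np.exp(rng.normal(0.0, PROFILE_JITTER_SD, 20))
    return row / row.sum()


def _sample_segments(rng, length: int, composition: dict):
    """Segment plan (ss letter per residue) following the composition."""
    letters = sorted(composition)
    probs = np.array([composition[s] for s in letters])
    plan = []
    while len(plan) < length:
        ss = letters[int(rng.choice(len(letters), p=probs))]
        lo, hi = _SEGMENT_LENGTHS[ss]
        seg = int(rng.integers(lo, hi + 1))
        plan.extend([ss] * min(seg, length - len(plan)))
    return "".join(plan)


def _make_chunk(rng, pdb_id: str, chain_id: str, length: int, composition: dict,
                torsion_noise: float, sequence: str | None = None) -> VallChunk:
    ss = _sample_segments(rng, length, composition)
    if sequence is None:
        sequence = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))
    phis = np.empty(length)
    psis = np.empty(length)
    omegas = np.full(length, 180.0)
    loop_choice = rng.integers(0, len(LOOP_TORSIONS), size=length)
    for i, s in enumerate(ss):
        if s == "H":
            base = HELIX_TORSIONS
        elif s == "E":
            base = STRAND_TORSIONS
        else:
            base = LOOP_TORSIONS[loop_choice[i]]
        phis[i] = base[0] + rng.normal(0.0, torsion_noise)
        psis[i] = base[1] + rng.normal(0.0, torsion_noise)
    gly = [a == "G" for a in sequence]
    coords = build_backbone(phis, psis, omegas, glycine_mask=gly)
    residues = [
        VallResidue(aa=sequence[i], ss=ss[i], phi=float(phis[i]), psi=float(psis[i]),
                    omega=float(omegas[i]), resi=i + 1, line_id=0,
                    bb_coords=coords[i], profile=_profile_row(sequence[i], rng))
        for i in range(length)
    ]
    return VallChunk(pdb_id=pdb_id, chain_id=chain_id, residues=residues)


def _assign_line_ids(chunks):
    """Number residues as the vall writer will (line 1 is the header)."""
    line = 1
    for chunk in chunks:
        for res in chunk.residues:
            line += 1
            res.line_id = line


def generate_vall(spec: FixtureSpec, path=None):
    """Generate a synthetic structure database.

    Returns ``(chunks, ground_truth)`` where ground_truth records planted
    chunk ids and per-chunk segment strings; when ``path`` is given the vall
    file is also written (gzip if the name ends in .gz).
    """
    rng = np.random.default_rng(spec.seed)
    decoys = []
    for i in range(spec.n_chunks):
        length = int(rng.integers(spec.chunk_length_range[0],
                                  spec.chunk_length_range[1] + 1))
        decoys.append(_make_chunk(rng, f"d{i:03d}", "A", length, spec.ss_composition,
                                  spec.torsion_noise))
    planted = []
    for j, pq in enumerate(spec.planted_queries):
        planted.append(_make_chunk(rng, f"q{j:03d}", "A", pq.length,
                                   spec.ss_composition, pq.noise, sequence=pq.sequence))
    chunks = decoys[:len(decoys) // 2] + planted + decoys[len(decoys) // 2:]
    _assign_line_ids(chunks)
    if path is not None:
        write_vall(chunks, path)
    ground_truth = {
        "planted_ids": [c.pdb_id for c in planted],
        "planted_chunks": planted,
        "segments": {c.chunk_id: c.ss_string for c in chunks},
    }
    return chunks, ground_truth


# ---------------------------------------------------------------------------
# query bundles


def _noisy_prediction(rng, ss_string: str, tag: str, noise: float) -> SSPrediction:
    """A synthetic "expert": mostly-confident probabilities for the true SS,
    with the top letter flipped at a ``noise`` fraction of positions."""
    from .constants import SS_INDEX
    probs = np.empty((len(ss_string), 3))
    for i, true in enumerate(ss_string):
        if noise > 0.0 and rng.random() < noise:
            top = rng.choice([s for s in "HEL" if s != true])
            conf = 0.70
        else:
            top = true
            conf = 0.90
        row = np.full(3, (1.0 - conf) / 2.0)
        row[SS_INDEX[top]] = conf
        probs[i] = row
    return SSPrediction(tag=tag, probs=probs)


def query_from_chunk(chunk: VallChunk, tags=("psipred", "sam", "jufo"),
                     noises=(0.0, 0.0, 0.0), seed: int = 0) -> Query:
    """In-memory query whose ground truth is a database chunk: its sequence
    and profile, noisy per-predictor SS predictions, and the chunk's own
    backbone as the reference structure."""
    rng = np.random.default_rng(seed)
    coords = {}
    for atom in ("N", "CA", "C", "O", "CB"):
        arr = np.full((chunk.L_C, 3), np.nan)
        for i, res in enumerate(chunk.residues):
            if res.has_atom(atom):
                arr[i] = res.bb_coords[atom]
        coords[atom] = arr
    query = Query(sequence=chunk.sequence, profile=chunk.profile_matrix(),
                  reference_coords=coords)
    for tag, noise in zip(tags, noises):
        query.add_ss_prediction(_noisy_prediction(rng, chunk.ss_string, tag, noise))
    return query


def write_fasta(sequence: str, path, name: str = "query") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i:i + 60] + "\n")


def write_profile(profile: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-residue amino-acid probabilities\n")
        fh.write(" ".join(AA_ALPHABET) + "\n")
        for row in profile:
            # enough precision that re-read rows still sum to 1 within 1e-6
            fh.write(" ".join(f"{v:.8f}" for v in row) + "\n")


def write_ss2(prediction: SSPrediction, sequence: str, path) -> None:
    """Write PSIPRED VFORMAT: rows ``idx aa letter pC pH pE``."""
    letters = prediction.argmax_letters()
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (synthetic)\n\n")
        for i, (aa, row) in enumerate(zip(sequence, prediction.probs), start=1):
            letter = "C" if letters[i - 1] == "L" else letters[i - 1]
            fh.write(f"{i:4d} {aa} {letter}   {row[2]:5.3f} {row[0]:5.3f} {row[1]:5.3f}\n")


def write_pdb(chunk: VallChunk, path) -> None:
    """Write the chunk backbone as a minimal single-chain PDB file."""
    with open(path, "w") as fh:
        serial = 0
        for res in chunk.residues:
            resname = AA1_TO_AA3[res.aa]
            for atom in ("N", "CA", "C", "O", "CB"):
                if not res.has_atom(atom):
                    continue
                serial += 1
                x, y, z = res.bb_coords[atom]
                name_field = f" {atom:<3s}"
                fh.write(f"ATOM  {serial:5d} {name_field}{'':1s}{resname:>3s} "
                         f"A{res.resi:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                         f"  1.00  0.00          {atom[0]:>2s}\n")
        fh.write("END\n")


def generate_query_bundle(spec: FixtureSpec, planted_chunk: VallChunk, outdir,
                          tags=("psipred", "sam", "jufo"),
                          noises=(0.0, 0.05, 0.2)) -> dict:
    """Write a complete query input set derived from a planted chunk:
    FASTA, text profile, one SS2 file per synthetic predictor (with
    per-predictor confusion noise so the experts can disagree), and a PDB of
    the planted backbone.  Returns a name -> path mapping."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)
    paths = {}
    paths["fasta"] = outdir / "query.fasta"
    write_fasta(planted_chunk.sequence, paths["fasta"])
    paths["profile"] = outdir / "query.profile"
    write_profile(planted_chunk.profile_matrix(), paths["profile"])
    paths["pdb"] = outdir / "query.pdb"
    write_pdb(planted_chunk, paths["pdb"])
    for tag, noise in zip(tags, noises):
        pred = _noisy_prediction(rng, planted_chunk.ss_string, tag, noise)
        p = outdir / f"query.{tag}.ss2"
        write_ss2(pred, planted_chunk.sequence, p)
        paths[f"ss2:{tag}"] = p
    return {k: str(v) for k, v in paths.items()}
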