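"""The three-stage picking workflow: build the scoring system, scan the
database chunk-wise scoring and collecting candidates, then select and write
the per-position fragment libraries.

The library layout follows the window convention in which a query of length
L_Q gets L_Q - L_F fragment sets per size (100 residues -> 91 sets of
9-mers and 97 sets of 3-mers); an "inclusive" switch yields the
conventional L_Q - L_F + 1 instead.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError
from .scoring import (ScoringContext, ScoringSystem, score_term_keys)
from .selection import (BoundedCollector, FragmentCandidate, GrabAllCollector,
                        QuotaCollector, candidate_sort_key, quota_build,
                        quota_select, select_best_total)
from .vall_store import apply_chunk_filters, chunk_windows

logger = logging.getLogger("fragpick")


def n_positions(L_Q: int, L_F: int, convention: str = "exclusive") -> int:
    """Number of per-position fragment sets for a query of length L_Q.

    The default ("exclusive") convention counts L_Q - L_F sets; "inclusive"
    adds the final window for L_Q - L_F + 1.
    """
    if L_Q <= L_F:
        raise InputError(f"query length {L_Q} must exceed fragment length {L_F}")
    if convention == "exclusive":
        return L_Q - L_F
    if convention == "inclusive":
        return L_Q - L_F + 1
    raise InputError(f"unknown window convention {convention!r}")


def torsion_option_count(frag_sizes, n_frags: int) -> int:
    """How many (phi, psi, omega) triplets a library offers an interior
    residue: each size contributes L_F windows covering the residue times
    N_F fragments per window."""
    return int(sum(L_F * n_frags for L_F in frag_sizes))


@dataclass
class PickerConfig:
    """Run-level knobs for the picking workflow."""

    frag_sizes: list = field(default_factory=lambda: [9, 3])
    n_candidates: int = 200  # N_C
    n_frags: int = 200  # N_F
    protocol: str = "best_fragments"  # best_fragments | quota | grab_all
    window_convention: str = "exclusive"
    chunk_filters: list = field(default_factory=list)
    quota_shares: dict | None = None
    positions: dict | None = None  # optional L_F -> list of 1-based positions
    submatrix: object | None = None
    submatrix_scale: float = 0.5
    n_design_cycles: int = 10

    def __post_init__(self):
        if any(L < 1 for L in self.frag_sizes):
            raise ConfigurationError("fragment sizes must be >= 1")
        if not (self.n_candidates >= self.n_frags >= 1):
            raise ConfigurationError(
                f"need N_C >= N_F >= 1, got {self.n_candidates}/{self.n_frags}")


@dataclass
class FragmentLibrary:
    """Selected fragments per (fragment length, query position), each list
    sorted by total score."""

    frag_sizes: list
    entries: dict  # (L_F, query_pos 1-based) -> list[FragmentCandidate]
    score_keys: list  # term keys in descending priority order

    def positions(self, L_F: int) -> list[int]:
        return sorted(p for (lf, p) in self.entries if lf == L_F)

    def fragments(self, L_F: int, query_pos: int) -> list:
        return self.entries[(L_F, query_pos)]


def _needs(specs, name) -> bool:
    return any(s.name == name for s in specs)


def _build_system(query, chunks, specs, config) -> ScoringSystem:
    from .scoring import build_rama_maps

    rama_maps = build_rama_maps(chunks) if _needs(specs, "RamaScore") else None
    ctx = ScoringContext(rama_maps=rama_maps, submatrix=config.submatrix,
                         submatrix_scale=config.submatrix_scale)
    system = ScoringSystem(specs, query, config.frag_sizes, ctx)
    if any(t.spec.name == "ProfileScoreL1" for t in system.terms):
        missing = [c.chunk_id for c in chunks if c.profile_matrix() is None]
        if missing:
            raise ConfigurationError(
                f"ProfileScoreL1 configured but {len(missing)} chunk(s) lack profile "
                f"columns (first: {missing[0]})")
    return system


def run_picking(query, chunks, specs, config: PickerConfig) -> FragmentLibrary:
    """Score every (chunk window, query position) pairing for every requested
    fragment size, collect per position, select, and late-score the final
    fragments.  Deterministic: identical inputs give identical libraries,
    independent of chunk order."""
    chunks = apply_chunk_filters(chunks, config.chunk_filters)
    if not chunks:
        raise InputError("no database chunks left after filtering")
    system = _build_system(query, chunks, specs, config)

    positions = {}
    for L_F in config.frag_sizes:
        if config.positions and L_F in config.positions:
            positions[L_F] = list(config.positions[L_F])
        else:
            positions[L_F] = list(range(1, n_positions(query.L_Q, L_F,
                                                       config.window_convention) + 1))

    def rank_factory(tag):
        pairs = system.pool_weight_keys(tag)

        def rank(cand):
            return sum(w * cand.score_map.values[k] for k, w in pairs)

        return rank

    collectors = {}
    for L_F in config.frag_sizes:
        for pos in positions[L_F]:
            if config.protocol == "quota":
                if config.quota_shares is None:
                    raise ConfigurationError("quota protocol requires quota shares")
                pools = quota_build(config.quota_shares, query.ss_predictions, pos, L_F,
                                    config.n_candidates, config.n_frags,
                                    rank_factory=rank_factory)
                collectors[(L_F, pos)] = QuotaCollector(pools)
            elif config.protocol == "grab_all":
                collectors[(L_F, pos)] = GrabAllCollector()
            else:
                collectors[(L_F, pos)] = BoundedCollector(config.n_candidates)

    for chunk in chunks:
        system.prepare_chunk(chunk)
        for L_F in config.frag_sizes:
            pos_list = positions[L_F]
            for offset in chunk_windows(chunk, L_F):
                frag_id = chunk.residues[offset].line_id
                for pos in pos_list:
                    cand = FragmentCandidate(pos, chunk, offset, L_F, frag_id=frag_id)
                    score_map = system.evaluate_candidate(cand)
                    if score_map.rejected_by is not None:
                        continue
                    cand.score_map = score_map
                    collectors[(L_F, pos)].insert(cand)

    entries = {}
    for (L_F, pos), collector in collectors.items():
        if isinstance(collector, QuotaCollector):
            selected = quota_select(collector.pools, config.n_frags)
        else:
            selected = select_best_total(collector, config.n_frags)
        if not selected:
            logger.warning("no fragment candidates survived at position %d (L_F=%d)",
                           pos, L_F)
        for cand in selected:
            system.late_score(cand)
        entries[(L_F, pos)] = selected
    return FragmentLibrary(frag_sizes=list(config.frag_sizes), entries=entries,
                           score_keys=system.term_keys())


# ---------------------------------------------------------------------------
# flexible-loop design protocol


def _default_perturb(sequence: str, designable, rng) -> str:
    """Mutate one random designable position to a random different residue."""
    from .constants import AA_ALPHABET

    pos = int(rng.choice(list(designable)))
    current = sequence[pos - 1]
    choices = [a for a in AA_ALPHABET if a != current]
    new = choices[int(rng.integers(len(choices)))]
    return sequence[:pos - 1] + new + sequence[pos:]


def run_flexloop_cycles(query, chunks, designable_positions, loop_range, cycles: int,
                        submatrix, *, frag_sizes=(3,), n_candidates=200, n_frags=200,
                        seed: int = 0, perturb=None, submatrix_scale: float = 0.5,
                        ss_weight: float = 2.0, profile_weight: float = 1.0):
    """Iterative design-time repicking: each cycle derives a profile from the
    *current* sequence by substitution-matrix convolution, repicks fragments
    for the loop windows against an all-loop secondary-structure objective,
    then perturbs the sequence (default: one random mutation at a designable
    position).  Returns one FragmentLibrary per cycle.

    This is a deliberately minimal stand-in for a full design loop: there is
    no rotamer packing or energy function, only the on-the-fly fragment
    repicking machinery.
    """
    from .query_model import Query, SSPrediction
    from .scoring import ScoreTermSpec

    loop_start, loop_end = loop_range
    if not (1 <= loop_start <= loop_end <= query.L_Q):
        raise InputError(f"loop range {loop_range} outside query 1..{query.L_Q}")
    if loop_end - loop_start + 1 < min(frag_sizes):
        raise InputError(
            f"loop window {loop_range} is shorter than the smallest fragment "
            f"size {min(frag_sizes)}")
    positions = {
        L_F: [p for p in range(loop_start, loop_end - L_F + 2)
              if p + L_F - 1 <= query.L_Q]
        for L_F in frag_sizes
    }
    specs = [
        ScoreTermSpec("SecondarySimilarity", 350, ss_weight, None, ["loop"], order=0),
        ScoreTermSpec("ProfileScoreSubMatrix", 200, profile_weight, None, [], order=1),
    ]
    rng = np.random.default_rng(seed)
    perturb = perturb or _default_perturb
    sequence = query.sequence
    libraries = []
    for _ in range(cycles):
        all_loop = SSPrediction("loop", np.tile([0.0, 0.0, 1.0], (len(sequence), 1)))
        cycle_query = Query(sequence=sequence, ss_predictions={"loop": all_loop},
                            reference_coords=query.reference_coords)
        config = PickerConfig(frag_sizes=list(frag_sizes), n_candidates=n_candidates,
                              n_frags=n_frags, protocol="best_fragments",
                              positions=positions, submatrix=submatrix,
                              submatrix_scale=submatrix_scale)
        libraries.append(run_picking(cycle_query, chunks, specs, config))
        sequence = perturb(sequence, designable_positions, rng)
    return libraries


# ---------------------------------------------------------------------------
# output files


def _frag_path(path_prefix, L_F: int) -> str:
    return f"{path_prefix}.{L_F}mers"


def write_fragment_file(library: FragmentLibrary, path_prefix) -> list[str]:
    """Write one Rosetta-style fragment file per fragment size.

    Per position: a ``position: P neighbors: N`` header, then per fragment
    L_F lines of ``pdb_id chain resi aa ss phi psi omega`` with 3-decimal
    torsions, fragments separated by blank lines.
    """
    paths = []
    for L_F in library.frag_sizes:
        path = _frag_path(path_prefix, L_F)
        with open(path, "w") as fh:
            for pos in library.positions(L_F):
                frags = library.fragments(L_F, pos)
                fh.write(f"position: {pos:12d} neighbors: {len(frags):12d}\n\n")
                for cand in frags:
                    for res in cand.residues():
                        fh.write(f"{cand.chunk.pdb_id:>4s} {cand.chunk.chain_id} "
                                 f"{res.resi:5d} {res.aa} {res.ss} "
                                 f"{res.phi:9.3f} {res.psi:9.3f} {res.omega:9.3f}\n")
                    fh.write("\n")
        paths.append(path)
    return paths


def read_fragment_file(path):
    """Parse a fragment file back into
    {position: [[(pdb, chain, resi, aa, ss, phi, psi, omega), ...], ...]}."""
    result = {}
    pos = None
    frag = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("position:"):
                tokens = line.split()
                pos = int(tokens[1])
                result[pos] = []
                frag = []
            elif not line.strip():
                if frag:
                    result[pos].append(frag)
                    frag = []
            else:
                t = line.split()
                frag.append((t[0], t[1], int(t[2]), t[3], t[4],
                             float(t[5]), float(t[6]), float(t[7])))
    if frag:
        result[pos].append(frag)
    return result


def write_score_file(library: FragmentLibrary, path_prefix) -> list[str]:
    """Write one score ("describe fragments") file per fragment size: per
    fragment one row of query position, vall start residue, source pdb and
    chain, middle-residue SS, every score component in descending priority
    (zero-weight metrics included), the weighted total, and the vall line
    number of the fragment start."""
    paths = []
    keys = library.score_keys
    for L_F in library.frag_sizes:
        path = _frag_path(path_prefix, L_F)
        with open(path, "w") as fh:
            fh.write("#query_pos vall_pos pdbid c ss " + " ".join(keys)
                     + " TOTAL FRAG_ID\n")
            for pos in library.positions(L_F):
                for cand in library.fragments(L_F, pos):
                    first = cand.chunk.residues[cand.offset]
                    cols = [f"{pos:10d}", f"{first.resi:8d}",
                            f"{cand.chunk.pdb_id:>5s}", cand.chunk.chain_id,
                            cand.middle_ss]
                    for k in keys:
                        cols.append(f"{cand.score_map.values[k]:8.3f}")
                    cols.append(f"{cand.score_map.total:8.3f}")
                    cols.append(f"{cand.frag_id:9d}")
                    fh.write(" ".join(cols) + "\n")
        paths.append(path)
    return paths
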