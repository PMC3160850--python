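"""Composite fragment scoring.

The total score of a fragment candidate is a weighted sum S = sum_i w_i S_i
of registered score terms; lower is better and every non-restraint term is
normalized to [0, 1] with 0 for a perfect match.  Terms carry a priority
(higher = evaluated earlier) and an optional maximum allowed value: the first
term exceeding its maximum rejects the candidate and stops evaluation.

Terms whose per-fragment value is a mean of independent per-residue values
are *caching* terms: for each database chunk they fill an L_Q x L_C matrix
of per-residue scores once, and every overlapping fragment window reads its
value off a diagonal mean.  Zero-weight terms are "late" metrics: they are
skipped during the scan and evaluated only on the final selected fragments.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import AA_INDEX, SS_INDEX, SS_LETTERS
from .errors import ConfigurationError, FragPickError, ParseError
from .geometry import dihedral, kabsch_rmsd, wrapped_angular_difference

# ---------------------------------------------------------------------------
# configuration


@dataclass
class FuncSpec:
    """A restraint penalty function.

    harmonic(x0, sd) and bounded(lb, ub, sd) act on distances in Angstrom;
    circular_harmonic(x0, sd) acts on a dihedral, with x0 and sd in radians
    as in the restraint file dialect.
    """

    form: str
    x0: float | None = None
    sd: float | None = None
    lb: float | None = None
    ub: float | None = None

    def __post_init__(self):
        if self.form not in ("harmonic", "bounded", "circular_harmonic"):
            raise ValueError(f"unknown function form {self.form!r}")
        if self.sd is None or self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.form == "bounded" and (self.lb is None or self.ub is None or self.lb > self.ub):
            raise ValueError("bounded function requires lb <= ub")

    def distance_value(self, d: float) -> float:
        if self.form == "harmonic":
            return ((d - self.x0) / self.sd) ** 2
        if self.form == "bounded":
            if d < self.lb:
                return ((d - self.lb) / self.sd) ** 2
            if d > self.ub:
                return ((d - self.ub) / self.sd) ** 2
            return 0.0
        raise FragPickError(f"{self.form} is not a distance function")

    def angle_value(self, measured_deg: float) -> float:
        if self.form != "circular_harmonic":
            raise FragPickError(f"{self.form} is not an angular function")
        delta_deg = wrapped_angular_difference(measured_deg, math.degrees(self.x0))
        return (math.radians(delta_deg) / self.sd) ** 2


@dataclass
class ScoreTermSpec:
    """One line of the score configuration: name, priority, weight w_i,
    optional maximum allowed value, free-form extras (tags, file names)."""

    name: str
    priority: int
    weight: float
    max_allowed: float | None = None
    extras: list = field(default_factory=list)
    order: int = 0  # file order, used as the stable tie-break on priority

    @property
    def is_late(self) -> bool:
        return self.weight == 0.0


@dataclass
class ScoreMap:
    """Per-candidate term values and total.

    When ``rejected_by`` is set, terms of lower priority were never
    evaluated and ``total`` is absent.
    """

    values: dict = field(default_factory=dict)
    total: float | None = None
    rejected_by: str | None = None


def parse_score_config(text: str) -> list[ScoreTermSpec]:
    """Parse the tabular score configuration (columns: name, priority,
    weight, max, extras...; '#' comments; '-' means no maximum).  Returns
    specs sorted by descending priority, ties broken by file order."""
    specs = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        cols = stripped.split()
        if len(cols) < 4:
            raise ParseError(
                f"score config line {line_no}: expected >= 4 columns, got {len(cols)}")
        name = cols[0]
        if name not in TERM_REGISTRY:
            raise ConfigurationError(
                f"unknown score term {name!r}; registered terms: "
                + ", ".join(sorted(TERM_REGISTRY)))
        max_allowed = None if cols[3] == "-" else float(cols[3])
        specs.append(ScoreTermSpec(name=name, priority=int(cols[1]),
                                   weight=float(cols[2]), max_allowed=max_allowed,
                                   extras=cols[4:], order=len(specs)))
    specs.sort(key=lambda s: (-s.priority, s.order))
    return specs


def score_term_keys(specs) -> list[str]:
    """A unique key per spec; duplicated term names are disambiguated by
    their first extra (the tag) or by file order."""
    counts = {}
    for s in specs:
        counts[s.name] = counts.get(s.name, 0) + 1
    keys = []
    for s in specs:
        if counts[s.name] == 1:
            keys.append(s.name)
        elif s.extras:
            keys.append(f"{s.name}[{s.extras[0]}]")
        else:
            keys.append(f"{s.name}[{s.order}]")
    return keys


def total_score(score_map: ScoreMap, specs) -> float:
    """S = sum_i w_i S_i over all terms; zero-weight terms contribute 0."""
    total = 0.0
    for spec, key in zip(specs, score_term_keys(specs)):
        if spec.weight == 0.0:
            continue
        if key not in score_map.values:
            raise FragPickError(f"term {key} (weight {spec.weight}) has no value")
        total += spec.weight * score_map.values[key]
    return total


# ---------------------------------------------------------------------------
# elementary score functions


def sequence_identity_score(query_window: str, frag_window: str) -> float:
    """1 - fraction of identical residues (0 = identical windows)."""
    if len(query_window) != len(frag_window):
        raise ValueError("windows differ in length")
    same = sum(a == b for a, b in zip(query_window, frag_window))
    return 1.0 - same / len(query_window)


def profile_l1_score(query_profile_window: np.ndarray,
                     vall_profile_window: np.ndarray) -> float:
    """Mean per-residue L1 distance between amino-acid probability rows,
    halved so the score lies in [0, 1]."""
    q = np.asarray(query_profile_window, dtype=float)
    v = np.asarray(vall_profile_window, dtype=float)
    if q.shape != v.shape:
        raise ValueError("profile windows differ in shape")
    return float(np.abs(q - v).sum() / (2.0 * q.shape[0]))


def secondary_identity_score(prediction_letters: str, frag_ss: str) -> float:
    """1 - fraction of positions whose predicted letter matches the
    database secondary structure."""
    if len(prediction_letters) != len(frag_ss):
        raise ValueError("windows differ in length")
    same = sum(a == b for a, b in zip(prediction_letters, frag_ss))
    return 1.0 - same / len(frag_ss)


def secondary_similarity_score(prediction_probs_window: np.ndarray, frag_ss: str) -> float:
    """Mean over residues of 1 - P_pred(observed letter)."""
    p = np.asarray(prediction_probs_window, dtype=float)
    if p.shape[0] != len(frag_ss):
        raise ValueError("windows differ in length")
    idx = [SS_INDEX[s] for s in frag_ss]
    return float(np.mean(1.0 - p[np.arange(len(frag_ss)), idx]))


N_RAMA_BINS = 36  # 10-degree phi/psi bins


def _rama_bin(angle_deg: float) -> int:
    return min(int((angle_deg + 180.0) // 10.0), N_RAMA_BINS - 1)


def build_rama_maps(chunks) -> dict:
    """Per-SS-letter (phi, psi) histograms over the database, 10-degree bins,
    Laplace-smoothed (+1 per bin) and normalized to sum 1."""
    maps = {s: np.ones((N_RAMA_BINS, N_RAMA_BINS)) for s in SS_LETTERS}
    for chunk in chunks:
        for res in chunk.residues:
            if math.isnan(res.phi) or math.isnan(res.psi):
                continue
            maps[res.ss][_rama_bin(res.phi), _rama_bin(res.psi)] += 1.0
    return {s: m / m.sum() for s, m in maps.items()}


def rama_score(prediction_probs_window: np.ndarray, frag_torsions, rama_maps: dict) -> float:
    """Mean over residues of 1 - sum_t P_pred(t) * map_t(bin) / max(map_t);
    residues with undefined torsions contribute 1."""
    p = np.asarray(prediction_probs_window, dtype=float)
    scores = []
    for r, (phi, psi) in enumerate(frag_torsions):
        if math.isnan(phi) or math.isnan(psi):
            scores.append(1.0)
            continue
        s = 1.0
        for t_idx, t in enumerate(SS_LETTERS):
            m = rama_maps[t]
            s -= p[r, t_idx] * m[_rama_bin(phi), _rama_bin(psi)] / m.max()
        scores.append(s)
    return float(np.mean(scores))


def fragment_crmsd(frag_bb_ca: np.ndarray, reference_window_ca: np.ndarray) -> float:
    """Minimal CA RMSD (Angstrom) over rigid superpositions (Kabsch)."""
    return kabsch_rmsd(frag_bb_ca, reference_window_ca)


def atom_pair_restraint_score(frag_coords: dict, restraint) -> float | None:
    """Penalty of one distance restraint on a fragment.

    ``frag_coords`` maps (query residue index, atom name) to coordinates for
    atoms inside the fragment window.  Returns None when an atom is missing
    (restraint not applicable to this fragment).
    """
    pts = [frag_coords.get(a) for a in restraint.atoms]
    if any(p is None for p in pts):
        return None
    d = float(np.linalg.norm(np.asarray(pts[0]) - np.asarray(pts[1])))
    return restraint.func.distance_value(d)


def dihedral_restraint_score(frag_coords: dict, restraint) -> float | None:
    """Penalty of one dihedral restraint on a fragment (None if an atom is
    missing)."""
    pts = [frag_coords.get(a) for a in restraint.atoms]
    if any(p is None for p in pts):
        return None
    return restraint.func.angle_value(dihedral(*pts))


ABEGO_SENTINEL = "-"


def abego_bin(phi: float, psi: float, omega: float, *,
              a_psi=(-75.0, 50.0), g_psi=(-100.0, 100.0), cis_omega=90.0) -> str:
    """Classify backbone torsions into the five torsion bins.

    O = cis omega (|omega| < 90); for trans residues, phi < 0 splits into
    A (helical psi range) and B (extended), phi >= 0 into G and E.  Undefined
    torsions give the sentinel '-'.
    """
    if math.isnan(phi) or math.isnan(psi) or math.isnan(omega):
        return ABEGO_SENTINEL
    if abs(omega) < cis_omega:
        return "O"
    if phi < 0.0:
        return "A" if a_psi[0] <= psi < a_psi[1] else "B"
    return "G" if g_psi[0] <= psi < g_psi[1] else "E"


def torsion_bin_score(bin_probs_window: np.ndarray, frag_torsions) -> float:
    """Mean over residues of 1 - P(observed torsion bin).

    Rows of all 1.0 therefore always score 0 ("no constraint").  Residues
    with undefined torsions score 1 - max(row), which is likewise 0 for
    unconstrained rows.
    """
    p = np.asarray(bin_probs_window, dtype=float)
    from .constants import ABEGO_INDEX
    scores = []
    for r, (phi, psi, omega) in enumerate(frag_torsions):
        b = abego_bin(phi, psi, omega)
        if b == ABEGO_SENTINEL:
            scores.append(1.0 - float(p[r].max()))
        else:
            scores.append(1.0 - float(p[r, ABEGO_INDEX[b]]))
    return float(np.mean(scores))


def profile_submatrix_score(derived_profile_window: np.ndarray, vall_window_aa: str) -> float:
    """Mean over residues of 1 - P_derived(database amino acid)."""
    p = np.asarray(derived_profile_window, dtype=float)
    if p.shape[0] != len(vall_window_aa):
        raise ValueError("windows differ in length")
    idx = [AA_INDEX[a] for a in vall_window_aa]
    return float(np.mean(1.0 - p[np.arange(len(vall_window_aa)), idx]))


# ---------------------------------------------------------------------------
# score term classes


@dataclass
class ScoringContext:
    """Run-wide resources shared by score terms."""

    rama_maps: dict | None = None
    submatrix: object | None = None
    submatrix_scale: float = 0.5


class FragmentScoreTerm:
    """Base class: one configured score term bound to a query."""

    caching = False

    def __init__(self, spec: ScoreTermSpec, key: str, query, ctx: ScoringContext):
        self.spec = spec
        self.key = key
        self.query = query
        self.tag: str | None = None

    def prepare_chunk(self, chunk) -> None:
        pass

    def score(self, chunk, qpos0: int, offset: int, L_F: int) -> float:
        raise NotImplementedError


class CachingScoreTerm(FragmentScoreTerm):
    """A term whose fragment score is the mean of per-residue scores; fills
    an L_Q x L_C matrix once per chunk."""

    caching = True

    def residue_cache(self, chunk) -> np.ndarray:
        raise NotImplementedError

    def score(self, chunk, qpos0, offset, L_F):
        cache = self.residue_cache(chunk)
        diag = [cache[qpos0 + k, offset + k] for k in range(L_F)]
        return float(np.mean(diag))


class SequenceIdentityTerm(FragmentScoreTerm):
    def score(self, chunk, qpos0, offset, L_F):
        return sequence_identity_score(self.query.sequence[qpos0:qpos0 + L_F],
                                       chunk.sequence[offset:offset + L_F])


class ProfileScoreL1Term(CachingScoreTerm):
    def __init__(self, spec, key, query, ctx):
        super().__init__(spec, key, query, ctx)
        if query.profile is None:
            raise ConfigurationError("ProfileScoreL1 requires a query profile")

    def residue_cache(self, chunk):
        v = chunk.profile_matrix()
        if v is None:
            raise ConfigurationError(
                f"chunk {chunk.chunk_id}: vall lacks profile columns needed by ProfileScoreL1")
        q = self.query.profile
        return 0.5 * np.abs(q[:, None, :] - v[None, :, :]).sum(axis=2)


def _resolve_tag(spec, key, query):
    if not spec.extras:
        raise ConfigurationError(f"{key} requires a secondary-structure prediction tag")
    tag = spec.extras[0]
    if tag not in query.ss_predictions:
        raise ConfigurationError(
            f"{key}: no secondary-structure prediction tagged {tag!r} "
            f"(available: {sorted(query.ss_predictions) or 'none'})")
    return tag


class SecondaryIdentityTerm(FragmentScoreTerm):
    def __init__(self, spec, key, query, ctx):
        super().__init__(spec, key, query, ctx)
        self.tag = _resolve_tag(spec, key, query)
        self._letters = query.ss_predictions[self.tag].argmax_letters()

    def score(self, chunk, qpos0, offset, L_F):
        return secondary_identity_score(self._letters[qpos0:qpos0 + L_F],
                                        chunk.ss_string[offset:offset + L_F])


class SecondarySimilarityTerm(CachingScoreTerm):
    def __init__(self, spec, key, query, ctx):
        super().__init__(spec, key, query, ctx)
        self.tag = _resolve_tag(spec, key, query)

    def residue_cache(self, chunk):
        probs = self.query.ss_predictions[self.tag].probs
        idx = np.array([SS_INDEX[s] for s in chunk.ss_string])
        return 1.0 - probs[:, idx]


class RamaScoreTerm(CachingScoreTerm):
    def __init__(self, spec, key, query, ctx):
        super().__init__(spec, key, query, ctx)
        self.tag = _resolve_tag(spec, key, query)
        if ctx.rama_maps is None:
            raise ConfigurationError("RamaScore requires Ramachandran maps")
        self.maps = ctx.rama_maps

    def residue_cache(self, chunk):
        probs = self.query.ss_predictions[self.tag].probs
        # per chunk residue: normalized map probability for each SS letter
        ratios = np.zeros((3, chunk.L_C))
        defined = np.ones(chunk.L_C, dtype=bool)
        for c, res in enumerate(chunk.residues):
            if math.isnan(res.phi) or math.isnan(res.psi):
                defined[c] = False
                continue
            for t_idx, t in enumerate(SS_LETTERS):
                m = self.maps[t]
                ratios[t_idx, c] = m[_rama_bin(res.phi), _rama_bin(res.psi)] / m.max()
        cache = 1.0 - probs @ ratios
        cache[:, ~defined] = 1.0
        return cache


class TorsionBinSimilarityTerm(CachingScoreTerm):
    def __init__(self, spec, key, query, ctx):
        super().__init__(spec, key, query, ctx)
        if query.torsion_bin_probs is None:
            raise ConfigurationError("TorsionBinSimilarity requires torsion-bin probabilities")

    def residue_cache(self, chunk):
        from .constants import ABEGO_INDEX
        p = self.query.torsion_bin_probs
        cols = np.empty((p.shape[0], chunk.L_C))
        for c, res in enumerate(chunk.residues):
            b = abego_bin(res.phi, res.psi, res.omega)
            if b == ABEGO_SENTINEL:
                cols[:, c] = 1.0 - p.max(axis=1)
            else:
                cols[:, c] = 1.0 - p[:, ABEGO_INDEX[b]]
        return cols


class FragmentCrmsdTerm(FragmentScoreTerm):
    def __init__(self, spec, key, query, ctx):
        super().__init__(spec, key, query, ctx)
        if query.reference_coords is None:
            raise ConfigurationError("FragmentCrmsd requires a reference structure")
        self._ref_ca = query.reference_ca()

    def score(self, chunk, qpos0, offset, L_F):
        frag_ca = np.array([chunk.residues[offset + k].bb_coords["CA"] for k in range(L_F)])
        return fragment_crmsd(frag_ca, self._ref_ca[qpos0:qpos0 + L_F])


class _RestraintTerm(FragmentScoreTerm):
    kind: str

    def __init__(self, spec, key, query, ctx):
        super().__init__(spec, key, query, ctx)
        self._restraints = [r for r in query.restraints if r.kind == self.kind]
        self._valid = {}  # L_F -> restraints usable at that fragment length

    def _usable(self, L_F):
        if L_F not in self._valid:
            from .query_model import validate_restraints
            valid, _ = validate_restraints(self._restraints, L_F, self.query.sequence)
            self._valid[L_F] = valid
        return self._valid[L_F]

    def _one(self, frag_coords, restraint):
        raise NotImplementedError

    def score(self, chunk, qpos0, offset, L_F):
        lo, hi = qpos0 + 1, qpos0 + L_F  # 1-based query range of this fragment
        vals = []
        frag_coords = None
        for r in self._usable(L_F):
            resis = [resi for resi, _ in r.atoms]
            if min(resis) < lo or max(resis) > hi:
                continue
            if frag_coords is None:
                frag_coords = {}
                for k in range(L_F):
                    res = chunk.residues[offset + k]
                    for atom, xyz in res.bb_coords.items():
                        frag_coords[(lo + k, atom)] = xyz
            v = self._one(frag_coords, r)
            if v is not None:
                vals.append(v)
        return float(np.mean(vals)) if vals else 0.0


class AtomPairConstraintsTerm(_RestraintTerm):
    kind = "atom_pair"

    def _one(self, frag_coords, restraint):
        return atom_pair_restraint_score(frag_coords, restraint)


class DihedralConstraintsTerm(_RestraintTerm):
    kind = "dihedral"

    def _one(self, frag_coords, restraint):
        return dihedral_restraint_score(frag_coords, restraint)


class ProfileScoreSubMatrixTerm(CachingScoreTerm):
    """Scores database residues by a profile derived on the fly from the
    current query sequence convolved with a substitution matrix; the backbone
    of the flexible-design protocol where no precomputed profile exists."""

    def __init__(self, spec, key, query, ctx):
        super().__init__(spec, key, query, ctx)
        matrix = ctx.submatrix
        if matrix is None and spec.extras:
            matrix = load_substitution_matrix(spec.extras[0])
        if matrix is None:
            raise ConfigurationError("ProfileScoreSubMatrix requires a substitution matrix")
        from .query_model import profile_from_submatrix
        self.derived_profile = profile_from_submatrix(query.sequence, matrix,
                                                      ctx.submatrix_scale)

    def residue_cache(self, chunk):
        idx = np.array([AA_INDEX[a] for a in chunk.sequence])
        return 1.0 - self.derived_profile[:, idx]


def load_substitution_matrix(name_or_path):
    """Load a substitution matrix by bundled name (e.g. BLOSUM62) or from a
    text file in the standard NCBI layout."""
    import os
    from Bio.Align import substitution_matrices

    if os.path.exists(str(name_or_path)):
        return substitution_matrices.read(str(name_or_path))
    base = os.path.basename(str(name_or_path))
    for candidate in (base, base.split(".")[0].upper()):
        try:
            return substitution_matrices.load(candidate)
        except FileNotFoundError:
            continue
    raise ConfigurationError(f"cannot load substitution matrix {name_or_path!r}")


TERM_REGISTRY = {
    "SequenceIdentity": SequenceIdentityTerm,
    "ProfileScoreL1": ProfileScoreL1Term,
    "SecondaryIdentity": SecondaryIdentityTerm,
    "SecondarySimilarity": SecondarySimilarityTerm,
    "RamaScore": RamaScoreTerm,
    "TorsionBinSimilarity": TorsionBinSimilarityTerm,
    "FragmentCrmsd": FragmentCrmsdTerm,
    "AtomPairConstraintsScore": AtomPairConstraintsTerm,
    "DihedralConstraintsScore": DihedralConstraintsTerm,
    "ProfileScoreSubMatrix": ProfileScoreSubMatrixTerm,
}


def precompute_cache(term: CachingScoreTerm, query, chunk) -> np.ndarray:
    """The L_Q x L_C per-residue score matrix of a caching term for one
    chunk; entry (q, c) scores query position q against chunk residue c."""
    if not term.caching:
        raise ConfigurationError(f"{term.key} is not a caching term")
    return term.residue_cache(chunk)


# ---------------------------------------------------------------------------
# the scoring system


class ScoringSystem:
    """Priority-ordered evaluator with per-chunk caches and late scoring."""

    def __init__(self, specs, query, frag_sizes, ctx: ScoringContext | None = None):
        self.specs = sorted(specs, key=lambda s: (-s.priority, s.order))
        self.query = query
        self.frag_sizes = list(frag_sizes)
        self.ctx = ctx or ScoringContext()
        keys = score_term_keys(self.specs)
        self.terms = [TERM_REGISTRY[s.name](s, k, query, self.ctx)
                      for s, k in zip(self.specs, keys)]
        self.active = [t for t in self.terms if not t.spec.is_late]
        self.late = [t for t in self.terms if t.spec.is_late]
        self._windows: dict = {}

    def prepare_chunk(self, chunk) -> None:
        """Fill per-residue caches and window-mean tables for the chunk."""
        self._windows.clear()
        for term in self.active:
            if not term.caching:
                continue
            cache = term.residue_cache(chunk)
            for L_F in self.frag_sizes:
                nq = cache.shape[0] - L_F + 1
                nc = cache.shape[1] - L_F + 1
                if nq < 1 or nc < 1:
                    continue
                w = np.zeros((nq, nc))
                for k in range(L_F):
                    w += cache[k:k + nq, k:k + nc]
                self._windows[(term.key, L_F)] = w / L_F

    def evaluate_candidate(self, candidate) -> ScoreMap:
        """Score a candidate in descending priority with max-threshold early
        discard; zero-weight (late) terms are skipped."""
        qpos0 = candidate.query_pos - 1
        chunk, offset, L_F = candidate.chunk, candidate.offset, candidate.L_F
        values = {}
        total = 0.0
        for term in self.active:
            if term.caching:
                v = float(self._windows[(term.key, L_F)][qpos0, offset])
            else:
                v = term.score(chunk, qpos0, offset, L_F)
            values[term.key] = v
            spec = term.spec
            if spec.max_allowed is not None and v > spec.max_allowed:
                return ScoreMap(values=values, total=None, rejected_by=term.key)
            total += spec.weight * v
        return ScoreMap(values=values, total=total)

    def late_score(self, candidate) -> None:
        """Evaluate zero-weight metric terms on a final fragment, in place."""
        qpos0 = candidate.query_pos - 1
        for term in self.late:
            candidate.score_map.values[term.key] = term.score(
                candidate.chunk, qpos0, candidate.offset, candidate.L_F)

    def term_keys(self) -> list[str]:
        return [t.key for t in self.terms]

    def pool_weight_keys(self, tag: str) -> list[tuple[str, float]]:
        """(key, weight) of terms a quota pool with the given predictor tag
        ranks by: the pool's tagged terms plus untagged shared terms."""
        return [(t.key, t.spec.weight) for t in self.active
                if t.tag is None or t.tag == tag]


def evaluate_candidate(candidate, system: ScoringSystem) -> ScoreMap:
    """Functional wrapper around :meth:`ScoringSystem.evaluate_candidate`
    (the system must have been prepared for the candidate's chunk)."""
    return system.evaluate_candidate(candidate)
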