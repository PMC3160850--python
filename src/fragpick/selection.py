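"""Candidate collection and final fragment selection.

During the chunk-wise scan every surviving candidate is offered to a
*collector*; after the scan a *selector* turns collector contents into the
final N_F fragments per query position.  Three collectors are provided:

* BoundedCollector - a bounded priority queue keeping the best N_C
  candidates seen so far (the default protocol);
* GrabAllCollector - keeps everything that passed scoring (useful with
  restrictive max-score thresholds);
* QuotaCollector - a set of per-secondary-structure quota pools that
  diversify the library according to predicted SS propensities.

All orderings use a deterministic total order (score, pdb id, chain,
offset, vall line number) so runs are bit-reproducible and independent of
candidate arrival order.
"""
from __future__ import annotations

import math
from bisect import insort
from dataclasses import dataclass, field

from .errors import ConfigurationError
from .vall_store import VallChunk


@dataclass
class FragmentCandidate:
    """A (query position, chunk window) pairing: the thing scored, collected
    and - if it survives - written out as a fragment."""

    query_pos: int  # 1-based query start
    chunk: VallChunk
    offset: int  # 0-based start inside the chunk
    L_F: int
    score_map: object | None = None
    frag_id: int | None = None  # vall line number of the first residue

    def __post_init__(self):
        if self.frag_id is None:
            self.frag_id = self.chunk.residues[self.offset].line_id

    @property
    def total(self) -> float:
        return self.score_map.total

    @property
    def middle_ss(self) -> str:
        return self.chunk.residues[self.offset + self.L_F // 2].ss

    def residues(self):
        return self.chunk.residues[self.offset:self.offset + self.L_F]


def candidate_sort_key(cand: FragmentCandidate):
    """Ascending-total order with a deterministic tie-break."""
    return (cand.total, cand.chunk.pdb_id, cand.chunk.chain_id, cand.offset, cand.frag_id)


@dataclass
class CollectorConfig:
    """How candidates are kept: collector kind, capacity N_C and final
    library size N_F."""

    kind: str = "bounded"  # bounded | grab_all | quota
    n_candidates: int = 200  # N_C
    n_frags: int = 200  # N_F
    comparator: object = None  # optional custom key(cand)

    def __post_init__(self):
        if self.kind not in ("bounded", "grab_all", "quota"):
            raise ConfigurationError(f"unknown collector kind {self.kind!r}")
        if not (self.n_candidates >= self.n_frags >= 1):
            raise ConfigurationError(
                f"need N_C >= N_F >= 1, got N_C={self.n_candidates} N_F={self.n_frags}")


class BoundedCollector:
    """Bounded priority queue: keeps the ``capacity`` best candidates under
    the comparator key; inserting a better candidate evicts the worst."""

    def __init__(self, capacity: int, key=candidate_sort_key):
        if capacity < 1:
            raise ConfigurationError("collector capacity must be >= 1")
        self.capacity = capacity
        self.key = key
        self._items: list = []  # (key, cand), ascending

    def __len__(self):
        return len(self._items)

    def insert(self, cand) -> bool:
        k = self.key(cand)
        if len(self._items) >= self.capacity and k >= self._items[-1][0]:
            return False
        insort(self._items, (k, cand))
        if len(self._items) > self.capacity:
            self._items.pop()
        return True

    @property
    def contents(self) -> list:
        """Candidates in ascending key order."""
        return [c for _, c in self._items]


class GrabAllCollector:
    """Keeps every candidate that passed the scoring stage."""

    def __init__(self, key=candidate_sort_key):
        self.key = key
        self._items: list = []

    def __len__(self):
        return len(self._items)

    def insert(self, cand) -> bool:
        self._items.append(cand)
        return True

    @property
    def contents(self) -> list:
        return sorted(self._items, key=self.key)


def bounded_insert(collector, candidate) -> bool:
    """Offer a fully scored candidate to a collector."""
    return collector.insert(candidate)


def grab_all(collector, candidate) -> bool:
    return collector.insert(candidate)


def select_best_total(collector, n_frags: int) -> list:
    """The best N_F candidates by total score (deterministic tie-break).
    When the collector holds at most N_F candidates this is the identity on
    its contents."""
    return collector.contents[:n_frags]


# ---------------------------------------------------------------------------
# quota


@dataclass
class QuotaPoolSpec:
    """One (predictor, SS letter) pool: its share of the collector and the
    tagged scoring scheme it ranks by."""

    predictor_tag: str
    ss_letter: str
    predictor_share: float
    scoring_tag: str = ""

    def __post_init__(self):
        if not self.scoring_tag:
            self.scoring_tag = self.predictor_tag


class QuotaPool:
    """A bounded sub-collector accepting only candidates whose middle
    residue carries one secondary-structure letter."""

    def __init__(self, spec: QuotaPoolSpec, capacity: int, target: int,
                 rank_value=None):
        self.spec = spec
        self.capacity = capacity
        self.target = target  # how many this pool contributes to the final N_F
        self._rank = rank_value or (lambda cand: cand.total)
        self._queue = BoundedCollector(max(capacity, 1), key=self._key) \
            if capacity > 0 else None

    def _key(self, cand):
        return (self._rank(cand), cand.chunk.pdb_id, cand.chunk.chain_id,
                cand.offset, cand.frag_id)

    def __len__(self):
        return 0 if self._queue is None else len(self._queue)

    def accept(self, cand) -> bool:
        if self._queue is None:  # zero-capacity pools exist but take nothing
            return False
        if cand.middle_ss != self.spec.ss_letter:
            return False
        return self._queue.insert(cand)

    @property
    def contents(self) -> list:
        return [] if self._queue is None else self._queue.contents


def quota_accept(pool: QuotaPool, candidate) -> bool:
    return pool.accept(candidate)


def read_quota_config(path) -> dict:
    """Read a quota definition file (rows: pool_id pool_name fraction) into
    a predictor-tag -> share mapping."""
    shares = {}
    with open(path) as fh:
        for raw in fh:
            stripped = raw.strip()
            if not stripped or stripped.startswith("#"):
                continue
            cols = stripped.split()
            if len(cols) != 3:
                raise ConfigurationError(f"quota config line {stripped!r}: expected 3 columns")
            shares[cols[1]] = float(cols[2])
    if not shares:
        raise ConfigurationError(f"quota config {path} defines no pools")
    return shares


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _allocate(shares: dict, propensities: dict, budget: int) -> dict:
    """Per-(tag, letter) allowance: round(budget * share * propensity),
    repaired so the allocations never sum above the budget (largest pools
    are decremented first)."""
    alloc = {}
    for tag, share in shares.items():
        for letter in "HEL":
            alloc[(tag, letter)] = _round_half_up(budget * share * propensities[tag][letter])
    excess = sum(alloc.values()) - budget
    while excess > 0:
        key = max(alloc, key=lambda k: (alloc[k], k))
        if alloc[key] == 0:
            break
        alloc[key] -= 1
        excess -= 1
    return alloc


def quota_build(shares: dict, ss_predictions: dict, query_pos: int, L_F: int,
                n_candidates: int, n_frags: int, rank_factory=None) -> list[QuotaPool]:
    """Build the quota pools for one (query position, fragment length).

    Pool capacity = round(N_C * predictor share * predicted propensity of
    the pool's SS letter at the fragment's middle residue); the pool's
    contribution to the final selection is the analogous round on N_F.
    ``rank_factory(tag)`` supplies the within-pool ranking function.
    """
    from .constants import SS_INDEX

    total_share = sum(shares.values())
    if abs(total_share - 1.0) > 1e-6:
        raise ConfigurationError(f"quota shares sum to {total_share}, expected 1.0")
    missing = [t for t in shares if t not in ss_predictions]
    if missing:
        raise ConfigurationError(f"no secondary-structure prediction tagged {missing[0]!r}")
    middle = query_pos + L_F // 2  # 1-based middle residue of the window
    propensities = {
        tag: {letter: float(ss_predictions[tag].probs[middle - 1, SS_INDEX[letter]])
              for letter in "HEL"}
        for tag in shares
    }
    capacities = _allocate(shares, propensities, n_candidates)
    targets = _allocate(shares, propensities, n_frags)
    pools = []
    for tag, share in shares.items():
        for letter in "HEL":
            spec = QuotaPoolSpec(predictor_tag=tag, ss_letter=letter,
                                 predictor_share=share)
            rank = rank_factory(tag) if rank_factory is not None else None
            pools.append(QuotaPool(spec, capacities[(tag, letter)],
                                   targets[(tag, letter)], rank_value=rank))
    return pools


class QuotaCollector:
    """Offers every candidate to every pool of one (position, L_F)."""

    def __init__(self, pools: list[QuotaPool]):
        self.pools = pools

    def __len__(self):
        return sum(len(p) for p in self.pools)

    def insert(self, cand) -> bool:
        accepted = False
        for pool in self.pools:
            accepted |= pool.accept(cand)
        return accepted


def quota_select(pools: list[QuotaPool], n_frags: int) -> list:
    """Final quota selection: each pool contributes up to its target of its
    best candidates; duplicates (same vall line) across pools count once;
    any shortfall is back-filled with the best remaining candidates across
    all pools.  The result is sorted by total score."""
    taken: set[int] = set()
    picked: list = []
    for pool in pools:
        contributed = 0
        for cand in pool.contents:
            if contributed >= pool.target or len(picked) >= n_frags:
                break
            if cand.frag_id in taken:
                continue
            picked.append(cand)
            taken.add(cand.frag_id)
            contributed += 1
    if len(picked) < n_frags:
        leftovers = []
        for pool in pools:
            for cand in pool.contents:
                if cand.frag_id not in taken:
                    leftovers.append(cand)
        leftovers.sort(key=candidate_sort_key)
        for cand in leftovers:
            if len(picked) >= n_frags:
                break
            if cand.frag_id in taken:
                continue
            picked.append(cand)
            taken.add(cand.frag_id)
    picked.sort(key=candidate_sort_key)
    return picked
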