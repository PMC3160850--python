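# Methods

## The picking model

`fragpick` builds per-position libraries of short backbone fragments
(typically 3- and 9-mers) for a query protein from a flat-file database of
known structures (the "vall"). The database is organized into *chunks* —
maximal gap-free stretches of one chain — and scanned chunk by chunk, each
chunk visited exactly once. Every complete window of a chunk is paired with
every query position as a *fragment candidate*, scored, offered to a
per-position *collector*, and after the scan a *selector* reduces each
collector's N_C candidates to the final N_F fragments.

The total score of a candidate is the weighted sum

    S = sum_i w_i * S_i

over configured score terms, lower being better. Terms are evaluated in
descending priority; each may carry a maximum allowed value, and the first
term exceeding its maximum rejects the candidate without evaluating the
rest. Wherever the term's definition admits it, S_i is normalized to
[0, 1] with 0 for a perfect match and 1 for a complete failure to match
(restraint penalties are the exception: quadratic penalties are unbounded
by construction, and their max-allowed column is the intended control).

Terms whose fragment value is a mean of independent per-residue values
(profile L1, secondary-structure similarity, Ramachandran, torsion-bin)
cache an L_Q x L_C matrix of per-residue scores per chunk; overlapping
windows then read diagonal means from the cache. Zero-weight terms are
*late* metrics: skipped during the scan, evaluated only on the final
fragments, and printed in the score files (the fragment-vs-reference
CA-RMSD is the typical use).

## Score terms

* **SequenceIdentity** — 1 − (identical residues)/L_F.
* **ProfileScoreL1** — mean per-residue L1 distance between the query's
  and the database residue's 20-way amino-acid probability rows, halved to
  lie in [0, 1].
* **SecondaryIdentity / SecondarySimilarity** — hard and probabilistic
  agreement between a tagged secondary-structure prediction and the
  database's DSSP-reduced assignment. SecondarySimilarity uses
  1 − P_pred(observed letter) per residue; note that on its own it always
  saturates toward the likelier state (a 51% helix / 49% strand position
  selects helices), which is what the quota mechanism counteracts.
* **RamaScore** — 1 − Σ_t P_pred(t)·M_t(bin)/max(M_t) per residue, where
  M_t are per-SS-letter 36×36 (10°) phi/psi histograms built from the
  supplied vall with +1 Laplace smoothing; normalizing by the map maximum
  makes the modal bin score 0. Residues with undefined torsions score 1.
* **TorsionBinSimilarity** — 1 − P(observed torsion bin) per residue over
  the five-state classification (A/B/E/G plus cis-omega O). Probability
  rows are stored raw; an all-1.0 row scores 0 everywhere and is the
  documented "no constraint" idiom. Residues with undefined torsions score
  1 − max(row), so unconstrained rows stay at 0 there too.
* **FragmentCrmsd** — minimal CA RMSD between the fragment and the aligned
  window of a reference structure over all rigid superpositions (Kabsch
  SVD with the determinant correction).
* **AtomPairConstraintsScore / DihedralConstraintsScore** — mean penalty of
  the restraints that fit entirely inside the fragment window (harmonic,
  bounded, or circular-harmonic forms). A restraint is usable for fragment
  length L_F only if its residue span is strictly less than L_F and it
  references backbone/CB atoms (CB of glycine does not exist); unusable
  restraints are ignored with a warning, never an error.
* **ProfileScoreSubMatrix** — like ProfileScoreL1 but against a profile
  derived on the fly from the current sequence by substitution-matrix
  convolution (softmax of scale·M[a,·], default scale 0.5, BLOSUM62); this
  is what makes design-time repicking self-contained.

## Collectors, selection, quota

The bounded collector is a bounded priority queue: it keeps the N_C best
candidates seen so far under a pluggable comparator (default: total score).
All orderings share one deterministic tie-break — (score, pdb id, chain,
offset, vall line number) — which makes collector contents independent of
candidate arrival order and runs bit-reproducible. The grab-all collector
keeps everything that survived scoring and is intended for exhaustive
enumeration under restrictive max-score thresholds.

The quota mechanism diversifies by secondary structure. For each query
position there is one pool per (predictor, SS letter); a pool accepts a
candidate only if the *middle residue* of the window carries the pool's
letter in the database's DSSP assignment. Pool capacity is
round(N_C · predictor share · predicted propensity of the letter at the
middle residue) — rounded half-up, then repaired downward (largest pools
first) so capacities never exceed N_C; zero-capacity pools exist but accept
nothing. Within a pool, candidates are ranked by the pool's tagged terms
(its predictor's SecondarySimilarity/RamaScore) plus the untagged shared
terms such as ProfileScoreL1 — the design choice we made where the ranking
basis was genuinely open. Final selection takes the analogous round of N_F
from each pool, counts duplicates (same vall start line) across pools once,
back-fills any shortfall with the best remaining candidates across all
pools, and sorts by total score. Because identically scoring pools can hold
identical candidates, the worst case contributes only the largest pool's
distinct members before back-fill — the reason the quota protocol defaults
to N_C = 700 ≫ N_F = 200.

## Library layout conventions

A query of length L_Q gets, per fragment size L_F, one fragment set per
position 1…L_Q − L_F by default (100 residues → 91 sets of 9-mers and 97
sets of 3-mers; with 200 fragments per position at sizes 3 and 9 an
interior residue sees 3·200 + 9·200 = 2400 torsion triplets). A
`window_convention="inclusive"` switch yields the conventional
L_Q − L_F + 1 sets instead. Positions are 1-based in all files and
messages; offsets are 0-based internally.

## Synthetic data: what it emulates and what it does not

The fixtures generator builds databases from idealized secondary-structure
segments — helix (−60, −45), strand (−120, 130), loops drawn from a fixed
small library of allowed pairs — with Gaussian torsion noise (default sd
8° for decoys), trans omega, and segment lengths of 6–12 (H), 4–8 (E) and
2–5 (L) residues. Backbone coordinates are rebuilt from the torsions by
sequential internal-coordinate (NeRF) chain placement with ideal bond
geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å and standard angles);
recomputing torsions from the built coordinates reproduces the inputs to
1e-6 degrees, which the tests verify. Default database scale is 50 chunks
of 30–60 residues — small enough that a full scan takes about a second,
large enough that every position has hundreds of competing windows.

Profile columns are a BLOSUM62 softmax around the residue identity with
seeded log-normal jitter (sd 0.3) per row. The jitter matters: real
alignment-derived profiles are position-specific, and without it two
occurrences of the same residue type would carry *identical* rows, so any
sequence-duplicate window (common for 3-mers even in a small database)
would tie the planted copy exactly instead of merely resembling it.
Synthetic "experts" emit secondary-structure predictions as
0.90/0.05/0.05 rows with the top letter flipped at a configurable fraction
of positions, which is enough to exercise disagreeing predictors in quota
tests.

What the generator does not emulate: realistic sequence evolution,
side-chain packing, non-ideal bond geometry, chain breaks from real
crystallographic gaps, or genuinely correlated predictor errors. Passing
the planted-recovery tests therefore shows that the pipeline ranks an
exact structural/profile match first against plausible decoys — not that
fragment quality on natural proteins matches any benchmark.

## Numerical choices and degenerate inputs

* Undefined torsions are NaN sentinels in the vall dialect; mid-chunk NaN
  torsions (and CA–CA distances above 4.5 Å, configurable) declare chain
  breaks.
* Equal score-config priorities keep file order (stable sort).
* Torsion-bin region boundaries default to the common convention
  (cis O at |ω| < 90°; φ < 0 splits at ψ ∈ [−75, 50) into A vs B; φ ≥ 0
  at ψ ∈ [−100, 100) into G vs E) and are keyword-configurable, since the
  five-state definition admits minor variants.
* Per-fragment aggregation of cached terms divides by L_F so 3-mers and
  9-mers share one scale; weights can absorb the difference if a plain sum
  is wanted.
* SS2 probability rows are renormalized on load (the format is rounded to
  three decimals); torsion-bin rows are deliberately not.
* An empty position (every candidate rejected by thresholds) produces an
  empty fragment set and a warning, not an error.
* The flexible-loop protocol is a minimal stand-in for a design loop: per
  cycle it derives a fresh profile from the current sequence, repicks
  fragments for the loop windows against an all-loop SS objective, and
  applies a pluggable sequence perturbation (default: one seeded random
  mutation at a designable position). There is no rotamer packing or
  energy model.

## Known limitations

Chemical-shift scoring is not implemented. Only the first model and first
polymer chain of a PDB file are read. The restraint dialect covers the
harmonic, bounded and circular-harmonic forms only. The quota mechanism
diversifies on secondary structure only, though the pool design admits any
observable computable for both query and database.
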