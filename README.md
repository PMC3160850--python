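# fragpick

Fragment-based protein structure prediction and loop modeling (Rosetta-style
coarse-grained Monte Carlo) needs, for every position of a query sequence, a
library of short backbone fragments (typically 3- and 9-mers) drawn from
known structures. `fragpick` builds such libraries: it scans a flat-file
structure database ("vall") of gap-free chain chunks, scores every candidate
window against every query position with a configurable prioritized
composite score, collects candidates in bounded or quota-diversified
collectors, and writes per-position fragment and score files.

The total score of a candidate is

&nbsp;&nbsp;&nbsp;&nbsp;S = Σᵢ wᵢ·Sᵢ

with lower better and each term Sᵢ normalized to [0, 1] where possible
(0 = perfect match). Terms are evaluated in descending priority with
optional maximum-allowed thresholds that discard a candidate early;
per-residue terms are cached per chunk as L_Q × L_C matrices so overlapping
windows are read off diagonals. Available terms include sequence identity,
profile L1 distance, secondary-structure identity/similarity against tagged
predictions, Ramachandran-map agreement, five-state torsion-bin similarity,
distance/dihedral restraints, substitution-matrix-derived profiles for
design-time repicking, and fragment-vs-reference Cα-RMSD (usually as a
zero-weight "late" metric). The quota protocol diversifies each position's
library across (predictor, secondary-structure) pools sized by
round(N · share · predicted propensity at the window's middle residue).

Intended users: structural bioinformaticians preparing fragment libraries
for folding/design pipelines, and method developers who need a transparent,
scriptable picker with a synthetic-data generator for testing.

## Worked example

Generate a self-contained synthetic input set (a 31-chunk database with one
planted copy of the query, plus FASTA/profile/SS2/PDB files for it), then
pick 9-mers with a profile + secondary-structure score:

```sh
fragpick fixtures --seed 7 --out-dir demo --n-chunks 30 \
    --chunk-min 25 --chunk-max 40 --planted-length 32
cd demo

cat > simple.wghts <<'EOF'
# score name priority wght max extras
SecondarySimilarity 350 1.0 - predA
ProfileScoreL1 200 0.5 -
FragmentCrmsd 0 0.0 -
EOF

cat > run.flags <<'EOF'
-in:file:vall vall.txt
-in::file::checkpoint query.profile
-in::file::s query.pdb
-frags::ss_pred query.psipred.ss2 predA
-frags::scoring::config simple.wghts
-frags::bounded_protocol
-frags::frag_sizes 9
-frags::n_candidates 200
-frags::n_frags 5
-out::file::frag_prefix frags
-frags::describe_fragments frags.fsc
EOF

fragpick best-fragments @run.flags
head -6 frags.fsc.9mers
```

prints

```
#query_pos vall_pos pdbid c ss SecondarySimilarity ProfileScoreL1 FragmentCrmsd TOTAL FRAG_ID
         1        1  q000 A H    0.100    0.000    0.000    0.100       492
         1       12  d028 A H    0.100    0.552    0.881    0.376       950
         1       17  d027 A H    0.100    0.556    0.682    0.378       929
         1        3  d013 A H    0.100    0.557    0.450    0.379       432
         1        2  d028 A H    0.100    0.572    0.519    0.386       940
```

Each row is one selected fragment: query position, start residue in the
source chain, source pdb/chain, middle-residue secondary structure, the
score components in descending priority, the weighted total, and the vall
line number of the fragment start. The planted copy (`q000`) ranks first at
position 1 with zero profile distance; its `FragmentCrmsd` column — a
zero-weight metric computed only for the final fragments — confirms it
superimposes exactly on the reference structure, while the best decoys sit
around 0.5–0.9 Å. All fragments score 0.100 on SecondarySimilarity because
the synthetic predictor assigns the true letter probability 0.90.

The fragment file `frags.9mers` lists, under each
`position: P neighbors: N` header, the L_F source residues of every
selected fragment with their φ/ψ/ω torsions — the actual Monte Carlo move
set. The `quota` subcommand adds `--quota-config` (predictor shares) for
diversified picking, and `flexloop` repicks loop fragments across
sequence-design cycles. Library-level APIs (`fragpick.run_picking`,
`fragpick.run_flexloop_cycles`) expose the same workflow in Python; see
`docs/methods.md` for the scoring model, conventions and limitations.

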