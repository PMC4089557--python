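# elucid

Stochastic computer-assisted structure elucidation (CASE) from minimal
spectroscopic input: given a molecular formula and a one-dimensional ¹³C
NMR peak list (with attached-hydrogen counts from DEPT 90/135), `elucid`
searches the space of constitutional isomers with an evolutionary
algorithm and returns a ranked list of candidate structures.  It is
aimed at metabolomics-style problems — small, natural-product-like
unknowns (≲15 heavy atoms) for which only fast 1D experiments are
available, where a single ¹³C spectrum underdetermines the structure
and candidate *ranking* is as important as candidate *generation*.

## How it works

**Search.** A candidate is a hydrogen-suppressed connected multigraph
over the heavy atoms of the formula (implicit hydrogens forced by fixed
valences).  Evolution starts from a population of 16 individuals seeded
by mutating one random structure of the formula.  Each generation every
individual is mutated once (a Faulon-style elementary move that
conserves the formula), doubling the population; after fitness
evaluation, round-robin tournament selection keeps the fittest 16.
Five stagnant generations trigger a niche (vicinity) search: four
mutants of each of the two fittest individuals expand the population to
24 for a five-generation trial, after which it contracts back to 16 if
the search is still stalled.  Every distinct constitution encountered is
archived and the archive is ranked into the solution set.

**Fitness.**  Three judges score each candidate:

- *NMR judge.*  Each carbon's shift is back-calculated by looking up its
  HOSE code (spherical environment, heights 4 → 1 with longest-match
  backoff) in an index built from a reference set of assigned spectra.
  Each index entry stores the mean observed shift and a confidence
  limit, CL = max(5 ppm, SE · t₀.₉₇₅,ₙ₋₁).  Carbons are assigned to
  experimental peaks within attached-hydrogen classes; a carbon earns
  `P_max` points when |δ_pred − δ_exp| ≤ CL, so

      Score_nmr = Σ_carbons P_max·[|δ_pred − δ_exp| ≤ CL],
      NMRcost_norm = Score_nmr / (Carbon_count · P_max) ∈ [0, 1].

- *NP-likeness judge.*  A fragment model trained on natural-product vs
  synthetic corpora assigns each 3-sphere atom signature a smoothed
  log-odds; a molecule's raw score is the per-heavy-atom mean, and
  NPcost_norm = (raw − min)/(max − min), clipped to [0, 1], with
  min/max the extremes over the training molecules.

- *Anti-Bredt judge.*  Candidates with a double bond at a bridgehead
  whose rings all have ≤ 7 atoms are vetoed as sterically impossible.

The combined fitness (higher is better) weights NMR agreement twice as
strongly as NP-likeness:

    Cost_total = NMRcost_norm / 1 + NPcost_norm / 2  ∈ [0, 1.5].

Because many isomers can satisfy every shift constraint exactly, the
NP term is what breaks those ties in favour of candidates that look
like natural products.

## Worked example

Everything below runs offline: the reference shift set and NP corpora
are generated synthetically, and the problem is *closed-loop* — its
spectrum is the index's own prediction for a known answer, so the answer
scores NMRcost_norm = 1 by construction.

```python
from elucid import (FixtureSpec, make_reference_set, make_np_corpora,
                    make_closed_loop_problem, build_index, train_fragment_model,
                    from_smiles, JudgeConfig, EAConfig, Problem, run)

answer = from_smiles("CC1CCOC1")                      # 2-methyltetrahydrofuran
spec = FixtureSpec(n_molecules=100, seed=3)
index = build_index(make_reference_set(spec, exclude={answer.key}))
np_set, syn_set = make_np_corpora(FixtureSpec(n_molecules=25, seed=3))
model = train_fragment_model(np_set, syn_set)

formula, spectrum, _ = make_closed_loop_problem(answer, index)
sol = run(Problem(formula, spectrum, answer), index, model,
          JudgeConfig(mode="nmr_np"), EAConfig(max_generations=200, seed=11))
print(f"{len(sol)} candidate constitutions; answer rank {sol.answer_rank}")
for s in sol.solutions[:5]:
    print(f"rank {s.rank}  {s.key:<12} NMR={s.record.nmr_norm:.3f} "
          f"NP={s.record.np_norm:.3f} total={s.record.total:.3f}"
          + ("  <- answer" if s.is_answer else ""))
```

prints

```
63 candidate constitutions; answer rank 1
rank 1  CC1CCOC1     NMR=1.000 NP=0.510 total=1.255  <- answer
rank 1  CCC1COC1     NMR=1.000 NP=0.510 total=1.255
rank 3  C=C(CC)CO    NMR=0.800 NP=0.553 total=1.077
rank 4  C=C(C)CCO    NMR=0.800 NP=0.510 total=1.055
rank 4  C=CC(C)CO    NMR=0.800 NP=0.510 total=1.055
```

The search traversed 63 constitutions of C₅H₁₀O; the answer sits at
rank 1 (tied with an oxetane isomer that satisfies the same five peaks
— exactly the kind of residual ambiguity a ¹³C-only experiment leaves).
Candidates that miss one peak drop to NMR = 4/5 = 0.8 and rank below
any full match regardless of their NP score, reflecting the 1 : ½
weighting.

The same pipeline is available from the shell:

```sh
elucid make-fixtures --out-dir fixtures --seed 1
elucid build-index --reference fixtures/reference.sdf --out index.tsv
elucid train-np --np-set fixtures/np_set.sdf \
       --synthetic-set fixtures/synthetic_set.sdf --out np.tsv
elucid elucidate --problem problem.yaml --index index.tsv \
       --np-model np.tsv --runs 10 --out results/
```

`problem.yaml` is a small YAML file (formula, peak list, judge/search
configuration, optional answer molfile); the schema is described in
`docs/methods.md`.

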