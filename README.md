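# fairspots

Fairness-aware selection of spatial hot spots.

## The problem

Spatial scan statistics find *hot spots* — localized regions whose population
shows a significantly elevated rate on a binary attribute (disease, crime,
poverty) — and return them as a ranked list **S** = [S₁, …, S_m], most
noteworthy first. When k of them are chosen for policy action (patrols,
interventions, aid), picking the top-k maximizes noteworthiness but says
nothing about *who* bears the consequences: the covered population can be
heavily skewed on protected attributes such as religion, caste or ethnicity.

`fairspots` treats the choice of k hot spots as a bi-objective problem. For a
candidate 𝒮 ⊆ S with |𝒮| = k:

- **Noteworthiness** N(𝒮) = Σ_{S∈𝒮} rank(S) — lower is better; the top-k
  choice attains the minimum k(k+1)/2.
- **Fairness** F(𝒮) = Σ_{P∈𝒫} W(Distrib_P(D), Distrib_P(Pop(𝒮))) — the sum
  over protected attributes P of the Wasserstein distance between the
  categorical distribution of the covered population Pop(𝒮) (the union of
  the chosen hot spots' members, each individual counted once) and that of
  the whole dataset D. F = 0 exactly at statistical parity.

Candidates live in the 2-D N–F plane; the interesting ones form the Pareto
frontier (skyline). Because the frontier of all C(m, k) subsets is too large
to enumerate or peruse, the tool returns **τ diverse Pareto-efficient
candidates**: the frontier is traced from best-N to best-F and τ points are
taken at the end-points of equal segments, so the analyst sees the whole
trade-off spectrum and picks the point their policy domain justifies.

Two solvers are provided:

- `exact_search` — enumerate all C(m, k) subsets, extract the global
  frontier, select τ diverse points (budget-guarded; the ground truth).
- `beam_search` — a beam search over the lexically ordered subset prefix
  tree: at each level only a diverse, beam-width-b sample of that level's
  Pareto frontier is expanded, so at most m + (k−1)·b·m nodes are ever
  evaluated instead of C(m, k).

A circular Bernoulli (case/control) scan is included to produce the ranked
list, but any detector that outputs an ordered hot-spot list can be plugged
in through the JSON exchange format. Evaluation metrics (DC, coverage,
minimum diversity), a synthetic-data generator with planted clusters and
skewed demographics, and a CLI complete the toolkit.

## Worked example

```python
import fairspots as fs

ds = fs.generate_dataset(fs.SyntheticConfig(seed=0))          # 1000 individuals
S = fs.rank_hotspots(ds, fs.ScanConfig(m=20, overlap="disjoint"))
res = fs.beam_search(S, ds, config=fs.SearchConfig(k=5, tau=5, b=5))
for c in res.candidates:
    print(f"ranks={c.ranks}  N={c.nf.N:.0f}  F={c.nf.F:.3f}  |Pop|={len(c.member_union)}")
```

```
ranks=(1, 2, 3, 4, 5)  N=15  F=0.302  |Pop|=343
ranks=(1, 2, 4, 6, 7)  N=20  F=0.092  |Pop|=196
ranks=(2, 4, 5, 7, 12)  N=30  F=0.029  |Pop|=117
ranks=(2, 4, 5, 12, 13)  N=36  F=0.022  |Pop|=115
ranks=(2, 4, 5, 14, 18)  N=43  F=0.015  |Pop|=108
```

The first row is the fairness-agnostic top-5 (N = 15, the minimum, but its
343 covered individuals are demographically skewed, F = 0.302). Moving down
the list trades rank-sum for balance: the fairness end covers a population
within 1.5% transport distance of the dataset's composition at roughly
triple the rank sum. Comparing against the exact enumeration of all
C(20, 5) = 15504 subsets:

```python
rep = fs.evaluate_run(S, ds, None, res, fs.SearchConfig(k=5, tau=5, b=5))
print(f"DC={rep['DC']:.3f}  Cov={rep['Cov_approx']:.3f}/{rep['Cov_exact']:.3f}  "
      f"MD={rep['MD_approx']:.3f}/{rep['MD_exact']:.3f}  nodes={res.nodes_evaluated}")
```

```
DC=0.025  Cov=0.996/0.997  MD=0.081/0.069  nodes=258
```

The beam evaluated 258 of 15504 subsets, yet its result sits 0.025 mean
normalized distance from the exact one, dominates 99.6% of the candidate
universe (exact: 99.7%), and is at least as spread out (minimum pairwise
distance 0.081 vs 0.069).

The same pipeline from a shell:

```sh
fairspots simulate --n-points 1000 --seed 0 --out points.csv
fairspots scan     --input points.csv --m 20 --overlap disjoint --out hotspots.json
fairspots search   --hotspots hotspots.json --points points.csv --k 5 --tau 5 --b 5 --out result.json
fairspots evaluate --hotspots hotspots.json --points points.csv --k 5 --tau 5 --b 5 --report report.json
```

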