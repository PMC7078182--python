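# homophilynet

An agent-based simulator of how social networks form when friends must be
*chosen*. It asks a behavioural-ecology question: why do people pick friends
who resemble them? The model's answer is structural — similarity-based
(homophilic) friend choice raises the clustering coefficient of one's ego
network, restoring the local interconnectedness that is lost when relatives
become scarce through falling fertility, urbanisation or migration.

## The model

A population of *n* egos starts from a **kin network** *g* (adjacency *a*),
generated by a three-generation pedigree with mean fertility *f* per couple:
two egos are connected iff they share at least two grandparents, i.e. they are
full siblings or first cousins. Each ego carries a one-dimensional trait
φᵢ ~ U(0, 100) and wants a uniform number ν of social contacts.

Friendship edges are then added one at a time to the combined network *h*
(adjacency *b*, initialised to *a*). Each round picks the still-unsaturated
agent *xi* with the fewest contacts and a partner *xj* among unsaturated,
unconnected agents by one of three rules:

- **homophily** — minimise the type distance c = |φ_xi − φ_xj|;
- **weighted** — minimise (φ_xi − φ_xj)² · d_b(xi, xj)^0.5, where d_b is the
  shortest-path length on the current network (unreachable pairs use a
  sentinel distance n);
- **random** — uniform choice (baseline).

The loop ends when everyone has ν contacts or no eligible unconnected pair
remains. Completed networks are summarised by

- λ = 1 − Σa/Σb, the fraction of contacts that are friends rather than kin;
- χ, the clustering coefficient of *b* (three variants: the standard average
  local clustering `chi_local`, and the triple-sum statistic
  ΣᵢΣⱼΣₖ b_ij b_ik b_jk normalised by nν(ν−1) as `chi_nu` or by n²ν(ν−1) as
  `chi_nu_nsq`).

Sweeping fertility moves the population from kin-rich (low λ) to kin-poor
(high λ) and traces χ(λ): monotone decline under random choice, but a
**u-shaped** fall-then-rise when homophily drives friend choice — the
signature of a demographic-transition society regaining clique-iness through
similarity-based friendship.

## Worked example

```python
from homophilynet import (PedigreeParams, SocialNetwork, assign_traits,
                          fill_friendships, generate_pedigree, summarise)

kin = generate_pedigree(PedigreeParams(n_egos=200, fertility=2.0, seed=7))
kin = assign_traits(kin, 0.0, 100.0, seed=8)
base = SocialNetwork.from_kin(kin, nu=20)
for algorithm in ("homophily", "weighted", "random"):
    s = summarise(fill_friendships(base, algorithm=algorithm, rng=9))
    print(f"{algorithm:>9}:  lambda={s.lambda_friend_ratio:.3f}  "
          f"chi_local={s.chi_local:.3f}")
```

prints

```
homophily:  lambda=0.681  chi_local=0.424
 weighted:  lambda=0.681  chi_local=0.429
   random:  lambda=0.681  chi_local=0.154
```

All three algorithms fill the same kin network (λ, the friend share of edges,
is identical), but homophilic choice nearly triples the clustering of the
random baseline: choosing similar friends makes one's friends likely to
choose each other, closing triangles. The `examples/` directory has one
narrative script per capability (kin generation, friend choice, the
transition sweep).

A thin CLI wraps the same functions:

```bash
homophilynet simulate --n 200 --nu 20 --fertility 2 --algorithm homophily --seed 7
homophilynet sweep --fertility-grid 1,2,4,8 --replicates 5 --n 200 --nu 20 --out-dir out/
homophilynet plot --metrics-csv out/metrics.csv --out-png curve.png
```

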