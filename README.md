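# domcons

Consensus of protein structural domain assignments from multiple methods.

Partitioning a protein chain into structural domains is a first step in
structure classification and in evolutionary and functional analysis, but
the available automatic assignment algorithms (PDP, DomainParser2, PUU,
DDomain, NCBI/VAST, DHcL, Dodis, ...) take different conceptual approaches
and frequently disagree. `domcons` takes the per-chain outputs of any set
of such methods — it does **not** run them — and:

* scores **pairwise agreement** between two methods' partitions,
* groups agreeing methods and reports a **simple** or **weighted consensus**
  assignment with a reliability score,
* analyses where each method places domain/fragment **boundaries relative
  to secondary-structure elements** (does a boundary cut a helix or strand?).

It is aimed at structural bioinformaticians who have several domain
parsers' outputs for a chain and want a single, quantified answer, and at
method developers studying the tendencies of individual parsers.

## The method

**Agreement.** Two assignments of the same chain agree when they have the
same number of domains, each sequence-matched domain pair has the same
number of fragments, and for every matched domain and fragment the residue
intersection covers at least 80% of *both* partners:

```
|A_i ∩ B_i| / |A_i| ≥ 0.8   and   |A_i ∩ B_i| / |B_i| ≥ 0.8
```

**Grouping and reliability.** Methods are processed in a fixed order; each
is compared against the representative (founder) of every existing group
and joins the first group it agrees with, else founds a new group. A
group's reliability is the percentage of methods it contains (simple mode),
or the normalized sum of its members' weights (weighted mode):

```
R(G) = 100 · Σ_{m∈G} w_m / Σ_{m present} w_m
```

A consensus is declared when the best group reaches 40%; if the runner-up
is within 10 points, both groups are suggested. With seven methods this
means at least three must agree.

**Weights.** The weighted mode starts from each method's prior success
rate on a balanced multi-domain benchmark (PDP 84.4, NCBI 81.9,
DomainParser2 78.1, DDomain 76.5, PUU 74.0, DHcL 68.3, Dodis 40.0) and
applies nine context rules — keyed to predicted domain counts, domain
fragmentation, and the chain's secondary-structure class (all-α / all-β /
α-β) — each multiplying an affected method's weight by 0.9 or 1.1.

**Boundary analysis.** A helix (DSSP codes H/G/I) is *cut* by a boundary
falling anywhere inside it except the two residues at either end; a strand
(code E) except its first and last residue. Per-method cut fractions are
tabulated.

## Worked example

Simulate seven methods observing a three-domain chain of 300 residues
(boundary jitter ±4, some merging and fragmentation), then build both
consensuses:

```
$ domcons simulate --seed 3 --out-dir demo --jitter 4 --merge-prob 0.25 \
      --split-prob 0.0 --fragment-prob 0.15
$ domcons consensus --assignments demo/assignments.tsv --mode simple
Chain SYN1A — simple consensus: consensus
   group 1 [ 14.3%] members=PDP rep=PDP domains D1:1-100; D2:101-200,234-267; D3:201-233,268-300
 * group 2 [ 57.1%] members=DomainParser2,PUU,NCBI,Dodis rep=DomainParser2 domains D1:1-100; D2:101-198; D3:199-300
   group 3 [ 14.3%] members=DDomain rep=DDomain domains D1:1-93,129-164; D2:94-128,165-199; D3:200-300
   group 4 [ 14.3%] members=DHcL rep=DHcL domains D1:1-99; D2:100-300
```

Four of the seven methods (57.1% ≥ 40%) agree on a three-domain partition
with boundaries near 100 and 198, so that partition (the group
representative's, marked `*`) is the consensus; the other methods either
fragmented a domain (PDP, DDomain) or merged two (DHcL). The weighted mode
uses the same groups but rescales the votes:

```
$ domcons consensus --assignments demo/assignments.tsv --mode weighted \
      --dssp demo/chain.dssp
Chain SYN1A — weighted consensus: consensus
Structure class: alpha_beta
   group 1 [ 18.3%] ...
 * group 2 [ 53.5%] members=DomainParser2,PUU,NCBI,Dodis ...
```

The winning group's score drops from 57.1% to 53.5% because the dissenting
PDP carries the largest prior weight and, with the α-β rule active, the
methods outside PDP's group are mildly downgraded — still a consensus.
Boundary placement relative to secondary structure, with a per-residue
context track:

```
$ domcons boundaries --assignments demo/assignments.tsv --dssp demo/chain.dssp --range 95:135
method  n_boundaries  n_helix_cuts  n_strand_cuts  helix_cut_fraction  strand_cut_fraction ...
PDP     8             1             1              0.125               0.125
...
             95 .....+.........+.........+.........+..... 135
             SS ..EEEE....HHHHHHHHHHH....EEEE....HHHHHHHH
            PDP .....||..................................
```

NCBI placed half of its boundaries inside helices; PDP's boundary pair at
100/101 sits in a loop and cuts nothing.

The same machinery is available as a library:

```python
from domcons import simple_consensus, formats
sets = formats.read_assignments("demo/assignments.tsv")
result = simple_consensus(sets[("SYN1", "A")])
print(result.status, result.groups[result.consensus[0]].reliability)
```

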