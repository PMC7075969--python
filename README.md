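# sigconn

Transcriptome-signature connectivity scoring for in-silico drug repurposing.

## The problem

A disease state can be summarised by its transcriptome signature — the sets of
genes significantly up- and down-regulated versus control.  Given a reference
database of *instances* (drug-treatment experiments, each stored as a full
ranking of array probes by treatment-induced expression change), one can ask
which compounds induce transcriptional changes that *oppose* the disease
signature.  Such oppositional compounds — flagged by a negative similarity
mean — are repurposing candidates: if a drug reverses the molecular state of
the disease, it may reverse the phenotype too.  The same machinery run with a
*drug's* own signature finds that drug's transcriptional neighbours, and
mechanism-of-action classes over-represented among them suggest new
pharmacology for the query drug.

sigconn implements this workflow for computational biologists: signature
construction from differential-expression tables or treated/control matrices,
cross-namespace probe mapping, rank-matrix database handling, the
Kolmogorov–Smirnov connectivity scoring scheme with empirical permutation
p-values, candidate ranking, MOA tallies, and a seeded synthetic-database
generator with planted ground truth so the whole pipeline is testable offline.

## The statistic

For a query with up-tag ranks `V(1) < … < V(t)` inside an instance's ranking
of `n` probes, the signed KS enrichment is

```
a  = max_j ( j/t − V(j)/n )          b  = max_j ( V(j)/n − (j−1)/t )
es = a   if a ≥ b,   else  −b
```

`es = +1` means the tags sit at the very top of the ranking.  Each instance
gets `es_up` and `es_down`; the raw score is `s = es_up − es_down` when the two
disagree in sign, and `s = 0` (a *null* instance) when they agree.  Raw scores
are scaled database-wide (positive by the maximum, negative by the minimum) to
connectivity scores `c ∈ [−1, 1]`.  Per compound group the engine reports:

* **similarity mean** — arithmetic mean of the members' `c`;
* **n** — number of member instances ("number of arrays");
* **enrichment** — the same KS statistic applied to the group's positions in
  the `c`-descending ordering of all `N` instances;
* **p-value** — fraction of random same-size instance sets whose enrichment is
  at least as extreme (100,000 draws by default; exact enumeration when the
  subset count is small);
* **rank** — by p ascending, then |enrichment|, then |similarity mean|.

## Worked example

`examples/02_simulate_and_query.py` plants one oppositional compound in a
synthetic 50-compound database (1000 probes, 4 instances per compound, effect
size 2, noise 1) and recovers it:

```
database: 200 instances x 1000 probes, 50 compounds

top 5 compound groups (negative similarity mean = opposes the query state):

 rank    group_key  n_instances  similarity_mean  enrichment  p_value
    1 cpd_000::SIM            4        -0.911932      -0.985   0.0000
    2 cpd_023::SIM            4         0.714481       0.815   0.0009
    3 cpd_030::SIM            4        -0.061844      -0.620   0.0281
    4 cpd_005::SIM            4         0.528689       0.585   0.0437
    5 cpd_033::SIM            4         0.146858       0.585   0.0437

planted compound cpd_000 recovered at rank 1 with similarity mean -0.912 and p = 0
```

The planted compound's instances all score strongly negative — its
transcriptional effect reverses the query signature — so the group sits at the
bottom of the connectivity ordering with enrichment near −1, and no random
4-instance set among 10,000 draws matches it (`p = 0` is reported verbatim, as
is conventional for empirical permutation p-values).

The other examples: `examples/01_disease_signature.py` (DE table → signature →
probe mapping with audit counts) and `examples/03_moa_inference.py`
(second-order drug query + MOA class tally).

The same pipeline is exposed as a CLI for shell use:

```bash
sigconn simulate --config sim.yaml --out-dir sim/
sigconn query --db sim/rank_matrix.tsv --meta sim/meta.tsv \
    --up sim/query_cpd_000_up.grp --down sim/query_cpd_000_down.grp \
    --n-perm 10000 --seed 1 --out results.tsv
sigconn moa --results results.tsv --annotations moa.tsv --top 10 --test --out tally.tsv
```

Every run writes a JSON manifest (resolved configuration, input digests, seed,
timestamps, drop/conflict counts) alongside its outputs.

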