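# dyncomm

Community detection and tracking in **dynamic networks** — ordered series of
network snapshots such as time-course protein interaction networks or
longitudinal social event attendance. The package answers two questions:
which modules persist across snapshots, and how do individual nodes move
between them?

## Method

The pipeline has two stages.

**Stage 1 — partition and stitch.** Each snapshot is partitioned
independently into *groups* by Louvain optimisation of Newman–Girvan
modularity

&nbsp;&nbsp;&nbsp;&nbsp;*Q* = Σ<sub>c</sub> [ *w*<sub>in</sub>(c)/*W* − (*d*(c)/2*W*)² ],

with a seed-controlled node visit order so results are reproducible.
Groups are then stitched into persistent *communities*: the groups of the
first snapshot seed communities 1..G₁, and every later group searches
backwards through time — one earlier time point at a time — for the group
most similar to it by Jaccard index |A∩B|/|A∪B|. A match is acceptable
when the index reaches a user threshold (default **0.4**); matching within
a time point is one-to-one and greedy in descending Jaccard order; a group
with no acceptable match within the search horizon founds a new community.

**Stage 2 — explain node trajectories.** Two alternative models:

* **Cost model** (stable communities): each node gets a *home* community at
  every time point by a per-node dynamic program minimising unit costs
  (defaults all **1**) for *switching* home, *visiting* a community other
  than its home, and being *absent* while its home community is present
  (absence is exempt when the community is absent too). The summary
  statistic is the average cost per node per time step, *C*/(*N·T*).
* **Sub-community model** (unstable communities): each node simply belongs
  to its group's community at each time, and nodes whose full membership
  trajectories are identical — absences included — form new
  *sub-communities*; a constant trajectory keeps its original community, a
  unique non-constant one stays unassigned. Per-node *promiscuity* (the
  frequency of community changes over consecutive present time points,
  normalised by T−1) quantifies instability.

Inputs are dynamic GEXF files (spells or timestamps) or one plain edge-list
file per snapshot; outputs are CSV membership tables and colour-coded HTML
reports. A planted-partition generator with synchronized switching cohorts
and node dropout provides ground-truthed test data.

## Worked example

```python
from dyncomm import Cohort, DynamicCommunityDetector, SyntheticSpec, generate

spec = SyntheticSpec(
    n_communities=4, nodes_per_community=12, T=5,
    p_in=0.95, p_out=0.02, seed=7,
    cohorts=[Cohort(members=["n000", "n001", "n002"], targets=[0, 1, 0, 2, 0])],
)
net, truth = generate(spec)
det = DynamicCommunityDetector(model="subcommunity",
                               jaccard_threshold=0.4, random_state=0).fit(net)
print("communities:", det.n_communities_)
print("sub-communities:", det.n_subcommunities_)
print("cohort labels:", {n: det.result_.label[n] for n in ["n000", "n001", "n002"]})
print("cohort pattern:", det.result_.pattern["n000"])
```

prints

```
communities: 4
sub-communities: 1
cohort labels: {'n000': 5, 'n001': 5, 'n002': 5}
cohort pattern: (1, 2, 1, 3, 1)
```

The four planted blocks come back as communities 1–4, and the cohort of
three nodes that hops between blocks in lockstep is recovered as one new
sub-community (label 5, above the community range) with the non-constant
pattern it was planted with. Running the cost model on the same network
(`model="cost"`) reports `total cost: 6.0, average cost: 0.025`: each of
the three cohort members is cheapest explained as a loyal member of block 1
making two excursions (two visit events each), so communities here are
stable for everyone else and cheap overall.

The same pipeline is available from the shell:

```sh
dyncomm run t1.edges t2.edges t3.edges --model subcommunity --out-dir out/
dyncomm sweep t1.edges t2.edges t3.edges --thresholds 0.2,0.4,0.6 --out-dir out/
```

`run` writes `membership.csv` and `report.html`; `sweep` re-matches the
same stage-1 partitions at each threshold and tabulates community counts,
mean sizes and mean node promiscuity.

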