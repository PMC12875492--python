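# netcentral

Graph-level **centralization** quantifies how strongly a network is organized
around one or a few hubs — the structural signature behind essential proteins
in interaction networks, integrative regions in brain connectomes, or
influential accounts in social media. Node-level centralities identify the
hubs themselves; centralization asks the network-level question: *to what
extent does this graph have a dominant node at all?*

`netcentral` implements **11 normalized centralization measures** for simple
undirected graphs, each mapped to [0, 1] with the star graph at (or near) the
top of its scale, together with the **dual evaluation framework** used to
compare them:

- an **axiomatic battery** testing each measure against six postulates of
  centralization (P1: zero on single-node/complete/empty graphs; P2: one on
  stars; P3: isomorphism invariance; P4: value below 1 without a saturated
  node; P5/P6: monotone response to node saturation), scanned over every
  connected labeled graph on up to 5 nodes plus a registry of known
  counterexample graphs;
- a **numerical battery** tracking each measure across six canonical graph
  families (star, ring, complete, and single-edge perturbations of each) as
  the order grows, scored against the family's expected limiting behavior;
- a **weighted overall score**, Total = w_A·S_A + w_N·S_N, combining the
  number of axioms satisfied and the number of topology criteria passed.

## The measures

For a graph G with n nodes, m edges, degrees d_i, adjacency eigenvalues λ_i:

| id  | name                          | definition (normalized)                              |
|-----|-------------------------------|------------------------------------------------------|
| NDC | degree centralization (Freeman) | n(d_max − d̄) / ((n−1)(n−2))                        |
| NBC | betweenness centralization    | Σ_i (C_B* − C_B(i)) / (n−1), normalized betweenness  |
| NCC | closeness centralization      | (2n−3) Σ_i (C_C* − C_C(i)) / ((n−1)(n−2))            |
| NHD | hub dominance                 | d_max / (n−1)                                        |
| NDV | degree variance               | Var(d) / DV_max(n)                                   |
| NGC | Gini coefficient of degrees   | Gini(d) / ((n−2)/n)                                  |
| NDE | degree entropy                | H(degree histogram) / ln n                           |
| NHT | hub formation tendency        | (Σd²/Σd) / ((m+1)/2)                                 |
| ABH | assortativity-based hubness   | (1 − r)/2, r = degree assortativity                  |
| ECD | eigenvector dispersion        | Var(eigenvector centrality) / ((n−1)/n²)             |
| NNC | natural-connectivity centralization | (λ_max − λ̄(G)) / λ_max, λ̄ = ln mean(e^λ)      |

Degenerate inputs (too few nodes, no edges) return 0 by stated convention and
are flagged as such on the returned `MeasureValue`.

## Worked example

The 6-node graph with edge list (0,1),(0,3),(0,4),(0,5),(1,2) — a star with
one edge rewired — is nearly maximally centralized:

```
$ printf '0 1\n0 3\n0 4\n0 5\n1 2\n' > rewired_star6.el
$ netcentral measure rewired_star6.el
ABH     0.869565
ECD     0.155298
NBC     0.82
NCC     0.73125
NDC     0.7
NDE     0.484196
NDV     0.55
NGC     0.45
NHD     0.8
NHT     0.8
NNC     0.764167
```

NBC = 0.82 says node 0 controls most shortest paths; NDC = 0.7 says its
degree advantage is 70% of the maximum a 6-node graph allows. This graph is
also an instructive stress case: saturating node 3 (connecting it to every
other node) *creates* a second hub yet **drops** NBC to 0.36 and NDC to 0.6 —
a violation of the monotone-saturation postulate P6 that the axiom battery
detects for NBC and NDC:

```python
>>> import netcentral as nc, networkx as nx
>>> g = nx.Graph([(0, 1), (0, 3), (0, 4), (0, 5), (1, 2)])
>>> nc.nbc(nc.saturate(g, 3)).value, nc.ndc(nc.saturate(g, 3)).value
(0.36, 0.6)
```

Running both batteries with equal weights ranks the measures:

```
$ netcentral score
         S_A  S_N  w_A  w_N  total
measure
NBC        5    6  0.5  0.5    5.5
NCC        5    6  0.5  0.5    5.5
NDC        5    6  0.5  0.5    5.5
NHD        5    3  0.5  0.5    4.0
ABH        3    4  0.5  0.5    3.5
NDE        3    4  0.5  0.5    3.5
NDV        3    4  0.5  0.5    3.5
NHT        3    4  0.5  0.5    3.5
NNC        4    3  0.5  0.5    3.5
NGC        2    4  0.5  0.5    3.0
ECD        2    3  0.5  0.5    2.5
```

The betweenness, closeness and degree centralizations come out on top (5.5 of
6 each); `netcentral triplet` computes exactly this trio for real networks,
extracting the largest connected component first when the input is
disconnected:

```
$ netcentral triplet rewired_star6.el
rewired_star6.el: n=6 m=5 d=(1,1.67,4) NBC=0.820 NCC=0.731 NDC=0.700
```

Other subcommands: `netcentral axioms` (compliance matrix with witness
graphs), `netcentral benchmark` (pass/fail matrix with value trajectories);
both emit JSON or CSV. Inputs may be whitespace edge lists, GML, or GraphML.

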