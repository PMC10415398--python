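# hicscape

Solution landscapes of multiscale communities in chromosome contact networks.

## The problem

Hi-C experiments count 3D contacts between all pairs of fixed-size genomic
bins (here 100 kb), producing a dense weighted network per chromosome.
Community detection on these networks — grouping bins with above-expected
mutual contacts — recovers structures such as TADs and A/B compartments.
But Hi-C networks are almost fully connected, so many different partitions
can have nearly identical quality: the optimum is *degenerate*, and any
single run of any community-detection method may return a structurally
arbitrary answer.

`hicscape` addresses this by mapping the **solution landscape** instead of
trusting one partition. It is aimed at computational biologists analysing
contact maps (Hi-C, scHi-C, HiChIP, or synthetic polymer models) who need
to know *at which scales* a community division is reproducible, and which
genomic bins are robustly assigned.

## The method

Communities maximise the parametric modularity with a polymer-aware null
model:

```
Q = (1/2m) Σ_{i≠j} (A_ij − γ P⁰_ij) δ(C_i, C_j)

P⁰_ij = 2m k_i k_j |i−j|^(−α) / Σ_{i'≠j'} k_i' k_j' |i'−j'|^(−α)
```

where `A` is the (Knight–Ruiz-balanced) contact matrix, `m` its total
weight, `k_i` node strengths, `γ` the scale parameter (larger γ → smaller
communities), and `α` the contact-decay exponent (≈1.08 for long-range,
≈0.75 for short-range contacts; α = 0 recovers the Newman–Girvan null).
A stochastic generalized-Louvain optimizer accepts positive-gain moves
with probability proportional to the gain, sampling feasible partitions
rather than collapsing onto one.

Many independent runs are then analysed as an ensemble:

- **distances** — symmetrized weighted mean Jaccard distance `d` between
  partitions (0 = identical);
- **landscape class** — mean distance MD(d) and quality variation CV(Q)
  flag degenerate regimes (dissimilar partitions, indistinguishable Q);
- **clusters** — partitions grouped around quality-ordered centres at
  threshold `d_max = 0.10`;
- **cores & fringe nodes** — per centre community, the node subset staying
  co-clustered in ≥ p = 0.9 of the cluster's partitions; `1 − c` scores
  each bin's assignment instability;
- **effective size** — `ŝ = n / 2^H` from the Shannon entropy `H` of
  community sizes, mapping γ to an interpretable scale in Mb;
- **annotation comparison** — adjusted mutual information against TAD or
  sub-compartment tracks.

## Worked example

```python
import hicscape as h

# synthetic chromosome: 300 bins, six planted 5 Mb blocks, power-law decay
spec = h.SyntheticSpec(n_bins=300, block_sizes=(50,)*6,
                       alpha_true=0.75, mu=50.0, epsilon=5.0, seed=20)
net, planted = h.generate_contacts(spec)

ens = h.sample_ensemble(net, alpha=0.75, gamma=1.0, n_runs=20, master_seed=2)
dm = h.pairwise_distances(ens)
print("Q_max      ", round(float(ens.qualities.max()), 4))
print("AMI planted", round(h.ami(ens.best(), planted), 4))
print("MD(d)      ", round(h.summarize_landscape(ens, dm).mean_distance, 4))

cs = h.cluster_partitions(ens, dm, d_max=0.10)
centre = ens[cs.centres[0]]
members = [ens[i] for i in cs.members(0) if i != cs.centres[0]]
cores = h.core_communities(members, centre, p=0.9)
print("clusters   ", cs.n_clusters)
print("core frac  ", round(cores.core_fraction, 4))
print("s_hat bins ", round(h.effective_size(ens.best(), net.resolution).effective_size_bins, 2))
```

prints

```
Q_max       0.3443
AMI planted 1.0
MD(d)       0.0
clusters    1
core frac   1.0
s_hat bins  50.0
```

With this strong planted signal every run recovers the six blocks exactly:
one cluster, all 20 partitions identical (MD(d) = 0), every bin a core
node, and an effective community size of 50 bins (5 Mb) — the planted
block size. On real chromosomes the interesting output is precisely the
regimes where these numbers degrade.

The same pipeline is available from the shell:

```bash
hicscape synth --blocks 50,50,50,50,50,50 --seed 1 --out work/synth
hicscape sample --input work/synth/contacts.tsv --alpha 0.75 --gamma 1.0 \
    --runs 20 --seed 2 --out work/ens
hicscape landscape --ensemble work/ens/ensemble.tsv --out work/land
hicscape cores --ensemble work/ens/ensemble.tsv --out work/cores
```

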