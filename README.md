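# selfsim

Ancestral rRNA reconstruction and detection of the repeated short fragments
("local self-similarities") shared by 16S, 5S and 23S ribosomal RNAs.

The three rRNA chains of the last universal common ancestor (LUCA) appear
to share short stretches with identical purine/pyrimidine arrangements —
possible relics of self-replicating RNA-world fragments that seeded the
ribosome.  `selfsim` is a library plus CLI for the full analysis chain
behind that question, aimed at molecular-evolution researchers:

1. **Ancestral reconstruction.** Given an aligned character matrix and a
   rooted tree with branch lengths, each alignment column is treated as an
   independent character under a symmetric 5-state Mk model over
   {A, U, G, C, gap}, with

   `p_stay(t) = 1/5 + (4/5) e^{-(5/4) r t}`, `p_change(t) = (1 - p_stay(t))/4`.

   Marginal state probabilities at the root or any clade MRCA come from a
   pruning (inside) pass plus an outside pass; the reconstructed sequence
   takes the per-site argmax, with the gap state written as `N`.
2. **Self-similarity search.** The reconstructed 16S+5S+23S chains are
   concatenated and projected to the RY level (A,G → R; U,C → Y) or kept at
   the AUGC level.  Every k-mer arrangement occurring at least twice (never
   crossing a molecule boundary, never containing N) is a *fragment*;
   occurrences overlapping an already-kept fragment by strictly more than
   40% of k are discarded as redundant (pseudo-positive) hits.
3. **Conservation tiers.** Fragments are projected through pairwise
   alignments onto extant species of six kingdoms; a fragment conserved in
   archaea and bacteria is `AB_conserved`, and in at least five of six
   kingdoms `universal`.
4. **Functional-site enrichment.** The number of catalogued ribosomal
   functional positions falling inside the fragments is compared with a
   Monte-Carlo null that samples the same number of positions uniformly
   without replacement (hypergeometric; analytic mean `n·K/N`).

## Worked example

Plant a repeated 15-mer into a random 360-nt three-chain background, search
it, and run the enrichment null at the study's parameters:

```python
from selfsim import (Level, Molecule, PlantedFragment, plant_repeats,
                     encode, find_repeats, filter_overlaps, mc_null)

plant = PlantedFragment(level=Level.AUGC, k=15, arrangement="AUGGCAUCCGAAUGC",
                        positions=((Molecule.S16, 30), (Molecule.S23, 80)))
concat, truth = plant_repeats({Molecule.S16: 120, Molecule.S5: 40,
                               Molecule.S23: 200}, [plant], seed=21)
fs = filter_overlaps(find_repeats(encode(concat, "augc"), 15))
for f in fs.fragments:
    print(f"  {f.molecule.value} {f.start}-{f.end}  {f.arrangement}")

print(mc_null(4566, 230, 805, reps=10_000, seed=1, observed=69).summary())
```

prints

```
  16S 30-44  AUGGCAUCCGAAUGC
  23S 80-94  AUGGCAUCCGAAUGC
Functional-site enrichment (sampling without replacement)
  positions sampled per rep: 805 of 4566
  functional positions:      230
  repetitions:               10000 (seed 1)
  null mean:                 40.52 (analytic 40.55, sd 5.70)
  observed:                  69
  empirical p (upper tail):  9.999e-05
```

The search recovers exactly the two planted occurrences (one type, union
span 30 nt).  In the enrichment test, sampling 805 of 4566 positions hits
about 41 of the 230 functional positions by chance, so an observed count of
69 is far in the upper tail (empirical p ≈ 1e-4 at 10,000 repetitions).

The CLI mirrors the library: `selfsim run --config run.yaml` drives the
whole pipeline, and `selfsim reconstruct | search | enrich | simulate`
expose the stages individually (see `selfsim --help`).

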