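import numpy as np
import pandas as pd
import pytest

from trccomics import (
    merge_union,
    normalize,
    simulate_counts,
    simulate_genome,
    simulate_peaks,
)


@pytest.fixture(scope="session")
def small_world():
    """50-gene genome with 10 planted regulon genes and zero-noise peaks."""
    annotation, sequences, truth = simulate_genome(n_genes=50, n_regulon=10, seed=11)
    tfe3, k27 = simulate_peaks(annotation, truth, n_samples=4, seed=11)
    return {
        "annotation": annotation,
        "sequences": sequences,
        "truth": truth,
        "tfe3": tfe3,
        "k27": k27,
        "compendium": merge_union(tfe3),
    }


@pytest.fixture(scope="session")
def cohort():
    """200-gene cohort of 60 tumour samples with planted signature structure."""
    annotation, sequences, truth = simulate_genome(n_genes=200, n_regulon=40, seed=5)
    counts, reference, gene_sets = simulate_counts(annotation, truth, n_samples=60, seed=5)
    return {
        "annotation": annotation,
        "truth": truth,
        "counts": counts,
        "normalized": normalize(counts),
        "reference": reference,
        "gene_sets": gene_sets,
    }


def brute_force_union(intervals: pd.DataFrame) -> pd.DataFrame:
    """O(n^2) oracle: union-find over the pairwise-overlap graph.

    Two intervals belong together iff they share >= 1 base (transitively);
    book-ended intervals do not overlap under half-open coordinates.
    """
    rows = []
    for chrom, sub in intervals.groupby("chrom"):
        ivs = list(zip(sub["start"], sub["end"]))
        parent = list(range(len(ivs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                if ivs[i][0] < ivs[j][1] and ivs[j][0] < ivs[i][1]:
                    parent[find(i)] = find(j)
        comps = {}
        for i, (s, e) in enumerate(ivs):
            r = find(i)
            lo, hi = comps.get(r, (s, e))
            comps[r] = (min(lo, s), max(hi, e))
        for s, e in comps.values():
            rows.append((chrom, int(s), int(e)))
    return (
        pd.DataFrame(rows, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )


def random_intervals(rng, n, chroms=("chrA", "chrB"), span=500):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, 60, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": starts,
            "end": starts + lengths,
        }
    )
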