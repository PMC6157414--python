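"""Shared fixtures: small simulated datasets and the hand-planted QC matrix."""

import numpy as np
import pandas as pd
import pytest

from wssgblup import GenotypeMatrix, Pedigree, SimConfig, SnpMap, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """~180-animal, 600-SNP dataset with one 30%-variance QTL."""
    cfg = SimConfig(
        n_founders=60, n_generations=1, n_families_per_gen=30,
        n_offspring_per_family=6, n_chromosomes=4, snps_per_chromosome=150,
        n_qtl=1, qtl_variance_shares=(0.30,), seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def trio_pedigree():
    return Pedigree(
        pd.DataFrame(
            {"animal": ["1", "2", "3"], "sire": ["0", "0", "1"], "dam": ["0", "0", "2"]}
        )
    )


def random_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """Random valid pedigree: each animal's parents drawn from earlier animals."""
    rows = []
    for i in range(n):
        if i < max(4, n // 10) or rng.random() < 0.15:
            rows.append((str(i + 1), "0", "0"))
        else:
            s, d = rng.choice(i, size=2, replace=False)
            rows.append((str(i + 1), str(s + 1), str(d + 1)))
    return Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))


def planted_qc_matrix():
    """10 animals x 10 SNPs with hand-planted QC failures.

    Plants (filter order SNP-CR -> animal-CR -> MAF -> HWE, recomputed on
    the survivors at each step):
      * s3: call rate 0.8 (missing in a8, a9)       -> SNP_CR
      * a10: missing 5 of the 9 surviving SNPs
        (s5..s9), call rate 4/9 ~ 0.44              -> ANIMAL_CR
      * s1, s2: monomorphic on the remaining 9      -> MAF
      * s4: all heterozygous, |1 - 2pq| = 0.5       -> HWE
      * s5..s10 pass everything                     -> 6 SNPs, 9 animals
    """
    n = np.nan
    # columns s1..s10; rows a1..a10
    codes = np.array(
        [
            # s1 s2 s3 s4 s5 s6 s7 s8 s9 s10
            [0, 2, 1, 1, 0, 0, 2, 0, 1, 0],
            [0, 2, 1, 1, 1, 1, 1, 0, 0, 1],
            [0, 2, 1, 1, 1, 2, 0, 1, 1, 1],
            [0, 2, 1, 1, 0, 0, 1, 1, 2, 0],
            [0, 2, 1, 1, 2, 1, 1, 2, 0, 2],
            [0, 2, 1, 1, 1, 1, 2, 1, 1, 1],
            [0, 2, 1, 1, 0, 0, 0, 0, 1, 0],
            [0, 2, n, 1, 1, 2, 1, 1, 0, 1],
            [0, 2, n, 1, 1, 1, 0, 2, 2, 1],
            [1, 1, 1, 1, n, n, n, n, n, 2],
        ],
        dtype=float,
    )
    smap = SnpMap(
        pd.DataFrame(
            {
                "snp_id": [f"s{j + 1}" for j in range(10)],
                "chromosome": ["1"] * 10,
                "position": np.arange(1, 11) * 1000,
            }
        )
    )
    ids = [f"a{i + 1}" for i in range(10)]
    return GenotypeMatrix(ids, smap, codes)
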