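"""Shared fixtures: small simulated datasets and exact-test oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from rrbsdiff.io import SampleTable
from rrbsdiff.simulate import GenomeSpec, PlantConfig, RrbsSimulation


def make_table(
    rows, sample_id="T1", condition="S", replicate=1
) -> SampleTable:
    """Build a SampleTable from (chrom, pos, strand, coverage, meth) rows."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "coverage", "meth_count"]
    )
    df["meth_pct"] = 100.0 * df["meth_count"] / df["coverage"]
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )
    return SampleTable(sample_id, condition, replicate, df)


def exact_fisher_two_sided(kt: int, nt: int, kr: int, nr: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Exact rational arithmetic: sums P(k) over every table with the same
    margins whose point probability is <= that of the observed table.
    """
    K, N = kt + kr, nt + nr
    p_obs = comb(nt, kt) * comb(nr, kr)
    lo, hi = max(0, K - nr), min(K, nt)
    total = 0
    for k in range(lo, hi + 1):
        p_k = comb(nt, k) * comb(nr, K - k)
        if p_k <= p_obs:
            total += p_k
    return float(Fraction(total, comb(N, K)))


@pytest.fixture(scope="session")
def small_sim() -> RrbsSimulation:
    """A miniature experiment: 2 autosomes + a short repeat array."""
    spec = GenomeSpec(
        chrom_lengths={"chrA": 150_000, "chrB": 150_000},
        array_length=60_000,
        n_cgi_per_autosome=10,
        genes_per_autosome=8,
    )
    plant = PlantConfig(
        n_reversion=4, n_treatment_hypo=2, n_treatment_hyper=2,
        n_resistance_only=2,
    )
    return RrbsSimulation(spec=spec, plant=plant, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_sim, tmp_path_factory):
    """The miniature experiment written as a dataset directory."""
    outdir = tmp_path_factory.mktemp("dataset")
    small_sim.write_dataset(outdir, force=True)
    return outdir


@pytest.fixture(scope="session")
def small_samples(small_sim):
    return small_sim.samples()
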