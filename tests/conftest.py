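"""Shared fixtures: small simulated panels/cohorts and the end-to-end demo run."""

import numpy as np
import pandas as pd
import pytest

from finerisk import run_demo, synthio
from finerisk.containers import DosageMatrix, SummaryStatSet


def make_panel(genotypes: np.ndarray, mafs=None, chrom="1", spacing=5_000,
               prefix="rs", alleles=("A", "G")) -> DosageMatrix:
    """Wrap a raw genotype array (n x m) into a DosageMatrix."""
    n, m = genotypes.shape
    snvs = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": 10_000 + np.arange(m) * spacing,
            "effect_allele": alleles[0],
            "other_allele": alleles[1],
            "locus": "locus01",
        },
        index=pd.Index([f"{prefix}{j + 1:03d}" for j in range(m)], name="snv"),
    )
    samples = pd.Index([f"I{i + 1:06d}" for i in range(n)], name="individual")
    return DosageMatrix(samples, snvs, genotypes.astype(float))


def ar_locus_panel(n: int, m: int, maf: float, ld: float, seed: int) -> DosageMatrix:
    """AR-correlated single-locus genotype panel at a fixed MAF."""
    rng = np.random.default_rng(seed)
    g = synthio._simulate_locus_dosages(n, np.full(m, maf), ld, rng)
    return make_panel(g)


def case_control_locus(seed: int, n: int = 20_000, m: int = 50, maf: float = 0.3,
                       ld: float = 0.5, causal=(10, 35), beta: float = 0.3):
    """Balanced case-control cohort with planted causal SNVs in one AR locus.

    Status is drawn from a logistic model at 50% prevalence and every
    individual is kept, giving an analysis sample of exactly n.
    """
    from scipy.optimize import brentq
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    panel = make_panel(synthio._simulate_locus_dosages(n, np.full(m, maf), ld, rng))
    dos = panel.dosages[:, list(causal)]
    lp = (dos - dos.mean(axis=0)) @ np.full(len(causal), beta)
    alpha = brentq(lambda a: expit(a + lp).mean() - 0.5, -10, 10)
    status = (rng.uniform(size=n) < expit(alpha + lp)).astype(int)
    cohort = pd.DataFrame({"status": status, "study": "sim"}, index=panel.samples)
    causal_ids = [panel.snvs.index[j] for j in causal]
    return panel, cohort, causal_ids


def make_sumstats(study: str, snvs, b, se, p=None, freq=0.3, n=10_000,
                  a1="A", a2="G") -> SummaryStatSet:
    """Hand-constructed summary-statistic set for closed-form tests."""
    from scipy.stats import norm

    k = len(snvs)
    b = np.broadcast_to(np.asarray(b, dtype=float), k)
    se = np.broadcast_to(np.asarray(se, dtype=float), k)
    if p is None:
        p = 2 * norm.sf(np.abs(b / se))
    table = pd.DataFrame(
        {
            "a1": np.broadcast_to(np.asarray(a1, dtype=object), k),
            "a2": np.broadcast_to(np.asarray(a2, dtype=object), k),
            "freq": np.broadcast_to(np.asarray(freq, dtype=float), k),
            "b": b,
            "se": se,
            "p": np.broadcast_to(np.asarray(p, dtype=float), k),
            "n": np.broadcast_to(np.asarray(n, dtype=float), k),
        },
        index=pd.Index(snvs, name="snv"),
    )
    return SummaryStatSet(study, table)


@pytest.fixture(scope="session")
def demo_result():
    """One full pipeline run shared by the end-to-end tests."""
    return run_demo(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort reused by covariate-level tests."""
    cfg = synthio.SimConfig(
        n_loci=2, snvs_per_locus=8, causal_per_locus=1,
        study_sizes={"a": (400, 600)}, seed=17,
    )
    panel, truth = synthio.simulate_panel(cfg)
    cohort = synthio.simulate_cohort(panel, truth, cfg)
    return panel, truth, cohort, cfg
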