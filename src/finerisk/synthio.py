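"""Synthetic multi-study case-control cohorts with LD-blocked genotypes.

The generator emulates the statistical structure a summary-statistics
fine-mapping / PRS analysis assumes: loci of correlated SNVs with a small
number of causal variants carrying log-odds effects, epidemiological
covariates including a BMI-by-menopause interaction, case-control
ascertainment from a base population at a target prevalence, and
training / validation / prospective-test style study partitions.

LD model
--------
Within a locus, haplotypes are drawn from a first-order autoregressive
latent Gaussian chain and thresholded at each SNV's allele-frequency
quantile; a diploid genotype is the sum of two independent haplotypes.
Thresholding attenuates correlation, so the latent AR coefficient for
each adjacent pair is calibrated (via the bivariate-normal orthant
probability, computed with Owen's T function) so that the *realized*
adjacent-genotype correlation equals ``ld_decay``.  Across loci SNVs are
independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, owens_t
from scipy.stats import norm

from .containers import MISSABLE_COVARIATES, DosageMatrix
from .errors import ConfigurationError, MatchingError, SimulationError

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: default per-unit log-OR covariate effects (seven factors + interaction)
DEFAULT_COVARIATE_EFFECTS = {
    "bmi": 0.02,
    "whr": 1.2,
    "menopause": 0.0,
    "age_menarche": -0.07,
    "age_first_birth": 0.03,
    "family_history": 0.8,
    "benign_breast_disease": 0.45,
    "bmi_x_menopause": 0.015,
}

#: covariate sampling distributions: (mean, sd) for continuous, p for binary
DEFAULT_COVARIATE_DISTS = {
    "bmi": (24.0, 3.0),
    "whr": (0.81, 0.05),
    "age_menarche": (14.8, 1.7),
    "age_first_birth": (26.0, 4.0),
    "family_history": 0.03,
    "benign_breast_disease": 0.2,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort generator.

    Defaults mirror the source analysis design at reduced scale: multiple
    case-control training studies, a validation study drawn from the same
    population, an age-matched prospective test study, and an external
    study standing in for an independent European-ancestry consortium.
    """

    n_loci: int = 8
    snvs_per_locus: int = 25
    causal_per_locus: int = 2
    ld_decay: float = 0.35
    maf_range: tuple = (0.1, 0.45)
    effect_size_dist: tuple = (0.25, 0.10)  # mean, sd of causal log-OR
    prevalence: float = 0.16
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    covariate_dists: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_DISTS))
    missing_rate: float = 0.04
    study_sizes: dict = field(
        default_factory=lambda: {
            "study_a": (1400, 1700),
            "study_b": (1000, 1300),
            "prospective_cohort": (500, 1300),
            "external_eur": (1500, 1500),
        }
    )
    seed: int = 2022
    base_margin: float = 1.35  # oversampling factor for the base population

    def validate(self) -> None:
        if self.n_loci < 1:
            raise ConfigurationError("n_loci must be >= 1")
        if self.snvs_per_locus < 1:
            raise ConfigurationError("snvs_per_locus must be >= 1")
        if not 0 <= self.causal_per_locus <= self.snvs_per_locus:
            raise ConfigurationError("causal_per_locus must be in [0, snvs_per_locus]")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ConfigurationError("ld_decay must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must be in (0, 1)")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1]")
        if not self.study_sizes:
            raise ConfigurationError("study_sizes must name at least one study")
        for study, (n_case, n_ctrl) in self.study_sizes.items():
            if n_case <= 0 or n_ctrl <= 0:
                raise ConfigurationError(f"study_sizes[{study!r}] must be positive")
        if self.base_margin <= 1.0:
            raise ConfigurationError("base_margin must exceed 1")

    def base_sizes(self) -> dict:
        """Base-population size per study, large enough to subsample from."""
        sizes = {}
        for study, (n_case, n_ctrl) in self.study_sizes.items():
            need = max(n_case / self.prevalence, n_ctrl / (1.0 - self.prevalence))
            sizes[study] = int(math.ceil(need * self.base_margin)) + 50
        return sizes


# ---------------------------------------------------------------------------
# latent-Gaussian LD calibration


def _bvn_cdf(h: float, k: float, r: float) -> float:
    """Standard bivariate normal P(X<=h, Y<=k) via Owen's T function."""
    if r == 0.0:
        return norm.cdf(h) * norm.cdf(k)
    if r >= 1.0:
        return norm.cdf(min(h, k))
    if r <= -1.0:
        return max(0.0, norm.cdf(h) + norm.cdf(k) - 1.0)
    # nudge exact zeros so the Owen's-T slope arguments are defined
    h = h if h != 0.0 else -1e-12
    k = k if k != 0.0 else -1e-12
    denom = math.sqrt(1.0 - r * r)
    a_h = (k - r * h) / (h * denom)
    a_k = (h - r * k) / (k * denom)
    beta = 0.0 if h * k > 0.0 else 0.5
    return float(0.5 * (norm.cdf(h) + norm.cdf(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta)


def _indicator_corr(t1: float, t2: float, r: float) -> float:
    """Correlation of the indicators 1{Z1<t1}, 1{Z2<t2} under latent corr r."""
    p1, p2 = norm.cdf(t1), norm.cdf(t2)
    s = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return (_bvn_cdf(t1, t2, r) - p1 * p2) / s


def _latent_corr_for_target(maf1: float, maf2: float, target: float) -> float:
    """Latent AR coefficient producing the target allele-indicator correlation.

    If the target exceeds the maximum correlation achievable for this MAF
    pair (Frechet bound), the latent coefficient is clamped near 1 and the
    realized correlation falls at that bound.
    """
    if target == 0.0:
        return 0.0
    t1, t2 = norm.ppf(maf1), norm.ppf(maf2)
    hi = 0.9999
    if _indicator_corr(t1, t2, hi) <= target:
        logger.debug(
            "LD target %.3f unreachable for MAF pair (%.3f, %.3f); clamping", target, maf1, maf2
        )
        return hi
    return brentq(lambda r: _indicator_corr(t1, t2, r) - target, 0.0, hi, xtol=1e-10)


def _simulate_locus_dosages(
    n: int, mafs: np.ndarray, ld_decay: float, rng: np.random.Generator
) -> np.ndarray:
    """Integer genotypes (n x m) for one locus under the calibrated AR chain."""
    m = len(mafs)
    thresholds = norm.ppf(mafs)
    if ld_decay > 0.0 and m > 1:
        lat = np.array(
            [_latent_corr_for_target(mafs[j], mafs[j + 1], ld_decay) for j in range(m - 1)]
        )
    else:
        lat = np.zeros(max(m - 1, 0))
    geno = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        noise = rng.standard_normal((n, max(m - 1, 1)))
        for j in range(1, m):
            r = lat[j - 1]
            z[:, j] = r * z[:, j - 1] + math.sqrt(1.0 - r * r) * noise[:, j - 1]
        geno += (z < thresholds).astype(np.int8)
    return geno


# ---------------------------------------------------------------------------
# panel simulation


def simulate_panel(config: SimConfig, rng: np.random.Generator | None = None):
    """Simulate the base-population dosage panel and its causal truth record.

    Returns
    -------
    panel : DosageMatrix
        Genotypes for the full base population (all studies' sampling pools).
    truth : pd.DataFrame
        One row per causal SNV: ``snv``, ``effect_allele``, ``log_or``,
        ``locus``, ``maf``; indexed by SNV id.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n_total = sum(config.base_sizes().values())
    lo, hi = config.maf_range
    eff_mean, eff_sd = config.effect_size_dist

    snv_rows = []
    blocks = []
    truth_rows = []
    for locus in range(config.n_loci):
        m = config.snvs_per_locus
        mafs = rng.uniform(lo, hi, size=m)
        geno = _simulate_locus_dosages(n_total, mafs, config.ld_decay, rng)
        blocks.append(geno)
        chrom = str(locus + 1)
        causal_idx = (
            rng.choice(m, size=config.causal_per_locus, replace=False)
            if config.causal_per_locus
            else np.array([], dtype=int)
        )
        for j in range(m):
            ea, oa = _BASES[rng.choice(4, size=2, replace=False)]
            snv_id = f"rs{locus + 1:02d}{j + 1:03d}"
            snv_rows.append(
                {
                    "snv": snv_id,
                    "chrom": chrom,
                    "pos": 10_000 + j * 5_000,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "locus": f"locus{locus + 1:02d}",
                    "maf": mafs[j],
                }
            )
            if j in causal_idx:
                truth_rows.append(
                    {
                        "snv": snv_id,
                        "effect_allele": ea,
                        "log_or": rng.normal(eff_mean, eff_sd),
                        "locus": f"locus{locus + 1:02d}",
                        "maf": mafs[j],
                    }
                )
    snvs = pd.DataFrame(snv_rows).set_index("snv")
    truth = pd.DataFrame(truth_rows, columns=["snv", "effect_allele", "log_or", "locus", "maf"])
    truth = truth.set_index("snv")
    samples = pd.Index([f"I{i + 1:06d}" for i in range(n_total)], name="individual")
    dosages = np.concatenate(blocks, axis=1).astype(np.float64)
    return DosageMatrix(samples, snvs, dosages), truth


# ---------------------------------------------------------------------------
# cohort simulation


def _draw_covariates(n: int, dists: dict, rng: np.random.Generator) -> pd.DataFrame:
    cov = pd.DataFrame(index=range(n))
    cov["age"] = np.clip(rng.normal(52.0, 9.0, n), 25.0, 79.0)
    # menopause tied to age through a random age-at-menopause
    cov["menopause"] = (cov["age"] > rng.normal(49.5, 4.0, n)).astype(int)
    for name in ("bmi", "whr", "age_menarche", "age_first_birth"):
        mean, sd = dists[name]
        draw = rng.normal(mean, sd, n)
        cov[name] = np.clip(draw, mean - 4 * sd, mean + 4 * sd)
    cov["bmi"] = np.maximum(cov["bmi"], 14.0)
    cov["whr"] = np.maximum(cov["whr"], 0.5)
    for name in ("family_history", "benign_breast_disease"):
        cov[name] = (rng.uniform(size=n) < dists[name]).astype(int)
    return cov


def _linear_predictor(panel, truth, cov, effects):
    """Centered genetic + covariate linear predictor on the log-odds scale."""
    lp = np.zeros(len(cov))
    if len(truth):
        idx = panel.snvs.index.get_indexer(truth.index)
        betas = truth["log_or"].to_numpy()
        dos = panel.dosages[:, idx]
        lp += (dos - dos.mean(axis=0)) @ betas
    for name, w in effects.items():
        if name == "bmi_x_menopause":
            # effect modification around the mean BMI, so the interaction
            # does not impose an enormous main shift between strata
            bmi_c = cov["bmi"] - cov["bmi"].mean()
            term = (bmi_c * cov["menopause"]).to_numpy()
        else:
            term = cov[name].to_numpy(dtype=float)
        lp += w * (term - term.mean())
    return lp


def simulate_cohort(
    panel: DosageMatrix,
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign covariates and case-control status, then sample study cohorts.

    Each study draws from its own disjoint block of the base population;
    the returned cohort table contains exactly the requested numbers of
    cases and controls per study.  Missingness (MCAR) is injected into the
    two age-at-event covariates at ``missing_rate``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    base_sizes = config.base_sizes()
    if sum(base_sizes.values()) > panel.n_samples:
        raise SimulationError(
            f"panel has {panel.n_samples} individuals; config requires "
            f"{sum(base_sizes.values())}"
        )
    missing_truth = [s for s in truth.index if s not in panel.snvs.index]
    if missing_truth:
        raise SimulationError(f"truth SNVs absent from panel: {missing_truth[:5]}")

    cov = _draw_covariates(panel.n_samples, config.covariate_dists, rng)
    lp = _linear_predictor(panel, truth, cov, config.covariate_effects)
    # intercept chosen so the base population hits the target prevalence
    alpha = brentq(lambda a: expit(a + lp).mean() - config.prevalence, -25.0, 25.0)
    status = (rng.uniform(size=len(lp)) < expit(alpha + lp)).astype(int)

    frames = []
    offset = 0
    for study, n_base in base_sizes.items():
        block = np.arange(offset, offset + n_base)
        offset += n_base
        n_case, n_ctrl = config.study_sizes[study]
        cases = block[status[block] == 1]
        ctrls = block[status[block] == 0]
        if len(cases) < n_case or len(ctrls) < n_ctrl:
            raise SimulationError(
                f"study {study!r}: needed {n_case} cases/{n_ctrl} controls, "
                f"base population yielded {len(cases)}/{len(ctrls)}"
            )
        take = np.concatenate(
            [rng.choice(cases, n_case, replace=False), rng.choice(ctrls, n_ctrl, replace=False)]
        )
        df = cov.iloc[take].copy()
        df.index = panel.samples[take]
        df.insert(0, "status", status[take])
        df.insert(1, "study", study)
        frames.append(df)
    cohort = pd.concat(frames)
    cohort.index.name = "individual"

    if config.missing_rate > 0:
        for col in MISSABLE_COVARIATES:
            mask = rng.uniform(size=len(cohort)) < config.missing_rate
            cohort.loc[mask, col] = np.nan
    return cohort


# ---------------------------------------------------------------------------
# rate tables


def make_rate_table(age_span=(20, 80), incidence_level=1e-3, mortality_level=5e-3) -> pd.DataFrame:
    """Build an annual-bin age/incidence/mortality table.

    ``incidence_level`` / ``mortality_level`` may each be a scalar (constant
    rate), an array of one value per year of age (inclusive span), or a
    callable ``rate(age)``.
    """
    lo, hi = age_span
    if hi < lo:
        raise ConfigurationError("age_span must be increasing")
    ages = np.arange(lo, hi + 1)

    def _expand(level, name):
        if callable(level):
            vals = np.asarray([float(level(a)) for a in ages])
        else:
            arr = np.asarray(level, dtype=float)
            vals = np.full(len(ages), float(arr)) if arr.ndim == 0 else arr
            if vals.shape != ages.shape:
                raise ConfigurationError(f"{name} array must have one value per year of age")
        if (vals < 0).any():
            raise ConfigurationError(f"{name} rates must be >= 0")
        return vals

    return pd.DataFrame(
        {
            "age": ages,
            "incidence": _expand(incidence_level, "incidence"),
            "mortality": _expand(mortality_level, "mortality"),
        }
    )


def expand_rate_table(rates: pd.DataFrame) -> pd.DataFrame:
    """Expand a 5-year-bin rate table to annual bins by repetition."""
    ages = rates["age"].to_numpy()
    steps = np.diff(ages)
    if len(steps) and (steps == 1).all():
        return rates.reset_index(drop=True)
    rows = []
    for i, row in rates.iterrows():
        width = int(steps[i]) if i < len(steps) else int(steps[-1]) if len(steps) else 1
        for k in range(width):
            rows.append({"age": int(row["age"]) + k, "incidence": row["incidence"], "mortality": row["mortality"]})
    return pd.DataFrame(rows)


def shanghai_like_rates(age_span=(20, 85)) -> pd.DataFrame:
    """Synthetic stand-in for an urban-Chinese female rate table.

    Breast-cancer incidence ramps to ~1.4 per 1000 person-years around
    age 60; all-cause mortality follows a Gompertz-like curve.  These are
    plausible magnitudes, not registry values.
    """
    inc = lambda a: 1.5e-3 / (1.0 + math.exp(-(a - 50.0) / 6.0))
    mort = lambda a: math.exp(-9.8 + 0.082 * a)
    return make_rate_table(age_span, inc, mort)


# ---------------------------------------------------------------------------
# partitioning


@dataclass
class PartitionSpec:
    """Requested composition of one partition.

    ``studies`` restricts the sampling pool; ``age_caliper`` switches to
    individually age-matched control sampling (controls per case must then
    be integral).
    """

    n_cases: int
    n_controls: int
    studies: tuple | None = None
    age_caliper: float | None = None


def _match_controls(cases: pd.DataFrame, controls: pd.DataFrame, per_case: int, caliper: float, rng):
    """Greedy nearest-age matching without replacement.

    Returns (matched control ids, unmatched case ids, (case, control) pairs).
    """
    ctrl_ages = controls["age"].to_numpy()
    order = np.argsort(ctrl_ages)
    avail_ages = ctrl_ages[order].tolist()
    avail_ids = controls.index.to_numpy()[order].tolist()
    matched = []
    unmatched = []
    pairs = []
    for cid in rng.permutation(cases.index.to_numpy()):
        age = cases.at[cid, "age"]
        picks = []
        for _ in range(per_case):
            if not avail_ages:
                break
            j = int(np.searchsorted(avail_ages, age))
            best, best_d = None, None
            for cand in (j - 1, j):
                if 0 <= cand < len(avail_ages):
                    d = abs(avail_ages[cand] - age)
                    if best_d is None or d < best_d:
                        best, best_d = cand, d
            if best is None or best_d >= caliper:
                break
            picks.append(avail_ids.pop(best))
            avail_ages.pop(best)
        if len(picks) < per_case:
            # return partial picks to the pool and record the failure
            for pid in picks:
                k = int(np.searchsorted(avail_ages, controls.at[pid, "age"]))
                avail_ages.insert(k, controls.at[pid, "age"])
                avail_ids.insert(k, pid)
            unmatched.append(cid)
        else:
            matched.extend(picks)
            pairs.extend((cid, pid) for pid in picks)
    return matched, unmatched, pairs


def split_cohort(
    cohort: pd.DataFrame,
    scheme: dict,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Assign disjoint partitions (a ``partition`` column) per ``scheme``.

    ``scheme`` maps partition label -> :class:`PartitionSpec` (or a
    ``(n_cases, n_controls)`` tuple).  Partitions are drawn sequentially
    without replacement; age-calipered partitions use greedy nearest-age
    matched control sampling (matched difference strictly below the
    caliper).
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    out = cohort.copy()
    out["partition"] = pd.NA
    out.attrs["matching"] = {}
    available = pd.Series(True, index=out.index)
    for name, spec in scheme.items():
        if not isinstance(spec, PartitionSpec):
            spec = PartitionSpec(*spec)
        pool = out[available]
        if spec.studies is not None:
            pool = pool[pool["study"].isin(spec.studies)]
        cases = pool[pool["status"] == 1]
        ctrls = pool[pool["status"] == 0]
        if len(cases) < spec.n_cases or len(ctrls) < spec.n_controls:
            raise SimulationError(
                f"partition {name!r}: requested {spec.n_cases}+{spec.n_controls}, "
                f"available {len(cases)} cases / {len(ctrls)} controls"
            )
        case_ids = rng.choice(cases.index.to_numpy(), spec.n_cases, replace=False)
        if spec.age_caliper is not None:
            if spec.n_controls % spec.n_cases:
                raise ConfigurationError(
                    f"partition {name!r}: matched design needs integral controls per case"
                )
            per_case = spec.n_controls // spec.n_cases
            matched, unmatched, pairs = _match_controls(
                cases.loc[case_ids], ctrls, per_case, spec.age_caliper, rng
            )
            out.attrs["matching"][name] = pairs
            if unmatched:
                raise MatchingError(
                    f"partition {name!r}: {len(unmatched)} cases could not be age-matched "
                    f"within {spec.age_caliper} years: {unmatched[:5]}",
                    unmatched=unmatched,
                )
            ctrl_ids = np.asarray(matched)
        else:
            ctrl_ids = rng.choice(ctrls.index.to_numpy(), spec.n_controls, replace=False)
        chosen = np.concatenate([case_ids, ctrl_ids])
        out.loc[chosen, "partition"] = name
        available.loc[chosen] = False
    return out


def partition(cohort: pd.DataFrame, name: str) -> pd.DataFrame:
    """Rows of ``cohort`` assigned to partition ``name``."""
    return cohort[cohort["partition"] == name]
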