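"""Synthetic multi-cohort platelet-transcriptome generator.

Emulates the data structure of a TEP (tumor-educated platelet) diagnostic
study: several hospital cohorts of ovarian-cancer (OC) patients, benign
adnexal mass (BAM) patients and healthy women, each contributing a gene x
sample read-count matrix plus clinical metadata (age, histology, FIGO
stage, grade, serum CA125). Counts follow a negative-binomial model with a
dispersion trend, log-normal library sizes, sparse multiplicative batch
effects, age-drifting nuisance genes and a sparse set of class-informative
signal genes. Ground truth (signal-gene identities, per-sample Bayes
posterior of the OC class) is recorded so downstream feature selection and
classification can be scored against a known generative optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DistSpec",
    "CohortSpec",
    "SimConfig",
    "SyntheticStudy",
    "default_config",
    "simulate_cohort",
    "simulate_ca125",
    "simulate_study",
]

CLASSES = ("OC", "BAM", "healthy")

# Histology / stage / grade sampling tables for OC and BAM samples. The
# proportions mirror a realistic case mix for a gynecologic-oncology referral
# hospital: mostly serous carcinomas, a sizeable borderline fraction, a small
# non-epithelial minority; BAMs split between endometriosis and other benign
# lesions.
OC_HISTOLOGY = {
    "serous": 178 / 289,
    "mucinous": 11 / 289,
    "endometrioid": 23 / 289,
    "clear_cell": 11 / 289,
    "borderline": 52 / 289,
    "non_epithelial": 14 / 289,
}
BAM_HISTOLOGY = {"endometriosis": 57 / 182, "other_benign": 125 / 182}
OC_EARLY_FRAC = 49 / 289  # FIGO I-IIA among OC
EARLY_STAGES = {"I": 0.8, "IIA": 0.2}
LATE_STAGES = {"IIB": 0.1, "III": 0.6, "IV": 0.3}
OC_GRADE = {"well": 36 / 289, "moderate": 48 / 289, "poor": 205 / 289}


@dataclass(frozen=True)
class DistSpec:
    """(mean, sd) of a normal distribution on the indicated scale."""

    mean: float
    sd: float

    def validate(self, name: str) -> None:
        if not math.isfinite(self.mean) or not math.isfinite(self.sd):
            raise ValueError(f"{name}: non-finite parameters")
        if self.sd < 0:
            raise ValueError(f"{name}: sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n_oc: int
    n_bam: int
    n_healthy: int
    n_batches: int = 2
    age_shift: float = 0.0  # additive shift (years) on every class mean
    ca125_missing_frac: float = 0.0

    @property
    def n_total(self) -> int:
        return self.n_oc + self.n_bam + self.n_healthy

    def validate(self) -> None:
        for f in ("n_oc", "n_bam", "n_healthy"):
            if getattr(self, f) < 0:
                raise ValueError(f"cohort {self.name}: {f} < 0")
        if self.n_total <= 0:
            raise ValueError(f"cohort {self.name}: empty cohort")
        if self.n_batches < 1:
            raise ValueError(f"cohort {self.name}: n_batches must be >= 1")
        if not 0.0 <= self.ca125_missing_frac <= 1.0:
            raise ValueError(f"cohort {self.name}: ca125_missing_frac outside [0,1]")


def _default_cohorts() -> tuple[CohortSpec, ...]:
    # Training + three validation cohorts; the third validation cohort gets an
    # older age distribution, lower OC prevalence (29/129) and mostly missing
    # CA125 (94/129), mimicking a European multi-center arm of an otherwise
    # Chinese hospital study.
    return (
        CohortSpec("training", 289, 182, 49),
        CohortSpec("vc1", 40, 25, 8),
        CohortSpec("vc2", 87, 68, 7),
        CohortSpec("vc3", 29, 14, 86, age_shift=7.0, ca125_missing_frac=94 / 129),
    )


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 5000
    cohorts: tuple[CohortSpec, ...] = field(default_factory=_default_cohorts)
    n_signal_genes: int = 60
    signal_log2fc: DistSpec = DistSpec(1.5, 0.3)
    baseline_log_mean: DistSpec = DistSpec(3.0, 1.5)  # natural log of abundance weight
    # alpha_i = a0 / mu_i + a1; the asymptote a1 = 0.4 reflects the large
    # inter-patient biological variability of clinical bulk RNA-seq, keeping
    # single genes only moderately discriminative
    nb_dispersion: tuple[float, float] = (1.0, 0.4)
    libsize_log_params: DistSpec = DistSpec(math.log(8e6), 0.35)
    batch_effect_sd: float = 0.3  # log-scale multiplicative, on 30% of genes
    batch_gene_frac: float = 0.3
    age_params: dict = field(
        default_factory=lambda: {"OC": (50.0, 10.0), "BAM": (46.0, 10.0), "healthy": (46.0, 10.0)}
    )
    n_age_genes: int = 100
    age_slope: DistSpec = DistSpec(0.01, 0.003)  # natural-log units per year
    ca125_log_params: dict = field(
        default_factory=lambda: {"OC": (2.0, 0.8), "BAM": (1.25, 0.45), "healthy": (1.1, 0.35)}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.n_signal_genes <= self.n_genes:
            raise ValueError("n_signal_genes outside [0, n_genes]")
        if self.n_signal_genes + self.n_age_genes > self.n_genes:
            raise ValueError("signal and age gene sets must fit disjointly in the gene universe")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")
        if not 0.0 <= self.batch_gene_frac <= 1.0:
            raise ValueError("batch_gene_frac outside [0,1]")
        a0, a1 = self.nb_dispersion
        if a0 < 0 or a1 <= 0:
            raise ValueError("nb_dispersion requires a0 >= 0 and a1 > 0")
        self.signal_log2fc.validate("signal_log2fc")
        self.baseline_log_mean.validate("baseline_log_mean")
        self.libsize_log_params.validate("libsize_log_params")
        self.age_slope.validate("age_slope")
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cohort names")
        for c in self.cohorts:
            c.validate()
        for table in (self.age_params, self.ca125_log_params):
            missing = set(CLASSES) - set(table)
            if missing:
                raise ValueError(f"missing per-class parameters for {sorted(missing)}")

    def cohort(self, name: str) -> CohortSpec:
        for c in self.cohorts:
            if c.name == name:
                return c
        raise KeyError(f"unknown cohort {name!r}; configured: {[c.name for c in self.cohorts]}")


def default_config(**overrides) -> SimConfig:
    """Study-sized default configuration (four cohorts, 5000 genes)."""
    return replace(SimConfig(), **overrides)


@dataclass
class SyntheticStudy:
    counts: dict  # cohort name -> DataFrame (genes x samples)
    meta: dict  # cohort name -> DataFrame (one row per sample)
    truth: dict  # cohort name -> dict with signal genes, bayes probs, batches
    config: SimConfig


# ---------------------------------------------------------------------------
# gene-level parameters (shared across cohorts so the gene universe is common)
# ---------------------------------------------------------------------------


def _gene_params(config: SimConfig) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    logw = rng.normal(config.baseline_log_mean.mean, config.baseline_log_mean.sd, n)
    frac = np.exp(logw)
    frac /= frac.sum()
    a0, a1 = config.nb_dispersion
    ref_mean = math.exp(config.libsize_log_params.mean) * frac
    alpha = a0 / ref_mean + a1

    perm = rng.permutation(n)
    signal_idx = np.sort(perm[: config.n_signal_genes])
    age_idx = np.sort(perm[config.n_signal_genes : config.n_signal_genes + config.n_age_genes])

    # the configured distribution IS the OC-vs-control fold-change law: signed
    # draws, so a positive mean yields mostly up-regulated signal genes
    log2fc = np.zeros(n)
    if config.n_signal_genes:
        log2fc[signal_idx] = rng.normal(
            config.signal_log2fc.mean, config.signal_log2fc.sd, config.n_signal_genes
        )

    age_slope = np.zeros(n)
    if config.n_age_genes:
        slopes = rng.normal(config.age_slope.mean, config.age_slope.sd, config.n_age_genes)
        age_slope[age_idx] = slopes * rng.choice([-1.0, 1.0], config.n_age_genes)

    return {
        "gene_ids": gene_ids,
        "frac": frac,
        "alpha": alpha,
        "signal_idx": signal_idx,
        "age_idx": age_idx,
        "log2fc": log2fc,
        "age_slope": age_slope,
    }


def _sample_categorical(rng, table: dict, size: int) -> np.ndarray:
    keys = list(table)
    p = np.array([table[k] for k in keys], dtype=float)
    p /= p.sum()
    return rng.choice(keys, size=size, p=p)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimConfig, cohort_name: str, gene_params: dict | None = None):
    """Draw one cohort's count matrix, metadata and ground truth.

    Returns ``(counts, meta, truth)`` where ``counts`` is a genes x samples
    integer DataFrame, ``meta`` one row per sample (CA125 left unset; see
    :func:`simulate_ca125`) and ``truth`` records signal genes, batch labels
    and each sample's generative posterior probability of the OC class.
    """
    config.validate()
    spec = config.cohort(cohort_name)
    idx = [c.name for c in config.cohorts].index(cohort_name)
    gp = gene_params if gene_params is not None else _gene_params(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1, idx)))

    n = spec.n_total
    classes = np.array(["OC"] * spec.n_oc + ["BAM"] * spec.n_bam + ["healthy"] * spec.n_healthy)
    sample_ids = np.array([f"{cohort_name}_s{i:04d}" for i in range(n)])

    ages = np.empty(n)
    for cls in CLASSES:
        mask = classes == cls
        mean, sd = config.age_params[cls]
        ages[mask] = rng.normal(mean + spec.age_shift, sd, mask.sum())
    ages = np.clip(np.round(ages), 18, 90)

    batch_of = rng.integers(0, spec.n_batches, n)
    batch_labels = np.array([f"{cohort_name}_b{b}" for b in batch_of])

    # each batch perturbs a random 30% gene subset by gene-wise log-normal shifts
    batch_shift = np.zeros((spec.n_batches, config.n_genes))
    if config.batch_effect_sd > 0 and spec.n_batches > 1:
        n_hit = int(round(config.batch_gene_frac * config.n_genes))
        for b in range(spec.n_batches):
            hit = rng.choice(config.n_genes, n_hit, replace=False)
            batch_shift[b, hit] = rng.normal(0.0, config.batch_effect_sd, n_hit)

    libsize = np.exp(
        rng.normal(config.libsize_log_params.mean, config.libsize_log_params.sd, n)
    )

    # reference age for centering the nuisance drift: cohort-level mean of the
    # configured class means, so age effects do not inflate library sums
    age_ref = np.mean([config.age_params[c][0] for c in CLASSES]) + spec.age_shift

    log_rel = np.log(gp["frac"])[:, None] + batch_shift[batch_of].T
    log_rel = log_rel + gp["age_slope"][:, None] * (ages - age_ref)[None, :]
    is_oc = (classes == "OC").astype(float)
    log_rel_oc = log_rel + math.log(2.0) * gp["log2fc"][:, None]
    log_rel_own = np.where(is_oc[None, :] > 0, log_rel_oc, log_rel)

    mu = libsize[None, :] * np.exp(log_rel_own)
    r = 1.0 / gp["alpha"][:, None]
    p = r / (r + mu)
    values = rng.negative_binomial(np.broadcast_to(r, mu.shape), p)

    counts = pd.DataFrame(values, index=gp["gene_ids"], columns=sample_ids)

    bayes = _bayes_posterior(values, libsize, log_rel, log_rel_oc, gp, spec)

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": cohort_name,
            "class": classes,
            "histology": _histology(rng, classes),
            "figo_stage": _figo(rng, classes),
            "grade": _grade(rng, classes),
            "age": ages,
            "ca125": np.nan,
            "batch": batch_labels,
        }
    )

    truth = {
        "signal_genes": list(gp["gene_ids"][gp["signal_idx"]]),
        "signal_log2fc": {
            g: float(f) for g, f in zip(gp["gene_ids"][gp["signal_idx"]], gp["log2fc"][gp["signal_idx"]])
        },
        "age_genes": list(gp["gene_ids"][gp["age_idx"]]),
        "batch": dict(zip(sample_ids, batch_labels)),
        "bayes_prob_oc": dict(zip(sample_ids, np.round(bayes, 10))),
        "library_size": dict(zip(sample_ids, libsize)),
    }
    return counts, meta, truth


def _bayes_posterior(values, libsize, log_rel_ctrl, log_rel_oc, gp, spec) -> np.ndarray:
    """P(OC | signal-gene counts) under the generative model, cohort prevalence prior."""
    sig = gp["signal_idx"]
    if len(sig) == 0 or spec.n_oc in (0, spec.n_total):
        return np.full(values.shape[1], spec.n_oc / spec.n_total, dtype=float)
    k = values[sig]
    r = (1.0 / gp["alpha"][sig])[:, None]
    mu_c = libsize[None, :] * np.exp(log_rel_ctrl[sig])
    mu_o = libsize[None, :] * np.exp(log_rel_oc[sig])
    ll_c = stats.nbinom.logpmf(k, r, r / (r + mu_c)).sum(axis=0)
    ll_o = stats.nbinom.logpmf(k, r, r / (r + mu_o)).sum(axis=0)
    prior = spec.n_oc / spec.n_total
    logits = (ll_o + math.log(prior)) - (ll_c + math.log1p(-prior))
    return 1.0 / (1.0 + np.exp(-np.clip(logits, -700, 700)))


def _histology(rng, classes):
    out = np.full(len(classes), "", dtype=object)
    oc = classes == "OC"
    bam = classes == "BAM"
    out[oc] = _sample_categorical(rng, OC_HISTOLOGY, oc.sum())
    out[bam] = _sample_categorical(rng, BAM_HISTOLOGY, bam.sum())
    return out


def _figo(rng, classes):
    out = np.full(len(classes), "", dtype=object)
    oc = np.flatnonzero(classes == "OC")
    early = rng.random(len(oc)) < OC_EARLY_FRAC
    out[oc[early]] = _sample_categorical(rng, EARLY_STAGES, int(early.sum()))
    out[oc[~early]] = _sample_categorical(rng, LATE_STAGES, int((~early).sum()))
    return out


def _grade(rng, classes):
    out = np.full(len(classes), "", dtype=object)
    oc = classes == "OC"
    out[oc] = _sample_categorical(rng, OC_GRADE, oc.sum())
    return out


# ---------------------------------------------------------------------------
# CA125
# ---------------------------------------------------------------------------


def simulate_ca125(meta: pd.DataFrame, config: SimConfig) -> pd.Series:
    """Serum CA125 (mU/L), log10-normal per class, missing per cohort fraction.

    Simulated independently of the transcriptome given the class label, so
    any gain of a combined TEP+CA125 model over either marker alone is
    attributable to genuinely independent information.
    """
    config.validate()
    if "class" not in meta.columns:
        raise ValueError("metadata lacks a 'class' column")
    out = pd.Series(np.nan, index=meta.index, dtype=float)
    names = [c.name for c in config.cohorts]
    for cohort_name, grp in meta.groupby("cohort", sort=False):
        spec = config.cohort(str(cohort_name))
        idx = names.index(spec.name)
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2, idx)))
        vals = np.empty(len(grp))
        cls = grp["class"].to_numpy()
        for c in CLASSES:
            mask = cls == c
            m, s = config.ca125_log_params[c]
            vals[mask] = 10.0 ** rng.normal(m, s, mask.sum())
        missing = rng.random(len(grp)) < spec.ca125_missing_frac
        vals[missing] = np.nan
        out.loc[grp.index] = vals
    return out


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------


def simulate_study(config: SimConfig | None = None) -> SyntheticStudy:
    """Simulate every configured cohort over a shared gene universe."""
    config = config if config is not None else default_config()
    config.validate()
    if len(config.cohorts) < 2:
        raise ValueError("a study needs at least 2 cohorts (training + validation)")
    gp = _gene_params(config)
    counts, meta, truth = {}, {}, {}
    for spec in config.cohorts:
        c, m, t = simulate_cohort(config, spec.name, gene_params=gp)
        m = m.copy()
        m["ca125"] = simulate_ca125(m, config).to_numpy()
        counts[spec.name], meta[spec.name], truth[spec.name] = c, m, t
    return SyntheticStudy(counts=counts, meta=meta, truth=truth, config=config)
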