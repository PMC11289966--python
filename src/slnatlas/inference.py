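"""Drainage-probability and tumour-prevalence estimation.

Three interval families, mirroring common practice for lymphoscintigraphy
node-field statistics:

* **bayes** — exact conjugate posteriors: Beta(1, 1) prior with binomial
  likelihood for drainage probabilities; Dirichlet(1, ..., 1) prior with
  multinomial likelihood for tumour prevalence.  Posterior means with
  equal-tailed 95% credible intervals, computed in closed form (no MCMC).
* **bootstrap** — non-parametric bootstrap, resampling *patients* (clusters
  of 1-2 tumours) with replacement; percentile intervals.
* **regression** — the fitted values of a saturated logistic model: Wald
  intervals on the log-odds scale, back-transformed.  For multinomial
  prevalence the regression-style column is the Sison-Glaz simultaneous
  interval.

Drainage probability: P(SLN in node field f | tumour in breast region r).
Tumour prevalence: P(tumour in region r), optionally conditioned on drainage
to a given node field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import (
    N_REGIONS,
    NODE_FIELD_INDEX,
    NODE_FIELDS,
    Cohort,
    ContingencyTable,
    build_contingency,
)
from .sisonglaz import sison_glaz_intervals

__all__ = [
    "IntervalEstimate",
    "BootstrapConfig",
    "PriorSpec",
    "drainage_bayes",
    "drainage_bootstrap",
    "drainage_regression",
    "prevalence_bayes",
    "prevalence_bootstrap",
    "prevalence_sison_glaz",
    "drainage_table",
    "prevalence_table",
    "prevalence_by_field",
]


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with interval bounds, all on the probability scale."""

    mean: float
    lower: float
    upper: float
    method: str  # bayes | bootstrap | regression | sison-glaz
    n_success: int
    n_total: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError(f"lower {self.lower} > upper {self.upper}")
        if self.n_success > self.n_total:
            raise ValueError("n_success cannot exceed n_total")


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: B replicates, seed, resampling unit, CI level."""

    B: int = 10_000
    seed: int = 0
    resample_unit: str = "patient"  # or "tumour"
    ci: float = 0.95

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.ci < 1.0:
            raise ValueError("ci must be in (0, 1)")
        if self.resample_unit not in ("patient", "tumour"):
            raise ValueError("resample_unit must be 'patient' or 'tumour'")


@dataclass(frozen=True)
class PriorSpec:
    """Conjugate prior settings; defaults are uniform (all ones)."""

    drainage_a: float = 1.0
    drainage_b: float = 1.0
    prevalence_alpha: tuple[float, ...] = field(default_factory=lambda: (1.0,) * N_REGIONS)
    credible_level: float = 0.95

    def __post_init__(self) -> None:
        if self.drainage_a <= 0 or self.drainage_b <= 0:
            raise ValueError("Beta prior parameters must be positive")
        if any(a <= 0 for a in self.prevalence_alpha):
            raise ValueError("Dirichlet concentrations must be positive")


def drainage_bayes(
    n_drain: int, n_total: int, prior: PriorSpec | None = None
) -> IntervalEstimate:
    """Conjugate Beta posterior for a drainage probability.

    With the uniform prior the posterior is Beta(n+1, N-n+1); the point
    estimate is the posterior mean and the interval the equal-tailed
    credible interval at ``prior.credible_level``.
    """
    prior = prior or PriorSpec()
    if not 0 <= n_drain <= n_total or n_total < 1:
        raise ValueError(f"need 0 <= n_drain <= n_total, n_total >= 1; got ({n_drain}, {n_total})")
    a = prior.drainage_a + n_drain
    b = prior.drainage_b + (n_total - n_drain)
    tail = (1.0 - prior.credible_level) / 2.0
    lower, upper = stats.beta.ppf([tail, 1.0 - tail], a, b)
    return IntervalEstimate(
        mean=a / (a + b),
        lower=float(lower),
        upper=float(upper),
        method="bayes",
        n_success=n_drain,
        n_total=n_total,
    )


def drainage_regression(
    n_drain: int, n_total: int, level: float = 0.95
) -> IntervalEstimate:
    """Logit-scale Wald interval around the fitted proportion n/N.

    Equals the fitted-value interval of a saturated logistic regression (an
    intercept-only fit for the whole breast; region as a categorical
    predictor gives the same formula cell-wise).  Degenerate cells (0 or all
    successes) get a one-sided interval with the exact Clopper-Pearson bound
    on the undefined side and are flagged.
    """
    if n_total < 1 or not 0 <= n_drain <= n_total:
        raise ValueError(f"invalid counts ({n_drain}, {n_total})")
    p_hat = n_drain / n_total
    tail = (1.0 - level) / 2.0
    if n_drain == 0:
        return IntervalEstimate(
            mean=0.0,
            lower=0.0,
            upper=float(stats.beta.ppf(1.0 - tail, 1, n_total)),
            method="regression",
            n_success=n_drain,
            n_total=n_total,
            degenerate=True,
        )
    if n_drain == n_total:
        return IntervalEstimate(
            mean=1.0,
            lower=float(stats.beta.ppf(tail, n_total, 1)),
            upper=1.0,
            method="regression",
            n_success=n_drain,
            n_total=n_total,
            degenerate=True,
        )
    z = stats.norm.ppf(1.0 - tail)
    logit = np.log(n_drain / (n_total - n_drain))
    se = np.sqrt(1.0 / n_drain + 1.0 / (n_total - n_drain))
    lo, hi = 1.0 / (1.0 + np.exp(-(logit + np.array([-z, z]) * se)))
    return IntervalEstimate(
        mean=p_hat,
        lower=float(lo),
        upper=float(hi),
        method="regression",
        n_success=n_drain,
        n_total=n_total,
    )


def prevalence_bayes(
    region_counts, prior: PriorSpec | None = None
) -> list[IntervalEstimate]:
    """Dirichlet-multinomial posterior for the 13 region proportions.

    With the uniform Dirichlet prior the posterior is Dirichlet(counts + 1);
    each region's marginal is Beta(n_r + 1, N - n_r + 12), summarized by its
    mean and equal-tailed interval.
    """
    prior = prior or PriorSpec()
    counts = np.asarray(region_counts, dtype=int)
    if counts.shape != (N_REGIONS,):
        raise ValueError(f"expected {N_REGIONS} region counts, got shape {counts.shape}")
    if (counts < 0).any() or counts.sum() < 1:
        raise ValueError("counts must be non-negative with positive total")
    alpha = counts + np.asarray(prior.prevalence_alpha)
    total = alpha.sum()
    tail = (1.0 - prior.credible_level) / 2.0
    lowers = stats.beta.ppf(tail, alpha, total - alpha)
    uppers = stats.beta.ppf(1.0 - tail, alpha, total - alpha)
    n = int(counts.sum())
    return [
        IntervalEstimate(
            mean=float(alpha[r] / total),
            lower=float(lowers[r]),
            upper=float(uppers[r]),
            method="bayes",
            n_success=int(counts[r]),
            n_total=n,
        )
        for r in range(N_REGIONS)
    ]


def prevalence_sison_glaz(region_counts, level: float = 0.95) -> list[IntervalEstimate]:
    """Simultaneous multinomial intervals for the 13 region proportions."""
    counts = np.asarray(region_counts, dtype=int)
    if counts.shape != (N_REGIONS,):
        raise ValueError(f"expected {N_REGIONS} region counts, got shape {counts.shape}")
    lower, upper, _, _ = sison_glaz_intervals(counts, level=level)
    n = int(counts.sum())
    return [
        IntervalEstimate(
            mean=float(counts[r] / n),
            lower=float(lower[r]),
            upper=float(upper[r]),
            method="sison-glaz",
            n_success=int(counts[r]),
            n_total=n,
        )
        for r in range(N_REGIONS)
    ]


# ---------------------------------------------------------------------------
# bootstrap machinery


def _cohort_arrays(cohort: Cohort):
    """Vectorized view of a preprocessed cohort: patient index per record,
    region per record, and the record x node-field membership matrix."""
    patients = cohort.patients
    pat_index = {p: i for i, p in enumerate(patients)}
    pat_of = np.array([pat_index[r.patient_id] for r in cohort], dtype=int)
    regions = np.array([r.clockface for r in cohort], dtype=int)
    member = np.zeros((len(cohort), len(NODE_FIELDS)), dtype=bool)
    for i, rec in enumerate(cohort):
        for f in rec.drained_fields:
            member[i, NODE_FIELD_INDEX[f]] = True
    return pat_of, regions, member, len(patients)


def _replicate_weights(pat_of, n_units: int, cfg: BootstrapConfig) -> np.ndarray:
    """(B, n_records) resampling multiplicities.

    Patient-level resampling draws whole patients with replacement (each draw
    carries all of the patient's tumours); tumour-level draws records
    directly.
    """
    rng = np.random.default_rng(cfg.seed)
    n_rec = len(pat_of)
    if cfg.resample_unit == "patient":
        unit_counts = rng.multinomial(n_units, np.full(n_units, 1.0 / n_units), size=cfg.B)
        return unit_counts[:, pat_of]
    return rng.multinomial(n_rec, np.full(n_rec, 1.0 / n_rec), size=cfg.B)


def _percentile_summary(samples: np.ndarray, ci: float):
    tail = (1.0 - ci) / 2.0
    lo, hi = np.quantile(samples, [tail, 1.0 - tail], axis=0)
    return samples.mean(axis=0), lo, hi


def drainage_bootstrap_all(
    cohort: Cohort, region: int | None = None, cfg: BootstrapConfig | None = None
) -> list[IntervalEstimate]:
    """Patient-level bootstrap of drainage proportions for all 12 node fields.

    Replicate weights are shared across fields so a whole drainage table
    costs one resampling pass.  ``region`` restricts the cohort to one
    clockface region before resampling.
    """
    cfg = cfg or BootstrapConfig()
    pat_of, regions, member, _ = _cohort_arrays(cohort)
    if region is not None:
        keep = regions == region
        if not keep.any():
            raise ValueError(f"no tumours in region {region}")
        pat_of, member = pat_of[keep], member[keep]
        # re-index the surviving patients compactly
        _, pat_of = np.unique(pat_of, return_inverse=True)
    n_units = pat_of.max() + 1 if cfg.resample_unit == "patient" else len(pat_of)
    w = _replicate_weights(pat_of, n_units, cfg)
    denom = w.sum(axis=1).astype(float)
    props = (w @ member) / denom[:, None]
    mean, lo, hi = _percentile_summary(props, cfg.ci)
    counts = member.sum(axis=0)
    n = member.shape[0]
    return [
        IntervalEstimate(
            mean=float(mean[f]),
            lower=float(lo[f]),
            upper=float(hi[f]),
            method="bootstrap",
            n_success=int(counts[f]),
            n_total=n,
        )
        for f in range(len(NODE_FIELDS))
    ]


def drainage_bootstrap(
    cohort: Cohort,
    node_field: str,
    region: int | None = None,
    cfg: BootstrapConfig | None = None,
) -> IntervalEstimate:
    """Bootstrap interval for drainage to one node field (see
    :func:`drainage_bootstrap_all`)."""
    return drainage_bootstrap_all(cohort, region=region, cfg=cfg)[NODE_FIELD_INDEX[node_field]]


def prevalence_bootstrap(
    cohort: Cohort,
    node_field: str | None = None,
    cfg: BootstrapConfig | None = None,
) -> list[IntervalEstimate]:
    """Patient-level bootstrap of the 13 region proportions.

    ``node_field`` restricts to tumours draining to that field (per-field
    tumour prevalence) before resampling.
    """
    cfg = cfg or BootstrapConfig()
    pat_of, regions, member, _ = _cohort_arrays(cohort)
    if node_field is not None:
        keep = member[:, NODE_FIELD_INDEX[node_field]]
        if not keep.any():
            raise ValueError(f"no tumours drain to {node_field}")
        pat_of, regions = pat_of[keep], regions[keep]
        _, pat_of = np.unique(pat_of, return_inverse=True)
    onehot = np.zeros((len(regions), N_REGIONS), dtype=bool)
    onehot[np.arange(len(regions)), regions] = True
    n_units = pat_of.max() + 1 if cfg.resample_unit == "patient" else len(pat_of)
    w = _replicate_weights(pat_of, n_units, cfg)
    props = (w @ onehot) / w.sum(axis=1).astype(float)[:, None]
    mean, lo, hi = _percentile_summary(props, cfg.ci)
    counts = onehot.sum(axis=0)
    n = len(regions)
    return [
        IntervalEstimate(
            mean=float(mean[r]),
            lower=float(lo[r]),
            upper=float(hi[r]),
            method="bootstrap",
            n_success=int(counts[r]),
            n_total=n,
        )
        for r in range(N_REGIONS)
    ]


# ---------------------------------------------------------------------------
# table-level drivers


def drainage_table(
    source: Cohort | ContingencyTable,
    methods: tuple[str, ...] = ("bayes", "bootstrap", "regression"),
    scope: str = "whole-breast",
    cfg: BootstrapConfig | None = None,
    prior: PriorSpec | None = None,
) -> dict[tuple[str, int | None, str], IntervalEstimate]:
    """Drainage estimates for every node field (x region when per-region).

    Returns a mapping ``(node_field, region-or-None, method) -> estimate``.
    Bootstrap requires record-level input (a Cohort); count-based methods
    accept either a Cohort or a ContingencyTable.
    """
    if scope not in ("whole-breast", "per-region"):
        raise ValueError("scope must be 'whole-breast' or 'per-region'")
    cohort = source if isinstance(source, Cohort) else None
    table = build_contingency(source) if cohort is not None else source
    if "bootstrap" in methods and cohort is None:
        raise ValueError(
            "bootstrap needs record-level data (a Cohort): patient-level "
            "resampling cannot be done from aggregate counts"
        )
    regions: list[int | None] = [None] if scope == "whole-breast" else list(range(N_REGIONS))
    out: dict[tuple[str, int | None, str], IntervalEstimate] = {}
    for region in regions:
        if region is None:
            n_total = table.n_total
            counts = table.field_totals
        else:
            n_total = int(table.region_totals[region])
            counts = table.field_counts[region]
        if n_total == 0:
            continue
        boot = (
            drainage_bootstrap_all(cohort, region=region, cfg=cfg)
            if "bootstrap" in methods
            else None
        )
        for f, name in enumerate(NODE_FIELDS):
            if "bayes" in methods:
                out[(name, region, "bayes")] = drainage_bayes(int(counts[f]), n_total, prior)
            if "regression" in methods:
                out[(name, region, "regression")] = drainage_regression(int(counts[f]), n_total)
            if boot is not None:
                out[(name, region, "bootstrap")] = boot[f]
    return out


def prevalence_table(
    source: Cohort | ContingencyTable,
    methods: tuple[str, ...] = ("bayes", "bootstrap", "sison-glaz"),
    cfg: BootstrapConfig | None = None,
    prior: PriorSpec | None = None,
) -> dict[tuple[int, str], IntervalEstimate]:
    """Tumour prevalence for the 13 regions, ``(region, method) -> estimate``."""
    cohort = source if isinstance(source, Cohort) else None
    table = build_contingency(source) if cohort is not None else source
    if "bootstrap" in methods and cohort is None:
        raise ValueError("bootstrap needs record-level data (a Cohort)")
    counts = table.region_totals
    out: dict[tuple[int, str], IntervalEstimate] = {}
    if "bayes" in methods:
        for r, est in enumerate(prevalence_bayes(counts, prior)):
            out[(r, "bayes")] = est
    if "sison-glaz" in methods:
        for r, est in enumerate(prevalence_sison_glaz(counts)):
            out[(r, "sison-glaz")] = est
    if "bootstrap" in methods:
        for r, est in enumerate(prevalence_bootstrap(cohort, cfg=cfg)):
            out[(r, "bootstrap")] = est
    return out


def prevalence_by_field(
    source: Cohort | ContingencyTable,
    node_field: str,
    methods: tuple[str, ...] = ("bayes", "sison-glaz"),
    cfg: BootstrapConfig | None = None,
    prior: PriorSpec | None = None,
) -> dict[tuple[int, str], IntervalEstimate]:
    """Region prevalence restricted to tumours draining to ``node_field``."""
    if node_field not in NODE_FIELD_INDEX:
        raise ValueError(f"unknown node field {node_field!r}")
    cohort = source if isinstance(source, Cohort) else None
    table = build_contingency(source) if cohort is not None else source
    counts = table.field_counts[:, NODE_FIELD_INDEX[node_field]]
    if counts.sum() == 0:
        raise ValueError(f"no tumours drain to {node_field}")
    out: dict[tuple[int, str], IntervalEstimate] = {}
    if "bayes" in methods:
        for r, est in enumerate(prevalence_bayes(counts, prior)):
            out[(r, "bayes")] = est
    if "sison-glaz" in methods:
        for r, est in enumerate(prevalence_sison_glaz(counts)):
            out[(r, "sison-glaz")] = est
    if "bootstrap" in methods:
        if cohort is None:
            raise ValueError("bootstrap needs record-level data (a Cohort)")
        for r, est in enumerate(prevalence_bootstrap(cohort, node_field=node_field, cfg=cfg)):
            out[(r, "bootstrap")] = est
    return out
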