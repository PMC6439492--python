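"""Approximate Bayesian computation over coalescent reference tables.

The pipeline mirrors the classic rejection + regression ABC workflow for
demographic model choice and parameter estimation:

1. :func:`compute_summary_stats` condenses a dataset (observed or
   simulated) into a fixed-order vector of group-level statistics;
2. :func:`build_reference_table` simulates parameter draws and their
   summary vectors under each candidate scenario;
3. :func:`rejection` retains the fraction of simulations closest to the
   observed vector (Euclidean distance on SD-standardized statistics);
4. :func:`model_choice_logistic` fits a multinomial logistic regression
   of scenario index on statistics over the retained set and evaluates it
   at the observed point (delta-method 95% CIs on the probabilities);
5. :func:`estimate_parameters` applies the local-linear regression
   adjustment with Epanechnikov kernel weights (sizes/times on log scale,
   admixture rate on logit scale) and reports weighted posterior
   summaries;
6. :func:`posterior_predictive_error` measures how often datasets
   simulated from the fitted posterior fail to re-select the scenario;
7. :func:`pca_check` projects observed and simulated vectors for a
   visual goodness-of-fit check.

Statistics that are undefined on a given dataset (e.g. F_ST for a
monomorphic pair) are imputed as 0 and flagged; columns with zero
variance across the reference table are excluded from distances.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import popgen_stats
from .coalsim import MutationModel, SampleConfig, simulate_dataset
from .datasets import PopulationDataset
from .demography import DemographicScenario, ParameterDraw

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStatVector",
    "ReferenceTable",
    "RejectionResult",
    "ModelChoiceResult",
    "ParameterPosterior",
    "PPEResult",
    "PcaCheckResult",
    "compute_summary_stats",
    "build_reference_table",
    "rejection",
    "model_choice_logistic",
    "estimate_parameters",
    "posterior_predictive_error",
    "pca_check",
    "weighted_quantile",
]

STAT_PREFIX = "ss_"
PARAM_PREFIX = "par_"


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SummaryStatVector:
    """Ordered, named summary-statistic vector for one dataset.

    ``defined`` flags statistics that were computable; undefined entries
    hold 0.0.
    """

    names: list[str]
    values: np.ndarray
    defined: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    def __len__(self) -> int:
        return len(self.names)


def _finalize(names: list[str], raw: list[float]) -> SummaryStatVector:
    values = np.asarray(raw, dtype=float)
    defined = np.isfinite(values)
    if not defined.all():
        undef = [n for n, d in zip(names, defined) if not d]
        logger.warning("undefined summary statistics imputed as 0: %s", undef)
    return SummaryStatVector(
        names=names, values=np.where(defined, values, 0.0), defined=defined
    )


def compute_summary_stats(
    dataset: PopulationDataset, level: str = "group"
) -> SummaryStatVector:
    """Group-level ABC summary vector for one dataset.

    Per sample (group): mean alleles/locus, mean gene diversity, mean
    allele-size variance; per sample pair: Weir–Cockerham F_ST, mean
    classification index (both directions averaged) and (delta-mu)^2.
    With a sequence locus, per sample: haplotype count, segregating
    sites, mean pairwise differences; per pair: haplotype-frequency F_ST
    and mean between-sample pairwise differences.  The vector ordering is
    fixed by the sorted sample labels, so observed and simulated data
    share one code path.
    """
    part = dataset.partition
    if level == "group" and part.population_to_group is None:
        level = "population"
    labels = sorted(
        part.groups if level == "group" else part.populations
    )
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for pairwise statistics")
    pairs = list(itertools.combinations(labels, 2))

    names: list[str] = []
    raw: list[float] = []

    bundle = popgen_stats.msat_group_bundle(dataset.genotypes, part, level=level)
    basics = bundle["basics"]
    for g in labels:
        names += [f"msat_na_{g}", f"msat_he_{g}", f"msat_v_{g}"]
        raw += [basics.loc[g, "N_A"], basics.loc[g, "H_E"], basics.loc[g, "V"]]
    for g1, g2 in pairs:
        names += [
            f"msat_fst_{g1}_{g2}",
            f"msat_lik_{g1}_{g2}",
            f"msat_dmu2_{g1}_{g2}",
        ]
        raw += [
            bundle["fst"].loc[g1, g2],
            bundle["lik"].loc[g1, g2],
            bundle["dmu2"].loc[g1, g2],
        ]

    if dataset.sequences is not None:
        seq = popgen_stats.sequence_group_bundle(
            dataset.sequences, part, level=level
        )
        summaries = seq["summaries"]
        for g in labels:
            names += [f"seq_h_{g}", f"seq_s_{g}", f"seq_mpd_{g}"]
            raw += [
                summaries.loc[g, "h"],
                summaries.loc[g, "S"],
                summaries.loc[g, "MPD"],
            ]
        for g1, g2 in pairs:
            names += [f"seq_fst_{g1}_{g2}", f"seq_mpd_{g1}_{g2}"]
            raw += [
                seq["fst"].loc[g1, g2],
                seq["mpd_between"].loc[g1, g2],
            ]
    return _finalize(names, raw)


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Bank of (scenario, parameter draw, summary vector) triplets.

    ``df`` has one row per simulation: a ``scenario`` column, parameter
    columns prefixed ``par_`` (NaN where a scenario lacks the parameter)
    and statistic columns prefixed ``ss_``.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def stat_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith(STAT_PREFIX)]

    @property
    def stat_names(self) -> list[str]:
        return [c[len(STAT_PREFIX):] for c in self.stat_columns]

    @property
    def param_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith(PARAM_PREFIX)]

    @property
    def scenarios(self) -> list[str]:
        return list(dict.fromkeys(self.df["scenario"]))

    def scenario_counts(self) -> pd.Series:
        return self.df["scenario"].value_counts()

    def stats_matrix(self) -> np.ndarray:
        return self.df[self.stat_columns].to_numpy(dtype=float)

    def append(self, other: "ReferenceTable") -> "ReferenceTable":
        """Concatenate two chunks with identical statistic layouts."""
        if self.stat_columns != other.stat_columns:
            raise ValueError("chunks have different statistic layouts")
        df = pd.concat([self.df, other.df], ignore_index=True)
        meta = dict(self.metadata)
        meta["n_rows"] = len(df)
        return ReferenceTable(df=df, metadata=meta)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#metadata: " + json.dumps(self.metadata, default=str) + "\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTable":
        metadata: dict = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#metadata: "):
                metadata = json.loads(first[len("#metadata: "):])
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        return cls(df=df, metadata=metadata)


def build_reference_table(
    scenarios: list[DemographicScenario],
    n_per_scenario: int,
    cfg: SampleConfig,
    model: MutationModel,
    rng: np.random.Generator,
    level: str = "group",
    max_retries: int = 3,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` datasets per scenario and collect their
    parameter draws and summary vectors.

    Reproducible given the generator state; a failed simulation is logged
    and retried with fresh draws up to ``max_retries`` times.  Build in
    chunks and combine with :meth:`ReferenceTable.append` to checkpoint
    long runs.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    param_names: list[str] = []
    for s in scenarios:
        for p in s.parameter_names:
            if p not in param_names:
                param_names.append(p)

    rows: list[dict] = []
    stat_names: list[str] | None = None
    for scenario in scenarios:
        for _ in range(n_per_scenario):
            for attempt in range(max_retries + 1):
                try:
                    draw = scenario.draw(rng)
                    ds = simulate_dataset(scenario, draw, cfg, model, rng)
                    vec = compute_summary_stats(ds, level=level)
                    break
                except Exception:
                    if attempt == max_retries:
                        raise
                    logger.exception(
                        "simulation failed under %s; retrying", scenario.name
                    )
            if stat_names is None:
                stat_names = vec.names
            elif vec.names != stat_names:
                raise RuntimeError("inconsistent summary-statistic layout")
            row: dict = {"scenario": scenario.name}
            for p in param_names:
                row[PARAM_PREFIX + p] = draw.values.get(p, np.nan)
            for n, v in zip(vec.names, vec.values):
                row[STAT_PREFIX + n] = v
            rows.append(row)
    df = pd.DataFrame(rows)
    metadata = {
        "n_per_scenario": n_per_scenario,
        "n_rows": len(df),
        "scenarios": [s.name for s in scenarios],
        "parameters": param_names,
        "sample_config": {
            "populations": dict(cfg.populations),
            "n_msat_loci": cfg.n_msat_loci,
            "sequence_length": cfg.sequence_length,
        },
        "mutation_model": {
            "msat_mu_mean": model.msat_mu_mean,
            "msat_rate_shape": model.msat_rate_shape,
            "p_geom": model.p_geom,
            "k_states": model.k_states,
            "seq_mu": model.seq_mu,
            "kappa": model.kappa,
            "mito_scale": model.mito_scale,
        },
    }
    return ReferenceTable(df=df, metadata=metadata)


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------


@dataclass
class RejectionResult:
    """Retained simulations (closest fraction) and their distances."""

    retained: pd.DataFrame
    distances: np.ndarray  # aligned with ``retained`` rows
    all_distances: np.ndarray  # aligned with the table rows
    used_stats: list[str]
    scales: pd.Series  # per-stat SD used for standardization
    center: pd.Series  # per-stat mean of the table
    tolerance: float

    @property
    def d_max(self) -> float:
        return float(self.distances.max()) if self.distances.size else 0.0


def _align_observed(table: ReferenceTable, observed: SummaryStatVector) -> pd.Series:
    obs = observed.as_series()
    missing = [n for n in table.stat_names if n not in obs.index]
    if missing:
        raise ValueError(f"observed vector lacks statistics: {missing[:5]}")
    return obs.loc[table.stat_names]


def rejection(
    table: ReferenceTable,
    observed: SummaryStatVector,
    tolerance: float,
) -> RejectionResult:
    """Retain the ``ceil(tolerance * n)`` simulations closest to the data.

    Distance is Euclidean on statistics standardized by the reference
    table's standard deviation; zero-variance statistics are excluded
    (logged).  Ties broken by row order.
    """
    if not 0.0 < tolerance <= 1.0:
        raise ValueError("tolerance must be in (0, 1]")
    obs = _align_observed(table, observed)
    stats = table.stats_matrix()
    sd = stats.std(axis=0, ddof=0)
    mean = stats.mean(axis=0)
    usable = sd > 0
    if not usable.any():
        raise ValueError("all summary statistics are constant in the table")
    dropped = [n for n, u in zip(table.stat_names, usable) if not u]
    if dropped:
        logger.warning("zero-variance statistics excluded from distance: %s", dropped)
    z = (stats[:, usable] - obs.to_numpy()[usable]) / sd[usable]
    dist = np.sqrt((z**2).sum(axis=1))
    n_keep = math.ceil(tolerance * len(table.df))
    order = np.argsort(dist, kind="stable")[:n_keep]
    order = np.sort(order)  # keep original row order among retained
    return RejectionResult(
        retained=table.df.iloc[order].reset_index(drop=True),
        distances=dist[order],
        all_distances=dist,
        used_stats=[n for n, u in zip(table.stat_names, usable) if u],
        scales=pd.Series(sd, index=table.stat_names),
        center=pd.Series(mean, index=table.stat_names),
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# multinomial logistic regression (ridge Newton)
# ---------------------------------------------------------------------------


def _fit_multinomial_ridge(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    ridge: float = 1e-6,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-penalized multinomial logistic fit by Newton's method.

    ``X`` excludes the intercept (added internally); ``y`` holds class
    codes 0..n_classes-1 with the last class as softmax baseline.
    Returns ``(B, cov)``: coefficients of shape (K-1, d+1) and the
    covariance of the flattened coefficients (inverse observed
    information, ridge included).
    """
    n, d = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    p = d + 1
    K = n_classes
    B = np.zeros((K - 1) * p)
    Y = np.zeros((n, K - 1))
    for k in range(K - 1):
        Y[:, k] = y == k

    def probs(Bmat: np.ndarray) -> np.ndarray:
        eta = Xd @ Bmat.T
        full = np.hstack([eta, np.zeros((n, 1))])
        full -= full.max(axis=1, keepdims=True)
        e = np.exp(full)
        return e / e.sum(axis=1, keepdims=True)

    def penalized_loglik(Bvec: np.ndarray) -> float:
        Bmat = Bvec.reshape(K - 1, p)
        P = probs(Bmat)
        idx = np.clip(y, 0, K - 1)
        ll = float(np.log(np.maximum(P[np.arange(n), idx], 1e-300)).sum())
        return ll - 0.5 * ridge * float(Bvec @ Bvec)

    ll_old = penalized_loglik(B)
    for _ in range(max_iter):
        Bmat = B.reshape(K - 1, p)
        P = probs(Bmat)[:, : K - 1]
        grad = ((Y - P).T @ Xd).ravel() - ridge * B
        # negative Hessian (observed information), built blockwise
        info = np.empty(((K - 1) * p, (K - 1) * p))
        for k in range(K - 1):
            for l in range(k, K - 1):
                w = P[:, k] * ((1.0 if k == l else 0.0) - P[:, l])
                block = Xd.T @ (Xd * w[:, None])
                info[k * p:(k + 1) * p, l * p:(l + 1) * p] = block
                if l != k:
                    info[l * p:(l + 1) * p, k * p:(k + 1) * p] = block.T
        info[np.diag_indices_from(info)] += ridge
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step halving to guarantee ascent
        scale_step = 1.0
        for _ in range(30):
            B_new = B + scale_step * step
            ll_new = penalized_loglik(B_new)
            if ll_new >= ll_old - 1e-12:
                break
            scale_step *= 0.5
        B = B_new
        if abs(ll_new - ll_old) < tol and float(np.abs(grad).max()) < 1e-4:
            ll_old = ll_new
            break
        ll_old = ll_new
    # covariance at the optimum
    Bmat = B.reshape(K - 1, p)
    P = probs(Bmat)[:, : K - 1]
    info = np.empty(((K - 1) * p, (K - 1) * p))
    for k in range(K - 1):
        for l in range(k, K - 1):
            w = P[:, k] * ((1.0 if k == l else 0.0) - P[:, l])
            block = Xd.T @ (Xd * w[:, None])
            info[k * p:(k + 1) * p, l * p:(l + 1) * p] = block
            if l != k:
                info[l * p:(l + 1) * p, k * p:(k + 1) * p] = block.T
    info[np.diag_indices_from(info)] += ridge
    cov = np.linalg.pinv(info)
    return Bmat, cov


@dataclass
class ModelChoiceResult:
    """Posterior scenario probabilities from rejection and logistic
    regression, with delta-method 95% CIs on the logistic estimates."""

    probabilities: pd.DataFrame  # index: scenario; columns: direct, logistic, lo, hi
    selected: str
    tolerance: float
    n_retained: int
    degenerate: bool = False

    def probability(self, scenario: str) -> float:
        return float(self.probabilities.loc[scenario, "logistic"])


def model_choice_logistic(
    table: ReferenceTable,
    observed: SummaryStatVector,
    tolerance: float = 0.01,
    ridge: float = 1e-6,
) -> ModelChoiceResult:
    """Scenario choice by multinomial logistic regression on the retained
    set, evaluated at the observed point.

    Statistics are standardized by the table SD and centered at the
    observed vector, so the fitted intercepts are the linear predictors
    at the data; 95% CIs propagate their covariance through the softmax
    (delta method).  Direct rejection proportions are reported alongside.
    """
    rej = rejection(table, observed, tolerance)
    scenarios = table.scenarios
    retained_scen = rej.retained["scenario"].to_numpy()
    counts = pd.Series(0.0, index=scenarios)
    vc = pd.Series(retained_scen).value_counts()
    counts.loc[vc.index] = vc
    direct = counts / counts.sum()

    present = [s for s in scenarios if counts[s] > 0]
    if len(present) < 2:
        logger.warning(
            "retained set contains a single scenario; degenerate probabilities"
        )
        prob = pd.DataFrame(
            {
                "direct": direct,
                "logistic": (direct > 0).astype(float),
                "lo": (direct > 0).astype(float),
                "hi": (direct > 0).astype(float),
            }
        )
        return ModelChoiceResult(
            probabilities=prob,
            selected=present[0],
            tolerance=tolerance,
            n_retained=len(rej.retained),
            degenerate=True,
        )

    obs = _align_observed(table, observed)
    use = [n for n in rej.used_stats]
    cols = [STAT_PREFIX + n for n in use]
    sd = rej.scales.loc[use].to_numpy()
    X = (rej.retained[cols].to_numpy(dtype=float) - obs.loc[use].to_numpy()) / sd
    code = {s: i for i, s in enumerate(present)}
    y = np.array([code[s] for s in retained_scen])
    K = len(present)
    B, cov = _fit_multinomial_ridge(X, y, K, ridge=ridge)

    p_feat = X.shape[1] + 1
    eta = B[:, 0]  # linear predictors at the observed point (features = 0)
    intercept_idx = np.arange(K - 1) * p_feat
    cov_eta = cov[np.ix_(intercept_idx, intercept_idx)]
    full = np.concatenate([eta, [0.0]])
    full -= full.max()
    e = np.exp(full)
    pk = e / e.sum()
    # Jacobian of softmax wrt the K-1 free predictors
    J = np.zeros((K, K - 1))
    for k in range(K):
        for l in range(K - 1):
            J[k, l] = pk[k] * ((1.0 if k == l else 0.0) - pk[l])
    cov_p = J @ cov_eta @ J.T
    se = np.sqrt(np.maximum(np.diag(cov_p), 0.0))
    lo = np.clip(pk - 1.96 * se, 0.0, 1.0)
    hi = np.clip(pk + 1.96 * se, 0.0, 1.0)

    logistic = pd.Series(0.0, index=scenarios)
    lo_s = pd.Series(0.0, index=scenarios)
    hi_s = pd.Series(0.0, index=scenarios)
    for s, i in code.items():
        logistic[s] = pk[i]
        lo_s[s] = lo[i]
        hi_s[s] = hi[i]
    prob = pd.DataFrame(
        {"direct": direct, "logistic": logistic, "lo": lo_s, "hi": hi_s}
    )
    selected = str(prob["logistic"].idxmax())
    return ModelChoiceResult(
        probabilities=prob,
        selected=selected,
        tolerance=tolerance,
        n_retained=len(rej.retained),
    )


# ---------------------------------------------------------------------------
# parameter estimation (local-linear regression adjustment)
# ---------------------------------------------------------------------------


def weighted_quantile(
    values: np.ndarray, weights: np.ndarray, q: float | np.ndarray
) -> np.ndarray:
    """Quantile(s) of a weighted sample (interpolated inverse CDF)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(q, cum, v)


def _transform(name: str, x: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    lo, hi = bounds
    if 0.0 <= lo and hi <= 1.0:  # rate-like parameter
        xc = np.clip(x, 1e-12, 1.0 - 1e-12)
        return np.log(xc / (1.0 - xc))
    return np.log(np.maximum(x, 1e-300))


def _back_transform(name: str, z: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    lo, hi = bounds
    if 0.0 <= lo and hi <= 1.0:
        return 1.0 / (1.0 + np.exp(-z))
    return np.exp(z)


def _prior_bounds(scenario: DemographicScenario, name: str) -> tuple[float, float]:
    dist, lo, hi = scenario.prior.params[name]
    lo_f = 0.0 if isinstance(lo, str) else float(lo)
    hi_f = np.inf if isinstance(hi, str) else float(hi)
    return lo_f, hi_f


@dataclass
class ParameterPosterior:
    """Weighted, regression-adjusted posterior sample with summaries."""

    scenario: str
    samples: pd.DataFrame  # adjusted draws, natural scale
    weights: np.ndarray  # normalized, sum to 1
    summary: pd.DataFrame  # index: parameter; columns: median, q2.5, q97.5
    adjusted: bool = True

    def sample_rows(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        idx = rng.choice(len(self.samples), size=n, p=self.weights)
        return self.samples.iloc[idx].reset_index(drop=True)


def estimate_parameters(
    table: ReferenceTable,
    observed: SummaryStatVector,
    tolerance: float,
    scenario: DemographicScenario,
    min_retained: int = 50,
) -> ParameterPosterior:
    """Local-linear ABC posterior for one scenario's parameters.

    Rejection runs on the scenario's own rows; retained draws get
    Epanechnikov weights ``1 - (d/d_max)^2`` and each parameter
    (log-transformed sizes/times, logit-transformed rates) is adjusted by
    a weighted linear regression on the standardized statistics,
    transported to the observed point.  A singular regression falls back
    to the unadjusted weighted sample with a warning.
    """
    sub_df = table.df[table.df["scenario"] == scenario.name].reset_index(drop=True)
    if sub_df.empty:
        raise ValueError(f"table has no rows for scenario {scenario.name!r}")
    sub = ReferenceTable(df=sub_df, metadata=table.metadata)
    rej = rejection(sub, observed, tolerance)
    n_ret = len(rej.retained)
    if n_ret < min_retained:
        raise ValueError(
            f"only {n_ret} retained rows for {scenario.name!r}; "
            f"need >= {min_retained} (raise the tolerance or the table size)"
        )
    d_max = rej.d_max
    if d_max > 0:
        w = 1.0 - (rej.distances / d_max) ** 2
    else:
        w = np.ones(n_ret)
    w = np.maximum(w, 1e-12)
    w = w / w.sum()

    obs = _align_observed(table, observed)
    use = rej.used_stats
    cols = [STAT_PREFIX + n for n in use]
    sd = rej.scales.loc[use].to_numpy()
    X = (rej.retained[cols].to_numpy(dtype=float) - obs.loc[use].to_numpy()) / sd

    params = scenario.parameter_names
    adjusted = True
    out = {}
    A = np.hstack([np.ones((n_ret, 1)), X])
    Aw = A * w[:, None]
    gram = A.T @ Aw
    for name in params:
        theta = rej.retained[PARAM_PREFIX + name].to_numpy(dtype=float)
        bounds = _prior_bounds(scenario, name)
        z = _transform(name, theta, bounds)
        if np.ptp(z) == 0.0:  # constant parameter collapses to itself
            out[name] = np.full(n_ret, theta[0], dtype=float)
            continue
        rhs = A.T @ (w * z)
        try:
            beta = np.linalg.solve(gram, rhs)
            cond_ok = np.isfinite(beta).all()
        except np.linalg.LinAlgError:
            cond_ok = False
        if not cond_ok:
            logger.warning(
                "singular local-linear regression for %s; using unadjusted sample",
                name,
            )
            adjusted = False
            out[name] = theta
            continue
        z_adj = z - X @ beta[1:]
        out[name] = _back_transform(name, z_adj, bounds)

    samples = pd.DataFrame(out)
    qs = {}
    for name in params:
        med, lo, hi = weighted_quantile(
            samples[name].to_numpy(), w, np.array([0.5, 0.025, 0.975])
        )
        qs[name] = {"median": med, "q2.5": lo, "q97.5": hi}
    summary = pd.DataFrame.from_dict(qs, orient="index")
    return ParameterPosterior(
        scenario=scenario.name,
        samples=samples,
        weights=w,
        summary=summary,
        adjusted=adjusted,
    )


# ---------------------------------------------------------------------------
# posterior predictive error
# ---------------------------------------------------------------------------


@dataclass
class PPEResult:
    """Scenario-choice error rate over posterior-predictive datasets."""

    error_rate: float
    n_pods: int
    selections: list[str]


def posterior_predictive_error(
    table: ReferenceTable,
    scenario: DemographicScenario,
    posterior: ParameterPosterior,
    n_pods: int,
    cfg: SampleConfig,
    model: MutationModel,
    rng: np.random.Generator,
    tolerance: float = 0.01,
    level: str = "group",
) -> PPEResult:
    """Fraction of pseudo-observed datasets, simulated under ``scenario``
    with parameters drawn from ``posterior``, for which model choice
    against ``table`` does not re-select the scenario."""
    if n_pods < 1:
        raise ValueError("n_pods must be >= 1")
    selections: list[str] = []
    errors = 0
    for _ in range(n_pods):
        values = _valid_posterior_draw(scenario, posterior, rng)
        draw = ParameterDraw(scenario.name, values)
        ds = simulate_dataset(scenario, draw, cfg, model, rng)
        vec = compute_summary_stats(ds, level=level)
        choice = model_choice_logistic(table, vec, tolerance)
        selections.append(choice.selected)
        if choice.selected != scenario.name:
            errors += 1
    return PPEResult(
        error_rate=errors / n_pods, n_pods=n_pods, selections=selections
    )


def _valid_posterior_draw(
    scenario: DemographicScenario,
    posterior: ParameterPosterior,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> dict[str, float]:
    """One posterior draw satisfying the scenario's structural constraints.

    Regression adjustment can push draws slightly outside the prior
    support or violate the event-time ordering; such draws are resampled
    and, as a last resort, times are nudged into order.
    """
    from .demography import validate_scenario

    for _ in range(max_tries):
        row = posterior.sample_rows(1, rng).iloc[0]
        values = {k: float(v) for k, v in row.items()}
        if not validate_scenario(scenario, ParameterDraw(scenario.name, values)):
            return values
    if "t1" in values and "t2" in values and values["t1"] >= values["t2"]:
        values["t1"] = 0.999 * values["t2"]
    if not validate_scenario(scenario, ParameterDraw(scenario.name, values)):
        return values
    raise RuntimeError(
        f"could not draw valid parameters from the posterior of {scenario.name!r}"
    )


# ---------------------------------------------------------------------------
# PCA model check
# ---------------------------------------------------------------------------


@dataclass
class PcaCheckResult:
    """Projection of reference, retained and observed summary vectors."""

    table_coords: np.ndarray
    observed_coords: np.ndarray
    retained_coords: np.ndarray | None
    explained_variance_ratio: np.ndarray
    components: np.ndarray


def pca_check(
    table: ReferenceTable,
    observed: SummaryStatVector,
    retained: pd.DataFrame | None = None,
    n_components: int = 2,
) -> PcaCheckResult:
    """PCA of the standardized reference-table statistics with the
    observed vector (and optionally the retained rows) projected in.

    A well-fitting model places the observed point inside the cloud of
    simulated points.  Plot rendering is left to the caller.
    """
    from sklearn.decomposition import PCA

    stats = table.stats_matrix()
    sd = stats.std(axis=0, ddof=0)
    usable = sd > 0
    if usable.sum() < 2:
        raise ValueError("need at least 2 varying statistics for a PCA")
    mean = stats.mean(axis=0)
    Z = (stats[:, usable] - mean[usable]) / sd[usable]
    n_components = min(n_components, Z.shape[1], Z.shape[0])
    pca = PCA(n_components=n_components)
    table_coords = pca.fit_transform(Z)

    obs = _align_observed(table, observed).to_numpy()
    z_obs = (obs[usable] - mean[usable]) / sd[usable]
    observed_coords = pca.transform(z_obs[None, :])[0]

    retained_coords = None
    if retained is not None:
        cols = [STAT_PREFIX + n for n in table.stat_names]
        r = retained[cols].to_numpy(dtype=float)
        z_r = (r[:, usable] - mean[usable]) / sd[usable]
        retained_coords = pca.transform(z_r)
    return PcaCheckResult(
        table_coords=table_coords,
        observed_coords=observed_coords,
        retained_coords=retained_coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=pca.components_,
    )
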