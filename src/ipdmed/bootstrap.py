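"""Stratified bootstrap-then-impute inference with BCa confidence intervals.

Participants are resampled with replacement separately within each (study, arm)
stratum, so every bootstrap dataset preserves all stratum sizes — this respects the
clustered design and keeps per-study and per-arm sample sizes fixed across replicates.
Each replicate is completed with multivariate-normal multiple imputation (bootstrap
first, impute second: imputation uncertainty is re-evaluated inside every replicate),
the mediation model is fitted on each completed copy, and per-replicate estimates are
pooled by the mean across imputations. Bias-corrected-and-accelerated (BCa) intervals
adjust the percentile endpoints for median bias (z0, from the share of replicates below
the original-sample estimate) and skewness (acceleration, from a leave-one-study-out
jackknife, which respects the clustering; the no-acceleration BC interval is available
for comparison).

Two point estimates are reported and labeled: the mean over bootstrap replicates and
the original-sample estimate (pooled over imputations with a reserved seed); BCa's bias
correction is anchored at the latter. Every replicate draws its randomness from a seed
ladder keyed by (base seed, replicate index), so any replicate is reproducible in
isolation and parallel execution cannot change results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from .data_model import Arm, IPDDataset, ModelSpec, TX_TERMS, detect_estimable_terms
from .imputation import draw_imputations
from .mediation import TERM_COLUMNS, WeightVector, compute_weights

__all__ = [
    "BootstrapConfig",
    "BootstrapDistribution",
    "parameter_names",
    "stratified_resample",
    "run_replicate",
    "run_bootstrap",
    "bca_interval",
    "jackknife_estimates",
]

_THETA_STREAM = 1_000_000_007  # reserved seed-ladder index for the original-sample fit
_JACK_STREAM = 2_000_000_011  # base index for jackknife refits


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for the stratified bootstrap-then-impute run.

    B bootstrap replicates, m imputations per replicate, interval level
    1 − alpha. ``acceleration_scheme`` chooses between leave-one-study-out
    jackknife acceleration and plain bias correction (accel = 0).
    """

    B: int = 5000
    m: int = 10
    alpha: float = 0.05
    seed: int = 0
    acceleration_scheme: Literal["JACKKNIFE_STUDY", "NONE"] = "JACKKNIFE_STUDY"
    weight_scheme: Literal["inv_sqrt_n", "uniform"] = "inv_sqrt_n"
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.B < 1 or self.m < 1 or not (0 < self.alpha < 1):
            raise ValueError("require B >= 1, m >= 1, 0 < alpha < 1")


def parameter_names(spec: ModelSpec) -> list[str]:
    """Ordered labels of the replicate parameter vector for a model spec."""
    names = [f"eqA_{t}" for t in spec.eqA_terms] + [f"eqB_{t}" for t in spec.eqB_terms]
    for arm in spec.arms:
        k = arm.value
        names += [
            f"a_{k}", f"direct_{k}", f"indirect_{k}", f"total_{k}",
            f"std_a_{k}", f"std_direct_{k}", f"std_indirect_{k}", f"std_total_{k}",
        ]
    names += ["b_med", "std_b_med_per_unit", "std_b_med_per_sd", "r2_A", "r2_B", "sd_A", "sd_B"]
    return names


class _AnalysisContext:
    """Precomputed numpy arrays for fast replicate evaluation.

    Holds the full numeric matrix (scores, demographics, treatment dummies, study
    dummies), the column subsets for the imputation model and the two design
    matrices, the stratum index arrays, and the weight vector. Columns with no
    variation in scope (study-level missing by design) are excluded from the
    imputation model; if such a column still has missing cells they are filled
    with the observed constant rather than imputed.
    """

    def __init__(self, ds: IPDDataset, spec: ModelSpec, weights: WeightVector):
        df = ds.df
        n = len(df)
        self.spec = spec
        self.names = parameter_names(spec)
        self.w = np.asarray(weights.w, dtype=float)

        cols: dict[str, np.ndarray] = {
            v: df[v].to_numpy(dtype=float)
            for v in ("bl_mediator", "post_mediator", "bl_outcome", "post_outcome",
                      "male", "firstyr", "nonwhite")
        }
        arm_vals = np.asarray([a.value for a in df["arm"]])
        for t in TX_TERMS:
            if t in spec.eqA_terms:
                cols[t] = (arm_vals == t.removeprefix("TX_")).astype(float)
        studies = list(dict.fromkeys(df["study"]))
        study_arr = df["study"].to_numpy()
        for s in studies[1:]:
            cols[f"_study_{s}"] = (study_arr == s).astype(float)

        self.col_names = list(cols)
        self.Z = np.column_stack([cols[c] for c in self.col_names])
        self.col_idx = {c: j for j, c in enumerate(self.col_names)}

        # imputation model: every column with variation among observed values
        mvn, const_fill = [], {}
        binary = {"male", "firstyr", "nonwhite"}
        for c, j in self.col_idx.items():
            col = self.Z[:, j]
            obs = col[~np.isnan(col)]
            if obs.size >= 2 and obs.min() < obs.max():
                mvn.append(j)
            elif np.isnan(col).any():
                fill = float(np.round(obs.mean())) if c in binary else float(obs.mean())
                const_fill[j] = fill
        self.mvn_idx = np.asarray(mvn, dtype=int)
        self.const_fill = const_fill
        self.binary_pos = tuple(
            k for k, j in enumerate(self.mvn_idx) if self.col_names[j] in binary
        )

        def _design_cols(terms):
            return np.asarray(
                [self.col_idx[t if t in TX_TERMS else TERM_COLUMNS[t]]
                 for t in terms if t != "intercept"],
                dtype=int,
            )

        self.eqA_cols = _design_cols(spec.eqA_terms)
        self.eqB_cols = _design_cols(spec.eqB_terms)
        self.yA_col = self.col_idx["post_mediator"]
        self.yB_col = self.col_idx["post_outcome"]
        self.strata = [np.asarray(v) for v in ds.strata.values()]
        self.has_missing = bool(np.isnan(self.Z).any())

    # -- resampling -----------------------------------------------------------
    def resample_indices(self, rng: np.random.Generator) -> np.ndarray:
        parts = [s[rng.integers(0, len(s), size=len(s))] for s in self.strata]
        return np.concatenate(parts)

    # -- fitting --------------------------------------------------------------
    @staticmethod
    def _wls_fast(X: np.ndarray, y: np.ndarray, w: np.ndarray):
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        yw = y * sw
        G = Xw.T @ Xw
        h = Xw.T @ yw
        c, low = cho_factor(G, lower=True)
        beta = cho_solve((c, low), h)
        sse = max(float(yw @ yw - beta @ h), 0.0)
        swsum = float(w.sum())
        ybar = float(w @ y) / swsum
        sst = float(w @ (y - ybar) ** 2)
        return beta, sse, sst, np.sqrt(sst / swsum)

    def fit_vector(self, C: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Parameter vector from one completed data matrix."""
        n = C.shape[0]
        ones = np.ones((n, 1))
        XA = np.hstack([ones, C[:, self.eqA_cols]])
        XB = np.hstack([ones, C[:, self.eqB_cols]])
        betaA, sseA, sstA, sdA = self._wls_fast(XA, C[:, self.yA_col], w)
        betaB, sseB, sstB, sdB = self._wls_fast(XB, C[:, self.yB_col], w)

        coefA = dict(zip(self.spec.eqA_terms, betaA))
        coefB = dict(zip(self.spec.eqB_terms, betaB))
        b_med = coefB["POST_PBS"]
        out = list(betaA) + list(betaB)
        for arm in self.spec.arms:
            t = f"TX_{arm.value}"
            a_k, d_k = coefA[t], coefB[t]
            ind = a_k * b_med
            tot = d_k + ind
            out += [a_k, d_k, ind, tot, a_k / sdA, d_k / sdB, ind / sdB, tot / sdB]
        out += [
            b_med, b_med / sdB, b_med * sdA / sdB,
            1.0 - sseA / sstA, 1.0 - sseB / sstB, sdA, sdB,
        ]
        return np.asarray(out)

    def evaluate(self, idx: np.ndarray | None, m: int, rng: np.random.Generator) -> np.ndarray:
        """Impute (if needed), fit on each completed copy, pool by the mean."""
        Zr = self.Z if idx is None else self.Z[idx]
        w = self.w if idx is None else self.w[idx]
        if not self.has_missing or not np.isnan(Zr).any():
            return self.fit_vector(Zr, w)
        sub = Zr[:, self.mvn_idx]
        imp = draw_imputations(sub, m=m, rng=rng, binary_cols=self.binary_pos)
        base = Zr.copy()
        for j, fill in self.const_fill.items():
            col = base[:, j]
            col[np.isnan(col)] = fill
        vecs = []
        for comp in imp.completed:
            C = base.copy()
            C[:, self.mvn_idx] = comp
            vecs.append(self.fit_vector(C, w))
        return np.mean(vecs, axis=0)


@dataclass
class BootstrapDistribution:
    """Replicate-by-parameter bootstrap distribution with BCa machinery."""

    names: list[str]
    estimates: np.ndarray  # (B_kept, P)
    theta_hat: np.ndarray  # original-sample estimate (P,)
    z0: np.ndarray
    accel: np.ndarray
    intervals: np.ndarray  # (P, 2)
    alpha: float
    n_discarded: int
    config: BootstrapConfig | None = None
    jackknife: np.ndarray | None = field(default=None, repr=False)

    @property
    def boot_mean(self) -> np.ndarray:
        """Per-parameter mean over bootstrap replicates (the reported point estimate)."""
        return self.estimates.mean(axis=0)

    def __getitem__(self, name: str) -> dict[str, float]:
        j = self.names.index(name)
        return {
            "estimate": float(self.boot_mean[j]),
            "original": float(self.theta_hat[j]),
            "lo": float(self.intervals[j, 0]),
            "hi": float(self.intervals[j, 1]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.names,
                "estimate": self.boot_mean,
                "original": self.theta_hat,
                "lo": self.intervals[:, 0],
                "hi": self.intervals[:, 1],
            }
        )


def stratified_resample(ds: IPDDataset, rng: np.random.Generator | int | None = None) -> IPDDataset:
    """One stratified bootstrap dataset: resample within each (study, arm) stratum.

    The result has exactly the original stratum sizes (hence study sizes and arm
    sizes), with rows drawn with replacement within their stratum.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    parts = [s[rng.integers(0, len(s), size=len(s))] for s in ds.strata.values()]
    return ds.subset(np.concatenate(parts))


def run_replicate(
    ds: IPDDataset,
    spec: ModelSpec,
    weights: WeightVector,
    m: int = 10,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One bootstrap replicate: resample, impute m times, fit, pool by the mean.

    Returns the pooled parameter vector in :func:`parameter_names` order.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ctx = _AnalysisContext(ds, spec, weights)
    idx = ctx.resample_indices(rng)
    return ctx.evaluate(idx, m, rng)


def bca_interval(
    boot_vals: np.ndarray,
    theta_hat: float,
    jack_vals: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected-and-accelerated interval from a bootstrap distribution.

    z0 = Phi^{-1} of the share of replicates below the original-sample estimate
    (ties counted half); acceleration from the jackknife skewness formula
    a = Σ(ȳ − y_i)³ / (6 [Σ(ȳ − y_i)²]^{3/2}) (0 if ``jack_vals`` is None or the
    denominator vanishes). Endpoints are empirical quantiles at the adjusted
    percentiles, with linear interpolation between order statistics. Degenerate
    distributions give lo = hi; an empty tail (all replicates on one side of the
    estimate) clamps z0 using 1/(2B) tail mass, with a warning.
    """
    v = np.asarray(boot_vals, dtype=float)
    B = v.size
    if B < 20:
        raise ValueError("need at least 20 bootstrap values for a BCa interval")
    if not np.all(np.isfinite(v)):
        raise ValueError("bootstrap values must be finite")
    if v.max() == v.min():
        warnings.warn("degenerate bootstrap distribution: interval collapses to a point",
                      stacklevel=2)
        return float(v[0]), float(v[0])
    p = (np.count_nonzero(v < theta_hat) + 0.5 * np.count_nonzero(v == theta_hat)) / B
    if p <= 0.0 or p >= 1.0:
        warnings.warn("all bootstrap values on one side of the estimate; clamping z0",
                      stacklevel=2)
        p = min(max(p, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = norm.ppf(p)
    a = 0.0
    if jack_vals is not None:
        y = np.asarray(jack_vals, dtype=float)
        y = y[np.isfinite(y)]
        if y.size >= 3:
            d = y.mean() - y
            denom = (d**2).sum() ** 1.5
            if denom > 0:
                a = float((d**3).sum() / (6.0 * denom))
    zlo, zhi = norm.ppf(alpha / 2.0), norm.ppf(1.0 - alpha / 2.0)
    a1 = norm.cdf(z0 + (z0 + zlo) / (1.0 - a * (z0 + zlo)))
    a2 = norm.cdf(z0 + (z0 + zhi) / (1.0 - a * (z0 + zhi)))
    lo, hi = np.quantile(v, [a1, a2], method="linear")
    return float(lo), float(hi)


def jackknife_estimates(
    ds: IPDDataset,
    spec: ModelSpec,
    weights: WeightVector | None = None,
    scheme: Literal["JACKKNIFE_STUDY"] = "JACKKNIFE_STUDY",
    m: int = 1,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Leave-one-study-out point-estimate vectors (for BCa acceleration).

    Refits the full point-estimate path (weights recomputed on the retained
    studies, imputation re-run with a reserved seed stream) once per omitted
    study. A parameter that becomes inestimable without some study (its arm or
    covariate variation disappears) is NaN in that row; acceleration falls back
    to zero for such parameters.

    Returns ``(parameter_names, S x P matrix)``.

    Raises
    ------
    ValueError
        With fewer than 3 studies.
    """
    studies = ds.study_ids
    if len(studies) < 3:
        raise ValueError("study-level jackknife requires at least 3 studies")
    names = parameter_names(spec)
    out = np.full((len(studies), len(names)), np.nan)
    for s_i, omit in enumerate(studies):
        sub = ds.subset_studies([s for s in studies if s != omit])
        spec_r = detect_estimable_terms(sub)
        # restrict to terms estimable in BOTH the full spec and the retained data
        spec_r = ModelSpec(
            tuple(t for t in spec_r.eqA_terms if t in spec.eqA_terms),
            tuple(t for t in spec_r.eqB_terms if t in spec.eqB_terms),
            spec_r.dropped,
        )
        w_r = compute_weights(sub, "uniform" if weights is not None and weights.scheme == "uniform" else "inv_sqrt_n")
        ctx = _AnalysisContext(sub, spec_r, w_r)
        rng = np.random.default_rng([seed, _JACK_STREAM % (2**31), s_i])
        vec = ctx.evaluate(None, m, rng)
        for nm, val in zip(ctx.names, vec):
            out[s_i, names.index(nm)] = val
    return names, out


def run_bootstrap(
    ds: IPDDataset,
    spec: ModelSpec | None = None,
    config: BootstrapConfig = BootstrapConfig(),
    weights: WeightVector | None = None,
) -> BootstrapDistribution:
    """Full stratified bootstrap-then-impute run with BCa intervals.

    Replicate b draws all its randomness from a generator seeded by
    ``(config.seed, b)``; the original-sample estimate uses a reserved stream.
    Replicates whose imputation or fit fails numerically are discarded and
    counted; more than 10% discards aborts the run.
    """
    if spec is None:
        spec = detect_estimable_terms(ds)
    if weights is None:
        weights = compute_weights(ds, config.weight_scheme)
    ctx = _AnalysisContext(ds, spec, weights)

    theta_rng = np.random.default_rng([config.seed, _THETA_STREAM])
    theta_hat = ctx.evaluate(None, config.m, theta_rng)

    def _one(b: int) -> np.ndarray | None:
        rng = np.random.default_rng([config.seed, b])
        idx = ctx.resample_indices(rng)
        try:
            return ctx.evaluate(idx, config.m, rng)
        except np.linalg.LinAlgError:
            return None

    if config.n_jobs > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=config.n_jobs)(delayed(_one)(b) for b in range(config.B))
    else:
        results = [_one(b) for b in range(config.B)]
    kept = [r for r in results if r is not None]
    n_discarded = config.B - len(kept)
    if n_discarded > 0.1 * config.B:
        raise RuntimeError(
            f"{n_discarded}/{config.B} bootstrap replicates discarded; "
            "data too sparse for stable imputation/fitting"
        )
    est = np.asarray(kept)

    jack = None
    if config.acceleration_scheme == "JACKKNIFE_STUDY":
        _, jack = jackknife_estimates(ds, spec, weights, m=config.m, seed=config.seed)

    P = est.shape[1]
    z0 = np.empty(P)
    accel = np.zeros(P)
    intervals = np.empty((P, 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clamp/degenerate warnings summarized by caller
        for j in range(P):
            jv = jack[:, j] if jack is not None else None
            lo, hi = bca_interval(est[:, j], float(theta_hat[j]), jv, config.alpha)
            intervals[j] = (lo, hi)
            p = (np.count_nonzero(est[:, j] < theta_hat[j])
                 + 0.5 * np.count_nonzero(est[:, j] == theta_hat[j])) / est.shape[0]
            p = min(max(p, 1.0 / (2 * est.shape[0])), 1.0 - 1.0 / (2 * est.shape[0]))
            z0[j] = norm.ppf(p)
            if jv is not None:
                y = jv[np.isfinite(jv)]
                if y.size >= 3:
                    d = y.mean() - y
                    denom = (d**2).sum() ** 1.5
                    if denom > 0:
                        accel[j] = (d**3).sum() / (6.0 * denom)
    return BootstrapDistribution(
        names=ctx.names,
        estimates=est,
        theta_hat=theta_hat,
        z0=z0,
        accel=accel,
        intervals=intervals,
        alpha=config.alpha,
        n_discarded=n_discarded,
        config=config,
        jackknife=jack,
    )
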