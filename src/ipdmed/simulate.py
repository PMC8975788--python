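"""Synthetic multi-study trial data with known mediation paths and MAR missingness.

The generator emulates the structure the pooled analysis assumes: ~10 randomized
trials with unbalanced arm availability (most studies evaluate one intervention format
against control), study-specific demographic composition (including all-female and
all-first-year studies), a bivariate-normal baseline (mediator, outcome) pair with
study-specific means, post-baseline scores generated from the two mediation equations
with known coefficients, and participant-level missing-at-random masking concentrated
in the baseline mediator. Truth (every path, the per-arm indirect and total effects)
is returned alongside the data, so estimator bias, interval coverage, and the value of
imputation can all be measured directly.

Between-study heterogeneity (random intercept or treatment-slope shifts) is available
as a stress dial but defaults to zero: the default conditions are the ones under which
the pooled fixed-effect model is correctly specified.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .data_model import Arm, IPDDataset, TX_TERMS

__all__ = [
    "StudyDesign",
    "SimulationDesign",
    "SyntheticTruth",
    "generate_multistudy",
    "apply_mar_missingness",
    "preset_integrate_like",
]

_MASKABLE = ("bl_mediator", "post_mediator", "bl_outcome", "post_outcome",
             "male", "firstyr", "nonwhite")


@dataclass
class StudyDesign:
    """One study's layout: arm sizes, demographic counts, baselines, missingness.

    Demographic composition and missingness are given as counts out of the study
    n (so an all-female study is ``female_n == n``); generation converts them to
    per-participant probabilities. ``missing_n`` maps variable name -> expected
    number of missing entries.
    """

    study_id: str
    arm_n: dict[Arm, int]
    female_n: int
    firstyr_n: int
    nonwhite_n: int
    bl_mediator_mean: float
    bl_mediator_sd: float
    bl_outcome_mean: float
    bl_outcome_sd: float
    missing_n: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return sum(self.arm_n.values())


@dataclass
class SimulationDesign:
    """Full multi-study design: layout plus generating coefficients.

    ``eqA_coef``/``eqB_coef`` are the true coefficients of the mediator and
    outcome equations on the raw score scale. ``tau_*`` set the SD of
    study-specific shifts (intercepts, or treatment slopes) — zero by default.
    ``baseline_corr`` is the within-study correlation of the baseline mediator
    and outcome. ``mar_slope`` is the logistic coefficient of the (centered)
    baseline outcome in the missingness model, making masking MAR rather than
    MCAR; per-variable marginal rates are hit by solving for the logistic
    intercept numerically.
    """

    studies: list[StudyDesign]
    eqA_coef: dict[str, float]
    eqB_coef: dict[str, float]
    resid_sd_A: float
    resid_sd_B: float
    tau_intercept_A: float = 0.0
    tau_intercept_B: float = 0.0
    tau_tx_A: float = 0.0
    tau_tx_B: float = 0.0
    baseline_corr: float = -0.35
    mar_slope: float = 0.3
    seed: int = 0

    def validate_design(self) -> None:
        if not self.studies:
            raise ValueError("design has no studies")
        for sd in self.studies:
            if any(v < 0 for v in sd.arm_n.values()):
                raise ValueError(f"study {sd.study_id}: negative arm size")
            if sd.bl_mediator_sd <= 0 or sd.bl_outcome_sd <= 0:
                raise ValueError(f"study {sd.study_id}: baseline SDs must be positive")
            for v, cnt in sd.missing_n.items():
                if v not in _MASKABLE or not (0 <= cnt < max(sd.n, 1)):
                    raise ValueError(f"study {sd.study_id}: bad missingness entry {v}={cnt}")
        if self.resid_sd_A < 0 or self.resid_sd_B < 0:
            # zero is allowed: the noiseless limit is a useful identification check
            raise ValueError("residual SDs must be nonnegative")
        if not (-1 < self.baseline_corr < 1):
            raise ValueError("baseline correlation must be in (-1, 1)")


@dataclass
class SyntheticTruth:
    """The generating effect values, per arm, with identity total = direct + indirect."""

    a: dict[Arm, float]
    direct: dict[Arm, float]
    b_med: float
    indirect: dict[Arm, float]
    total: dict[Arm, float]
    study_effects: dict[str, dict[str, float]]


def _substream(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng([seed, k])


def generate_multistudy(
    design: SimulationDesign, seed: int | None = None
) -> tuple[IPDDataset, SyntheticTruth]:
    """Draw one complete multi-study dataset from the design (no missingness yet).

    All randomness flows from a single seed through named substreams
    (demographics, baselines, study effects, residual errors), so datasets are
    reproducible and masking can be applied separately.
    """
    design.validate_design()
    seed = design.seed if seed is None else seed
    rng_demo = _substream(seed, 0)
    rng_base = _substream(seed, 1)
    rng_study = _substream(seed, 2)
    rng_err = _substream(seed, 3)

    cA, cB = design.eqA_coef, design.eqB_coef
    frames = []
    study_effects: dict[str, dict[str, float]] = {}
    for sd in design.studies:
        n = sd.n
        if n == 0:
            continue
        u = {
            "uA": design.tau_intercept_A * rng_study.standard_normal(),
            "uB": design.tau_intercept_B * rng_study.standard_normal(),
        }
        for t in TX_TERMS:
            u[f"uA_{t}"] = design.tau_tx_A * rng_study.standard_normal()
            u[f"uB_{t}"] = design.tau_tx_B * rng_study.standard_normal()
        study_effects[sd.study_id] = u

        arms = np.concatenate([np.repeat(a.value, k) for a, k in sd.arm_n.items()])
        male = (rng_demo.random(n) < 1.0 - sd.female_n / n).astype(float)
        firstyr = (rng_demo.random(n) < sd.firstyr_n / n).astype(float)
        nonwhite = (rng_demo.random(n) < sd.nonwhite_n / n).astype(float)

        cov = design.baseline_corr * sd.bl_mediator_sd * sd.bl_outcome_sd
        L = np.linalg.cholesky(
            [[sd.bl_mediator_sd**2, cov], [cov, sd.bl_outcome_sd**2]]
        )
        z = rng_base.standard_normal((n, 2)) @ L.T
        bl_med = sd.bl_mediator_mean + z[:, 0]
        bl_out = sd.bl_outcome_mean + z[:, 1]

        tx = {t: (arms == t.removeprefix("TX_")).astype(float) for t in TX_TERMS}
        lpA = (
            cA["intercept"] + u["uA"]
            + sum((cA[t] + u[f"uA_{t}"]) * tx[t] for t in TX_TERMS)
            + cA["BL_ALCPROB"] * bl_out + cA["BL_PBS"] * bl_med
            + cA["MALE"] * male + cA["FIRSTYR"] * firstyr + cA["NONWHITE"] * nonwhite
        )
        post_med = lpA + design.resid_sd_A * rng_err.standard_normal(n)
        lpB = (
            cB["intercept"] + u["uB"]
            + sum((cB[t] + u[f"uB_{t}"]) * tx[t] for t in TX_TERMS)
            + cB["BL_ALCPROB"] * bl_out + cB["BL_PBS"] * bl_med
            + cB["POST_PBS"] * post_med
            + cB["MALE"] * male + cB["FIRSTYR"] * firstyr + cB["NONWHITE"] * nonwhite
        )
        post_out = lpB + design.resid_sd_B * rng_err.standard_normal(n)

        frames.append(pd.DataFrame({
            "study": sd.study_id,
            "arm": [Arm(a) for a in arms],
            "bl_mediator": bl_med,
            "post_mediator": post_med,
            "bl_outcome": bl_out,
            "post_outcome": post_out,
            "male": male,
            "firstyr": firstyr,
            "nonwhite": nonwhite,
        }))
    ds = IPDDataset(pd.concat(frames, ignore_index=True))

    b_med = cB["POST_PBS"]
    a = {Arm[t.removeprefix("TX_")]: cA[t] for t in TX_TERMS}
    direct = {Arm[t.removeprefix("TX_")]: cB[t] for t in TX_TERMS}
    indirect = {k: a[k] * b_med for k in a}
    total = {k: direct[k] + indirect[k] for k in a}
    truth = SyntheticTruth(a=a, direct=direct, b_med=b_med, indirect=indirect,
                           total=total, study_effects=study_effects)
    return ds, truth


def _solve_logit_intercept(rate: float, offset: np.ndarray) -> float:
    """Intercept alpha with mean(expit(alpha + offset)) == rate."""
    if np.allclose(offset, 0.0):
        return float(np.log(rate / (1.0 - rate)))
    return float(brentq(lambda al: expit(al + offset).mean() - rate, -30.0, 30.0))


def apply_mar_missingness(
    ds: IPDDataset,
    design: SimulationDesign,
    rng: np.random.Generator | int | None = None,
) -> IPDDataset:
    """Mask cells missing-at-random, hitting each study's target rates on average.

    For each study and maskable variable with a nonzero target, a participant's
    masking probability follows a logistic model with slope ``design.mar_slope``
    on the centered baseline outcome (zero slope for the baseline outcome's own
    tiny missingness, so the mechanism conditions only on effectively complete
    quantities); the intercept is solved numerically so the marginal rate equals
    the target. Study and arm are never masked.
    """
    if not isinstance(rng, np.random.Generator):
        rng = _substream(design.seed if rng is None else rng, 4)
    df = ds.df.copy()
    for sd in design.studies:
        rows = np.nonzero((df["study"] == sd.study_id).to_numpy())[0]
        if rows.size == 0:
            continue
        bl_out = df["bl_outcome"].to_numpy()[rows]
        centered = bl_out - np.nanmean(bl_out)
        centered = np.nan_to_num(centered)
        for var, cnt in sd.missing_n.items():
            rate = cnt / sd.n
            if rate <= 0:
                continue
            slope = 0.0 if var == "bl_outcome" else design.mar_slope
            alpha = _solve_logit_intercept(rate, slope * centered)
            p = expit(alpha + slope * centered)
            hit = rows[rng.random(rows.size) < p]
            df.iloc[hit, df.columns.get_loc(var)] = np.nan
    return IPDDataset(df)


def preset_integrate_like() -> SimulationDesign:
    """A packaged 10-study design emulating a pooled brief-intervention synthesis.

    Layout: 3691 participants across ten randomized trials with the arm sizes,
    demographic composition, baseline score distributions, and participant-level
    missingness pattern of a real college-drinking synthesis (one all-female
    study, three all-first-year studies, baseline-mediator missingness of 12-36%
    in most studies, near-complete outcomes). Generating effects are plausible
    and small: the stand-alone feedback arm improves the mediator by ~0.07 SD and
    a one-SD mediator increase reduces the outcome by ~0.22 SD, so the true
    indirect effect is about -0.015 SD.
    """
    # per study: (id, {arm: n}, female, firstyr, nonwhite,
    #             bl_med mean/sd, bl_out mean/sd, missing counts)
    C, M, P, G = Arm.CONTROL, Arm.MIPF, Arm.PF, Arm.GMI
    rows = [
        ("2", {C: 74, P: 70}, 44, 85, 40, (0.9, 0.8), (-0.5, 0.7),
         {"bl_mediator": 18}),
        ("8a", {C: 429, P: 398}, 576, 386, 103, (0.5, 0.8), (0.1, 0.9),
         {"bl_mediator": 206, "post_mediator": 12, "bl_outcome": 3,
          "nonwhite": 11, "firstyr": 6}),
        ("8b", {C: 585, P: 544}, 688, 532, 369, (0.5, 0.9), (0.2, 1.0),
         {"bl_mediator": 258, "post_mediator": 25, "bl_outcome": 3,
          "nonwhite": 8, "firstyr": 5}),
        ("8c", {C: 131, P: 113}, 147, 91, 31, (0.4, 0.9), (0.1, 0.9),
         {"bl_mediator": 40, "post_mediator": 1, "nonwhite": 3, "firstyr": 1}),
        ("9", {C: 78, M: 79, P: 77, G: 80}, 200, 314, 84, (0.4, 0.8), (0.9, 0.7),
         {"post_mediator": 6}),
        ("12", {C: 81, M: 76}, 83, 5, 11, (-0.4, 0.9), (0.4, 0.6),
         {"nonwhite": 3}),
        ("16", {C: 86, G: 97}, 183, 183, 63, (0.8, 1.2), (-0.1, 0.9),
         {"bl_mediator": 66, "post_mediator": 3, "nonwhite": 2}),
        ("18", {C: 67, P: 73}, 101, 41, 13, (0.5, 0.8), (0.1, 0.9),
         {"bl_mediator": 9, "post_mediator": 2, "post_outcome": 2,
          "male": 1, "firstyr": 1}),
        ("21", {C: 66, M: 68, P: 59}, 125, 78, 27, (0.3, 0.9), (0.9, 0.8),
         {"post_mediator": 2, "post_outcome": 2}),
        ("22", {C: 189, M: 171}, 207, 360, 30, (0.4, 0.8), (0.0, 0.9),
         {"bl_mediator": 72}),
    ]
    studies = [
        StudyDesign(
            study_id=sid, arm_n=arm_n, female_n=fem, firstyr_n=fy, nonwhite_n=nw,
            bl_mediator_mean=bm[0], bl_mediator_sd=bm[1],
            bl_outcome_mean=bo[0], bl_outcome_sd=bo[1], missing_n=miss,
        )
        for sid, arm_n, fem, fy, nw, bm, bo, miss in rows
    ]
    eqA = {
        "intercept": 0.10, "TX_MIPF": 0.03, "TX_PF": 0.063, "TX_GMI": 0.03,
        "BL_ALCPROB": -0.05, "BL_PBS": 0.60,
        "MALE": -0.10, "FIRSTYR": -0.05, "NONWHITE": 0.05,
    }
    eqB = {
        "intercept": 0.10, "TX_MIPF": -0.02, "TX_PF": 0.005, "TX_GMI": -0.03,
        "BL_ALCPROB": 0.60, "BL_PBS": 0.02, "POST_PBS": -0.22,
        "MALE": 0.05, "FIRSTYR": 0.02, "NONWHITE": -0.02,
    }
    return SimulationDesign(
        studies=studies,
        eqA_coef=eqA,
        eqB_coef=eqB,
        resid_sd_A=0.68,
        resid_sd_B=0.68,
        seed=20211112,
    )


def design_to_dict(design: SimulationDesign) -> dict:
    """Plain-dict form of a design (arms as strings), for YAML round trips."""
    d = asdict(design)
    for s in d["studies"]:
        s["arm_n"] = {a.value if isinstance(a, Arm) else str(a): n
                      for a, n in s["arm_n"].items()}
    return d


def design_from_dict(d: dict) -> SimulationDesign:
    studies = []
    for s in d["studies"]:
        s = dict(s)
        s["arm_n"] = {Arm(a): int(n) for a, n in s["arm_n"].items()}
        studies.append(StudyDesign(**s))
    rest = {k: v for k, v in d.items() if k != "studies"}
    return SimulationDesign(studies=studies, **rest)
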