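"""Participant-level data structures for pooled multi-study mediation analysis.

The analysis operates on a long-format table with one row per participant: a study
label, a randomized arm (control or one of three brief-intervention formats), mediator
and outcome scores at baseline and one post-baseline wave, and three binary demographic
covariates. Missing participant-level entries are carried as NaN; study identity and
arm are never missing. Rows are grouped into (study, arm) strata, which are both the
bootstrap resampling units and the bookkeeping device for arm availability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Arm",
    "VARIABLES",
    "MASKABLE",
    "TX_TERMS",
    "EQA_TERMS_FULL",
    "EQB_TERMS_FULL",
    "IPDDataset",
    "ModelSpec",
    "ValidationReport",
    "load_ipd",
    "build_strata",
    "detect_estimable_terms",
    "validate",
]


class Arm(str, Enum):
    """Randomized allocation: control or one of three brief-intervention formats.

    MIPF = individually delivered motivational interviewing with personalized
    feedback; PF = stand-alone personalized feedback; GMI = group motivational
    interviewing.
    """

    CONTROL = "CONTROL"
    MIPF = "MIPF"
    PF = "PF"
    GMI = "GMI"


#: canonical participant-level variable columns (besides study/arm)
VARIABLES = (
    "bl_mediator",
    "post_mediator",
    "bl_outcome",
    "post_outcome",
    "male",
    "firstyr",
    "nonwhite",
)

#: variables that may carry participant-level missingness
MASKABLE = VARIABLES

BINARY_VARIABLES = ("male", "firstyr", "nonwhite")

#: treatment dummy terms in fixed order (control is always the omitted reference)
TX_TERMS = ("TX_MIPF", "TX_PF", "TX_GMI")

_TERM_TO_ARM = {"TX_MIPF": Arm.MIPF, "TX_PF": Arm.PF, "TX_GMI": Arm.GMI}
_DEMO_TERMS = {"MALE": "male", "FIRSTYR": "firstyr", "NONWHITE": "nonwhite"}

#: full term sets of the two mediation equations (mediator equation A, outcome
#: equation B); sub-models use subsets of these.
EQA_TERMS_FULL = (
    "intercept",
    "TX_MIPF",
    "TX_PF",
    "TX_GMI",
    "BL_ALCPROB",
    "BL_PBS",
    "MALE",
    "FIRSTYR",
    "NONWHITE",
)
EQB_TERMS_FULL = EQA_TERMS_FULL[:6] + ("POST_PBS",) + EQA_TERMS_FULL[6:]

_ARM_ALIASES = {
    "CONTROL": Arm.CONTROL,
    "CTRL": Arm.CONTROL,
    "MIPF": Arm.MIPF,
    "MI+PF": Arm.MIPF,
    "MI_PF": Arm.MIPF,
    "PF": Arm.PF,
    "GMI": Arm.GMI,
}


@dataclass
class IPDDataset:
    """Pooled individual-participant-data table with stratum bookkeeping.

    Parameters
    ----------
    df
        One row per participant with columns ``study``, ``arm`` (an :class:`Arm`)
        and the seven score/covariate columns in :data:`VARIABLES`. Missing
        participant-level values are NaN. Row order is preserved from the source.
    """

    df: pd.DataFrame
    strata: dict[tuple[str, Arm], np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.strata:
            self.strata = build_strata(self)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def study_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.df["study"]:
            seen.setdefault(s)
        return list(seen)

    @property
    def study_sizes(self) -> dict[str, int]:
        return self.df.groupby("study", sort=False).size().to_dict()

    def arms_present(self, study_id: str | None = None) -> list[Arm]:
        sub = self.df if study_id is None else self.df[self.df["study"] == study_id]
        present = set(sub["arm"])
        return [a for a in Arm if a in present]

    def subset(self, rows: np.ndarray | Sequence[int]) -> "IPDDataset":
        """Row subset / resample by positional indices (strata rebuilt)."""
        return IPDDataset(self.df.iloc[np.asarray(rows)].reset_index(drop=True))

    def subset_studies(self, studies: Sequence[str]) -> "IPDDataset":
        keep = self.df["study"].isin(list(studies)).to_numpy()
        return IPDDataset(self.df.loc[keep].reset_index(drop=True))

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out["arm"] = [a.value for a in out["arm"]]
        out.to_csv(path, index=False, na_rep="")


@dataclass(frozen=True)
class ModelSpec:
    """Which regression terms are estimable for a given analysis scope.

    ``eqA_terms`` index the mediator equation, ``eqB_terms`` the outcome equation
    (always ``eqA_terms`` plus the post-baseline mediator). ``dropped`` records
    excluded terms with a reason: ``no-arm`` for intervention groups a study did
    not evaluate, ``no-variance`` for demographic covariates constant in scope.
    """

    eqA_terms: tuple[str, ...]
    eqB_terms: tuple[str, ...]
    dropped: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if "intercept" not in self.eqA_terms:
            raise ValueError("intercept must be present in eqA_terms")
        if "POST_PBS" not in self.eqB_terms:
            raise ValueError("POST_PBS must be present in eqB_terms")
        a_tx = {t for t in self.eqA_terms if t in TX_TERMS}
        b_tx = {t for t in self.eqB_terms if t in TX_TERMS}
        if a_tx != b_tx:
            raise ValueError("treatment terms must match between the two equations")

    @property
    def arms(self) -> tuple[Arm, ...]:
        return tuple(_TERM_TO_ARM[t] for t in TX_TERMS if t in self.eqA_terms)


def load_ipd(path, column_map: Mapping[str, str] | None = None) -> IPDDataset:
    """Read a long-format participant CSV into a validated :class:`IPDDataset`.

    The file is comma-separated UTF-8 with a header row; empty cells or ``NA``
    denote missing. ``column_map`` maps canonical names (``study``, ``arm``,
    :data:`VARIABLES`) to the file's column names; omitted entries default to the
    canonical name itself. Arm labels are matched case-insensitively against
    CONTROL/CTRL, MIPF/MI+PF, PF, GMI.

    Raises
    ------
    ValueError
        If a row has an unknown arm label or a missing study/arm cell (the error
        names the offending row), or a required column is absent.
    """
    colmap = {c: c for c in ("study", "arm", *VARIABLES)}
    if column_map:
        colmap.update(column_map)
    raw = pd.read_csv(path, na_values=["", "NA"], keep_default_na=False, dtype={colmap["study"]: str})
    missing_cols = [v for v in colmap.values() if v not in raw.columns]
    if missing_cols:
        raise ValueError(f"input file lacks required columns: {missing_cols}")
    df = pd.DataFrame({canon: raw[src] for canon, src in colmap.items()})

    for i, val in enumerate(df["study"]):
        if pd.isna(val) or str(val).strip() == "":
            raise ValueError(f"row {i}: missing study identifier")
    arms = []
    for i, val in enumerate(df["arm"]):
        if pd.isna(val):
            raise ValueError(f"row {i}: missing arm label")
        key = str(val).strip().upper()
        if key not in _ARM_ALIASES:
            raise ValueError(f"row {i}: unknown arm label {val!r}")
        arms.append(_ARM_ALIASES[key])
    df["arm"] = arms
    for v in VARIABLES:
        df[v] = pd.to_numeric(df[v], errors="raise").astype(float)
    return IPDDataset(df.reset_index(drop=True))


def build_strata(ds: IPDDataset) -> dict[tuple[str, Arm], np.ndarray]:
    """Partition row indices by (study, arm) — the bootstrap resampling strata.

    Returns a dict keyed by (study_id, arm) whose values are positional row-index
    arrays; every row belongs to exactly one stratum and sizes sum to ``ds.n``.
    """
    keys = pd.MultiIndex.from_arrays([ds.df["study"], ds.df["arm"]])
    strata: dict[tuple[str, Arm], np.ndarray] = {}
    order = np.arange(len(ds.df))
    for (study, arm), idx in pd.Series(order, index=keys).groupby(level=[0, 1], sort=False):
        strata[(study, arm)] = idx.to_numpy()
    return strata


def detect_estimable_terms(ds: IPDDataset, scope: str | None = None) -> ModelSpec:
    """Determine the estimable regression terms for a study or the pooled sample.

    A treatment dummy is retained iff that arm occurs within scope; a demographic
    covariate is retained iff its observed values vary (at least two observed
    participants with nonzero variance). Baseline mediator/outcome, the intercept,
    and (in the outcome equation) the post-baseline mediator are always retained.
    Arms a study did not evaluate, and covariates without variation, are
    study-level missing by design and are excluded rather than imputed.

    Parameters
    ----------
    scope
        A study identifier, or None for the full pooled sample.

    Raises
    ------
    ValueError
        If the scope selects no rows or contains no control arm (no reference
        group to contrast against).
    """
    sub = ds.df if scope is None else ds.df[ds.df["study"] == scope]
    if len(sub) == 0:
        raise ValueError(f"scope {scope!r} selects no records")
    arms = set(sub["arm"])
    if Arm.CONTROL not in arms:
        raise ValueError(f"scope {scope!r} has no control arm (no reference group)")

    dropped: list[tuple[str, str]] = []
    eqA: list[str] = ["intercept"]
    for t in TX_TERMS:
        if _TERM_TO_ARM[t] in arms:
            eqA.append(t)
        else:
            dropped.append((t, "no-arm"))
    eqA += ["BL_ALCPROB", "BL_PBS"]
    for term, col in _DEMO_TERMS.items():
        obs = sub[col].dropna()
        if len(obs) >= 2 and obs.nunique() > 1:
            eqA.append(term)
        else:
            dropped.append((term, "no-variance"))
    eqA_ordered = tuple(t for t in EQA_TERMS_FULL if t in eqA)
    eqB_ordered = tuple(t for t in EQB_TERMS_FULL if t in eqA or t == "POST_PBS")
    return ModelSpec(eqA_ordered, eqB_ordered, tuple(dropped))


@dataclass
class ValidationReport:
    """Per-study bookkeeping: sizes, arm availability, and missingness rates."""

    n_total: int
    study_counts: dict[str, int]
    arm_counts: dict[str, dict[str, int]]
    missing_counts: dict[str, dict[str, int]]
    missing_rates: dict[str, dict[str, float]]
    overall_missing_counts: dict[str, int]
    overall_missing_rates: dict[str, float]
    problems: list[str]

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.__dict__, indent=indent)

    def to_text(self) -> str:
        lines = [f"records: {self.n_total}", "per-study counts:"]
        for s, n in self.study_counts.items():
            arms = ", ".join(f"{a}={c}" for a, c in self.arm_counts[s].items())
            lines.append(f"  study {s}: n={n} ({arms})")
        lines.append("overall missingness:")
        for v in MASKABLE:
            lines.append(
                f"  {v}: {self.overall_missing_counts[v]} ({100 * self.overall_missing_rates[v]:.1f}%)"
            )
        if self.problems:
            lines.append("problems:")
            lines += [f"  - {p}" for p in self.problems]
        return "\n".join(lines)


def validate(ds: IPDDataset) -> ValidationReport:
    """Summarize the dataset and flag structural problems (without raising)."""
    df = ds.df
    study_counts = {s: int(n) for s, n in df.groupby("study", sort=False).size().items()}
    arm_counts = {
        s: {a.value: int((sub["arm"] == a).sum()) for a in Arm if (sub["arm"] == a).any()}
        for s, sub in df.groupby("study", sort=False)
    }
    missing_counts, missing_rates = {}, {}
    for s, sub in df.groupby("study", sort=False):
        missing_counts[s] = {v: int(sub[v].isna().sum()) for v in MASKABLE}
        missing_rates[s] = {v: float(sub[v].isna().mean()) for v in MASKABLE}
    overall_counts = {v: int(df[v].isna().sum()) for v in MASKABLE}
    overall_rates = {v: float(df[v].isna().mean()) for v in MASKABLE}

    problems = []
    for s in study_counts:
        if Arm.CONTROL.value not in arm_counts[s]:
            problems.append(f"study {s} has no control arm")
        for v in ("post_outcome", "post_mediator"):
            if missing_rates[s][v] >= 1.0:
                problems.append(f"study {s}: {v} entirely missing")
    return ValidationReport(
        n_total=len(df),
        study_counts=study_counts,
        arm_counts=arm_counts,
        missing_counts=missing_counts,
        missing_rates=missing_rates,
        overall_missing_counts=overall_counts,
        overall_missing_rates=overall_rates,
        problems=problems,
    )
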