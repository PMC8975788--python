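"""Study-specific sub-models, leave-one-study-out sensitivity, and forest reporting.

Each study gets its own reduced mediation model containing only the terms estimable
within it: arms the study actually evaluated and demographic covariates that vary among
its participants (a study enrolling only first-year students contributes no first-year
coefficient). Sub-model inference bootstraps within the study's own (study, arm)
strata with uniform weights — the inverse-root-size weighting is a between-study
device. The leave-one-study-out (LOSO) analysis repeats the full pooled pipeline once
per omitted study, recomputing weights on the retained studies, to check that no single
trial drives the pooled conclusions. The forest table lines up per-study and pooled
indirect/total effects (standardized with respect to the outcome) for display.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bootstrap import BootstrapConfig, BootstrapDistribution, run_bootstrap
from .data_model import IPDDataset, ModelSpec, detect_estimable_terms
from .mediation import compute_weights

__all__ = ["StudyResult", "LosoResult", "ForestTable", "fit_study_submodel",
           "leave_one_study_out", "forest_table"]


@dataclass
class StudyResult:
    """A study's reduced mediation model with bootstrap intervals."""

    study_id: str
    spec: ModelSpec
    n: int
    boot: BootstrapDistribution

    def effect_table(self) -> pd.DataFrame:
        """Standardized indirect and total effects for arms evaluated in this study."""
        rows = []
        for arm in self.spec.arms:
            for eff in ("indirect", "total"):
                rec = self.boot[f"std_{eff}_{arm.value}"]
                rows.append({"study": self.study_id, "arm": arm.value, "effect": eff,
                             "n": self.n, **rec})
        return pd.DataFrame(rows)


def fit_study_submodel(ds: IPDDataset, study_id: str, config: BootstrapConfig) -> StudyResult:
    """Fit one study's reduced sub-model with a within-study stratified bootstrap.

    Terms a study cannot estimate (absent arms, constant covariates) are excluded
    rather than imputed: they are missing by design at the study level. Weights
    are uniform within a single study; acceleration is unavailable (a one-study
    jackknife is undefined), so the bias-corrected interval is used.
    """
    if study_id not in ds.study_ids:
        raise ValueError(f"study {study_id!r} not in dataset")
    sub = ds.subset_studies([study_id])
    spec = detect_estimable_terms(sub)
    weights = compute_weights(sub, "uniform")
    cfg = replace(config, acceleration_scheme="NONE")
    boot = run_bootstrap(sub, spec, cfg, weights)
    return StudyResult(study_id=study_id, spec=spec, n=sub.n, boot=boot)


@dataclass
class LosoResult:
    """Leave-one-study-out re-analyses of the pooled model.

    ``results`` maps omitted study -> the full pooled bootstrap without it;
    ``summary`` reports the range of each standardized effect across omissions.
    """

    results: dict[str, BootstrapDistribution]
    summary: pd.DataFrame


def leave_one_study_out(ds: IPDDataset, config: BootstrapConfig) -> LosoResult:
    """Repeat the full pooled analysis once per omitted study.

    Weights and the estimable term set are recomputed on the retained studies
    (omitting the only study evaluating an arm removes that arm's effects from
    that re-analysis). Each omission uses the base seed offset by the omitted
    study's index, so individual re-analyses are reproducible in isolation.
    """
    studies = ds.study_ids
    if len(studies) < 3:
        raise ValueError("leave-one-study-out requires at least 3 studies")
    results: dict[str, BootstrapDistribution] = {}
    for s_i, omit in enumerate(studies):
        sub = ds.subset_studies([s for s in studies if s != omit])
        spec = detect_estimable_terms(sub)
        scheme = config.acceleration_scheme if len(studies) - 1 >= 3 else "NONE"
        cfg = replace(config, seed=config.seed + s_i + 1, acceleration_scheme=scheme)
        results[omit] = run_bootstrap(sub, spec, cfg)

    rows = []
    effect_names = sorted(
        {n for b in results.values() for n in b.names
         if n.startswith(("std_indirect_", "std_total_"))}
    )
    for name in effect_names:
        vals = [b[name]["estimate"] for b in results.values() if name in b.names]
        rows.append({"parameter": name, "n_omissions": len(vals),
                     "min": min(vals), "max": max(vals), "range": max(vals) - min(vals)})
    return LosoResult(results=results, summary=pd.DataFrame(rows))


@dataclass
class ForestTable:
    """Per-study and pooled indirect/total effects, ready for display."""

    rows: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.4f")

    @staticmethod
    def from_tsv(path) -> "ForestTable":
        return ForestTable(pd.read_csv(path, sep="\t", dtype={"study": str}))

    def plot(self, path=None):
        """Forest plot: one marker + interval per row, pooled rows at the bottom."""
        import matplotlib.pyplot as plt

        df = self.rows.iloc[::-1].reset_index(drop=True)
        fig, ax = plt.subplots(figsize=(7, 0.35 * len(df) + 1.5))
        y = np.arange(len(df))
        colors = {"MIPF": "tab:green", "PF": "tab:blue", "GMI": "tab:red"}
        for i, r in df.iterrows():
            ax.errorbar(
                r["estimate"], y[i],
                xerr=[[r["estimate"] - r["lo"]], [r["hi"] - r["estimate"]]],
                fmt="s" if r["study"] == "overall" else "o",
                color=colors.get(r["arm"], "k"), markersize=5, capsize=2,
            )
        ax.axvline(0.0, color="0.6", lw=0.8, ls="--")
        ax.set_yticks(y)
        ax.set_yticklabels(
            [f"{r['study']} {r['arm']} {r['effect']}" for _, r in df.iterrows()], fontsize=8
        )
        ax.set_xlabel("standardized effect on post-baseline outcome")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def forest_table(
    overall: BootstrapDistribution | None,
    study_results: list[StudyResult] = (),
) -> ForestTable:
    """Assemble the forest table: per-study rows first, pooled rows last.

    Ordering follows the display convention: for each study, indirect then total
    per evaluated arm; then the pooled-model rows labeled ``overall``.
    """
    frames = [r.effect_table() for r in study_results]
    if overall is not None:
        rows = []
        for name in overall.names:
            for eff in ("indirect", "total"):
                prefix = f"std_{eff}_"
                if name.startswith(prefix):
                    rows.append({"study": "overall", "arm": name.removeprefix(prefix),
                                 "effect": eff, "n": None, **overall[name]})
        frames.append(pd.DataFrame(rows))
    if not frames:
        raise ValueError("nothing to tabulate")
    cols = ["study", "arm", "effect", "n", "estimate", "original", "lo", "hi"]
    return ForestTable(pd.concat(frames, ignore_index=True)[cols])
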