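"""The 2 x 2 x 8 x 3 analysis multiverse and its robustness summaries.

Ninety-six pipeline variants arise from crossing ROI creation (PROB, COG),
temporal filtering (HP, BP), eight nuisance-regression combinations of
{WM, CSF, NS}, and three connectivity metrics (FULL, PARTIAL, REGPARTIAL).
Robustness of each horn-to-horn index is summarized as sign counts,
FWE-significance counts and factor attributions, and two joint tests use
all 96 analyses at once: the average-across-analyses sign-flip test and
non-parametric combination with Fisher's function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .connectivity import INDICES, MetricSpec, group_average
from .inference import (_flip_matrix, fwe_family, npc_fisher_family,
                        percent_positive)
from .preprocess import run_pipeline

ROI_LEVELS = ("PROB", "COG")
FILTER_LEVELS = ("HP", "BP")
# the eight nuisance-regression combinations, in canonical report order
NUISANCE_SETS = ((), ("WM",), ("WM", "CSF"), ("WM", "NS"),
                 ("WM", "CSF", "NS"), ("CSF",), ("CSF", "NS"), ("NS",))
METRIC_LEVELS = ("FULL", "PARTIAL", "REGPARTIAL")


@dataclass(frozen=True)
class PipelineConfig:
    """One cell of the analysis multiverse."""

    roi: str = "PROB"
    filt: str = "HP"
    nuisance: tuple = ()
    metric: str = "FULL"
    lam: float = 5.0

    def __post_init__(self):
        if self.roi not in ROI_LEVELS or self.filt not in FILTER_LEVELS \
                or self.metric not in METRIC_LEVELS:
            raise ValueError(f"invalid pipeline {self}")
        if tuple(self.nuisance) not in NUISANCE_SETS:
            raise ValueError(f"invalid nuisance set {self.nuisance}")

    @property
    def pipeline_id(self) -> str:
        nuis_tag = "+".join(self.nuisance) if self.nuisance else "none"
        return f"{self.roi}-{self.filt}-{nuis_tag}-{self.metric}"

    def metric_spec(self) -> MetricSpec:
        return MetricSpec(metric=self.metric, lam=self.lam)


def enumerate_pipelines(lam: float = 5.0) -> list:
    """The full 96-pipeline Cartesian product, in deterministic order."""
    return [PipelineConfig(roi=r, filt=f, nuisance=n, metric=m, lam=lam)
            for r, f, n, m in product(ROI_LEVELS, FILTER_LEVELS,
                                      NUISANCE_SETS, METRIC_LEVELS)]


@dataclass
class MultiverseResult:
    """Per-subject indices, group means and inference for all pipelines."""

    table: pd.DataFrame        # rows: subject x pipeline; cols: indices
    group: pd.DataFrame        # rows: pipeline; group means per index
    inference: pd.DataFrame    # rows: pipeline x index; t, p, p_fwe
    n_subjects: int
    seed: object = None
    pipelines: list = field(default_factory=list)


def run_multiverse(assets_list, n_flips: int = 10000, seed=None,
                   lam: float = 5.0, alpha: float = 0.05) -> MultiverseResult:
    """Execute all 96 pipelines on a prepared cohort and test each one.

    Per pipeline, group inference on the four indices uses synchronized
    sign flips shared across all pipelines (FWE over the four indices
    within each pipeline).
    """
    pipelines = enumerate_pipelines(lam=lam)
    n = len(assets_list)
    rows = []
    for pipe in pipelines:
        for assets in assets_list:
            try:
                cs = run_pipeline(assets, roi=pipe.roi, filt=pipe.filt,
                                  nuisance_set=pipe.nuisance,
                                  metric=pipe.metric_spec())
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline {pipe.pipeline_id} failed on subject "
                    f"{assets.subject!r}: {exc}") from exc
            rows.append({"subject": assets.subject,
                         "pipeline": pipe.pipeline_id, "roi": pipe.roi,
                         "filter": pipe.filt,
                         "nuisance": "+".join(pipe.nuisance) or "none",
                         "metric": pipe.metric,
                         "DD": cs.r_dd, "VV": cs.r_vv, "W": cs.r_w,
                         "B": cs.r_b})
    table = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    flips, _ = _flip_matrix(n, n_flips, rng)
    group_rows, inf_rows = [], []
    for pipe in pipelines:
        sub = table[table["pipeline"] == pipe.pipeline_id]
        values = sub[list(INDICES)].to_numpy()
        results = fwe_family(values, n_flips=n_flips, seed=seed, flips=flips)
        grow = {"pipeline": pipe.pipeline_id, "roi": pipe.roi,
                "filter": pipe.filt,
                "nuisance": "+".join(pipe.nuisance) or "none",
                "metric": pipe.metric}
        for j, idx in enumerate(INDICES):
            grow[idx] = group_average(values[:, j])
            grow[f"{idx}_pct_positive"] = percent_positive(values[:, j])
            inf_rows.append({"pipeline": pipe.pipeline_id, "index": idx,
                             "t": results[j].stat,
                             "p_uncorrected": results[j].p_uncorrected,
                             "p_fwe": results[j].p_fwe,
                             "significant": results[j].p_fwe <= alpha})
        group_rows.append(grow)
    return MultiverseResult(table=table, group=pd.DataFrame(group_rows),
                            inference=pd.DataFrame(inf_rows), n_subjects=n,
                            seed=seed, pipelines=pipelines)


def robustness_summary(result: MultiverseResult) -> dict:
    """Sign counts, significance counts and factor attribution tables."""
    n_pipe = len(result.group)
    counts = {}
    for idx in INDICES:
        pos = int((result.group[idx] > 0).sum())
        sig = int(result.inference.query("index == @idx")["significant"].sum())
        counts[idx] = {"positive": pos, "negative": n_pipe - pos,
                       "significant": sig, "nonsignificant": n_pipe - sig}
    # factor attribution: significance cross-tabulated against each factor level
    merged = result.inference.merge(result.group[["pipeline", "roi", "filter",
                                                  "nuisance", "metric"]],
                                    on="pipeline")
    attribution = {}
    for idx in INDICES:
        sub = merged[merged["index"] == idx]
        tabs = {}
        for factor in ("roi", "filter", "nuisance", "metric"):
            tabs[factor] = pd.crosstab(sub[factor], sub["significant"])
        attribution[idx] = tabs
    return {"n_pipelines": n_pipe, "counts": counts, "attribution": attribution}


def joint_inference(result: MultiverseResult, n_flips: int = 10000,
                    seed=None) -> pd.DataFrame:
    """Average-across-analyses and NPC joint tests per index, FWE over the four.

    Both tests pool all pipelines: the first asks whether the per-subject
    average over the 96 analyses is nonzero, the second (NPC/Fisher)
    whether all 96 effects are zero.
    """
    per_index = {}
    for idx in INDICES:
        wide = result.table.pivot(index="subject", columns="pipeline",
                                  values=idx)
        per_index[idx] = wide.to_numpy()
    # averaged test with FWE over the four indices (shared flips)
    avg_mat = np.column_stack([per_index[idx].mean(axis=1) for idx in INDICES])
    avg_results = fwe_family(avg_mat, n_flips=n_flips, seed=seed)
    npc_results = npc_fisher_family(per_index, n_flips=n_flips, seed=seed)
    rows = []
    for j, idx in enumerate(INDICES):
        rows.append({"index": idx, "test": "average",
                     "stat": avg_results[j].stat,
                     "p_uncorrected": avg_results[j].p_uncorrected,
                     "p_fwe": avg_results[j].p_fwe})
        rows.append({"index": idx, "test": "npc_fisher",
                     "stat": npc_results[idx].stat,
                     "p_uncorrected": npc_results[idx].p_uncorrected,
                     "p_fwe": npc_results[idx].p_fwe})
    return pd.DataFrame(rows)
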