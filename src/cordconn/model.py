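"""Group-level horn-connectivity model with a statsmodels-like interface.

``HornConnectivityModel`` wraps per-subject horn-to-horn correlation
indices (however obtained: a direct pipeline run, a cohort on disk, or a
hand-built DataFrame); ``fit`` performs the sign-flip permutation inference
(one-sample tests with FWE over the four indices, plus the six paired
contrasts with FWE over six) and returns a results object carrying
estimates, their uncertainties and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .connectivity import INDICES, MetricSpec, group_average
from .inference import fwe_family, percent_positive


class HornConnectivityModel:
    """Group model for the four horn-to-horn connectivity indices.

    Parameters
    ----------
    data : DataFrame
        One row per subject, columns at least DD, VV, W, B (dimensionless
        correlation coefficients in [-1, 1]).
    """

    def __init__(self, data: pd.DataFrame):
        data = pd.DataFrame(data)
        missing = [c for c in INDICES if c not in data.columns]
        if missing:
            raise ValueError(f"missing index columns: {missing}")
        if len(data) < 2:
            raise ValueError("need at least two subjects")
        self.data = data.reset_index(drop=True)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_correlation_sets(cls, corr_sets, subjects=None) -> "HornConnectivityModel":
        rows = [cs.as_series() for cs in corr_sets]
        df = pd.DataFrame(rows)
        if subjects is not None:
            df.index = list(subjects)
        return cls(df)

    @classmethod
    def from_cohort(cls, cohort_dir, roi: str = "PROB", filt: str = "HP",
                    nuisance_set=(), metric: MetricSpec = MetricSpec(),
                    segment: str = None) -> "HornConnectivityModel":
        """Run one analysis pipeline over a cohort directory.

        ``segment`` restricts the horn masks to one spinal segment
        (C6/C7/C8/T1); None uses the whole cord.
        """
        from .images import AtlasBundle
        from .masks import (build_cog_horn_masks, build_prob_horn_masks,
                            build_segment_masks)
        from .preprocess import prepare_subject, run_pipeline
        from .synthetic import load_cohort
        import yaml
        from pathlib import Path

        cohort_dir = Path(cohort_dir)
        atlas = AtlasBundle.load(cohort_dir / "atlas")
        manifest = yaml.safe_load((cohort_dir / "manifest.yaml").read_text())
        task_times = manifest.get("task_times_s")
        prob = build_prob_horn_masks(atlas.gm)
        cog = build_cog_horn_masks(prob)
        segment_slices = None
        if segment is not None:
            segs = build_segment_masks(atlas.segments)
            seg_mask = segs[segment]
            segment_slices = sorted(set(np.nonzero(seg_mask)[2].tolist()))
        corr_sets, subjects = [], []
        for sub, fmri, physio, _ in load_cohort(cohort_dir):
            assets = prepare_subject(fmri, physio, atlas, prob, cog,
                                     task_times=task_times, subject=sub)
            corr_sets.append(run_pipeline(assets, roi=roi, filt=filt,
                                          nuisance_set=nuisance_set,
                                          metric=metric,
                                          segment_slices=segment_slices))
            subjects.append(sub)
        return cls.from_correlation_sets(corr_sets, subjects)

    # -- estimation -------------------------------------------------------
    def fit(self, n_flips: int = 10000, seed=None,
            contrasts: bool = True) -> "HornConnectivityResults":
        values = self.data[list(INDICES)].to_numpy(dtype=float)
        results = fwe_family(values, n_flips=n_flips, seed=seed)
        params = pd.Series({idx: group_average(values[:, j])
                            for j, idx in enumerate(INDICES)})
        bse = pd.Series({idx: values[:, j].std(ddof=1) / np.sqrt(len(values))
                         for j, idx in enumerate(INDICES)})
        pct = pd.Series({idx: percent_positive(values[:, j])
                         for j, idx in enumerate(INDICES)})
        tvalues = pd.Series({idx: results[j].stat
                             for j, idx in enumerate(INDICES)})
        pvalues = pd.Series({idx: results[j].p_uncorrected
                             for j, idx in enumerate(INDICES)})
        pvalues_fwe = pd.Series({idx: results[j].p_fwe
                                 for j, idx in enumerate(INDICES)})
        contrast_df = None
        if contrasts:
            pairs = list(combinations(INDICES, 2))
            diffs = np.column_stack([values[:, INDICES.index(a)]
                                     - values[:, INDICES.index(b)]
                                     for a, b in pairs])
            cres = fwe_family(diffs, n_flips=n_flips, seed=seed)
            contrast_df = pd.DataFrame(
                [{"contrast": f"{a} - {b}",
                  "mean_diff": float(diffs[:, j].mean()),
                  "t": cres[j].stat,
                  "p_uncorrected": cres[j].p_uncorrected,
                  "p_fwe": cres[j].p_fwe}
                 for j, (a, b) in enumerate(pairs)]).set_index("contrast")
        return HornConnectivityResults(
            model=self, params=params, bse=bse, tvalues=tvalues,
            pvalues=pvalues, pvalues_fwe=pvalues_fwe,
            percent_positive=pct, contrasts=contrast_df,
            n_resamples=results[0].n_resamples, seed=seed,
            nobs=len(self.data))


@dataclass
class HornConnectivityResults:
    """Estimates, uncertainties and permutation p-values for the group."""

    model: HornConnectivityModel
    params: pd.Series          # group-mean r per index
    bse: pd.Series             # standard error of the mean
    tvalues: pd.Series
    pvalues: pd.Series         # two-tailed, uncorrected
    pvalues_fwe: pd.Series     # FWE over the four indices
    percent_positive: pd.Series
    contrasts: pd.DataFrame = None
    n_resamples: int = 0
    seed: object = None
    nobs: int = 0
    extra: dict = field(default_factory=dict)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Normal-approximation confidence interval for the group mean."""
        from scipy import stats
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.params - z * self.bse,
                             "upper": self.params + z * self.bse})

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean_r": self.params, "sem": self.bse,
                             "t": self.tvalues, "p": self.pvalues,
                             "p_fwe": self.pvalues_fwe,
                             "pct_positive": self.percent_positive})

    def summary(self) -> str:
        lines = [
            "Horn-to-horn resting-state connectivity (sign-flip inference)",
            f"No. subjects: {self.nobs}    resamples: {self.n_resamples}"
            f"    seed: {self.seed}",
            "",
            self.as_frame().to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        if self.contrasts is not None:
            lines += ["", "Paired contrasts (FWE over 6 tests):",
                      self.contrasts.to_string(
                          float_format=lambda v: f"{v: .4f}")]
        return "\n".join(lines)
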