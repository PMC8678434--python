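"""Statsmodels-style entry point: a model object built from diary data whose
``fit()`` runs the whole analysis and returns a results object.

The analysis chain is: derive per-day flare states from the flare petal ->
reconstruct flare episodes (one-missing-day bridge rule) and summarise
duration/frequency -> aggregate per-participant flare-on/off means and
difference features -> paired t-tests per variable (Table-1 analogue) ->
eligibility filter (>= min_days entry days, complete difference features) ->
min-max normalise to [-1, 1] -> affinity propagation at preference quantile
q -> between-cluster Welch contrasts of difference features, raw means,
baseline covariates and episode durations (Table-2/3/4 analogues).
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .apcluster import APConfig, APResult, cluster_feature_matrix
from .catalogue import CLUSTERING_VARIABLES, DEFAULT_CATALOGUE, PetalCatalogue, REPORT_VARIABLE_ORDER
from .data import BaselineRecord, ParticipantSeries, derive_flare_states
from .episodes import (
    EpisodeSummary,
    FlareEpisode,
    flare_frequency_interval,
    segment_episodes,
    summarize_episodes,
)
from .features import (
    FeatureRow,
    NormalizedFeatureMatrix,
    aggregate_flare_features,
    eligibility_filter,
    feature_frame,
    normalize_features,
)
from .io import read_baseline, read_daily_entries
from .stats import (
    WelchTestResult,
    build_table1,
    compare_cluster_baselines,
    compare_cluster_features,
    welch_t_test,
)


class FlareDiaryModel:
    """Flare-phenotype analysis of a daily symptom-diary cohort.

    Parameters
    ----------
    series : list of ParticipantSeries
        One date-ordered diary per participant.
    baseline : list of BaselineRecord, optional
        Baseline clinical covariates for cluster characterisation.
    flare_threshold : int
        Flare petal scores <= threshold count as flare-on (default 3, the
        scale midpoint; scores run 1 = least healthy to 5).
    min_days : int
        Minimum distinct entry days for clustering eligibility (default 10).
    clustering_variables : sequence of str
        Difference features fed to clustering (default: the 7 fixed symptom
        petals).
    ap_config : APConfig
        Affinity propagation settings (preference quantile q, damping, ...).
    normalization : {"minmax", "maxabs"}
        Column rescaling scheme for the difference features.
    frequency_method : {"span", "onset"}
        Flare-frequency definition (observation span / episode count, or
        mean onset-to-onset gap).
    alpha : float
        Significance convention for flagging paired-test rows (default 0.01).
    """

    def __init__(
        self,
        series: Sequence[ParticipantSeries],
        baseline: Sequence[BaselineRecord] | None = None,
        *,
        catalogue: PetalCatalogue = DEFAULT_CATALOGUE,
        flare_threshold: int = 3,
        min_days: int = 10,
        clustering_variables: Sequence[str] = CLUSTERING_VARIABLES,
        ap_config: APConfig = APConfig(),
        normalization: str = "minmax",
        frequency_method: str = "span",
        alpha: float = 0.01,
        ground_truth=None,
    ) -> None:
        self.series = list(series)
        self.baseline = list(baseline) if baseline is not None else None
        self.catalogue = catalogue
        self.flare_threshold = int(flare_threshold)
        self.min_days = int(min_days)
        self.clustering_variables = list(clustering_variables)
        self.ap_config = ap_config
        self.normalization = normalization
        self.frequency_method = frequency_method
        self.alpha = float(alpha)
        self.ground_truth = ground_truth
        unknown = [v for v in self.clustering_variables if v not in catalogue]
        if unknown:
            raise ValueError(f"clustering variables not in catalogue: {unknown}")

    # ------------------------------------------------------------------
    @classmethod
    def from_csv(
        cls, diary_path, baseline_path=None, *, catalogue=DEFAULT_CATALOGUE, **kwargs
    ) -> "FlareDiaryModel":
        series = read_daily_entries(diary_path, catalogue)
        baseline = read_baseline(baseline_path) if baseline_path else None
        return cls(series, baseline, catalogue=catalogue, **kwargs)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, baseline=None, *, catalogue=DEFAULT_CATALOGUE, **kwargs
    ) -> "FlareDiaryModel":
        from .io import frame_to_series

        return cls(frame_to_series(frame, catalogue), baseline, catalogue=catalogue, **kwargs)

    @classmethod
    def from_synthetic(cls, config=None, seed: int = 0, **kwargs) -> "FlareDiaryModel":
        from .simulate import SyntheticCohortConfig, generate_cohort

        config = config or SyntheticCohortConfig()
        series, baseline, truth = generate_cohort(config, seed=seed)
        return cls(series, baseline, ground_truth=truth, **kwargs)

    # ------------------------------------------------------------------
    def fit(self) -> "FlareAnalysisResults":
        log: list[dict] = []
        states = {
            s.participant_id: derive_flare_states(s, self.flare_threshold)
            for s in self.series
        }
        episodes = {
            s.participant_id: segment_episodes(s, states[s.participant_id])
            for s in self.series
        }
        series_by_pid = {s.participant_id: s for s in self.series}
        episode_summary = summarize_episodes(
            episodes, series_by_pid, frequency_method=self.frequency_method
        )
        rows = [
            aggregate_flare_features(s, states[s.participant_id], self.catalogue)
            for s in self.series
        ]
        table1 = build_table1(rows, REPORT_VARIABLE_ORDER, alpha=self.alpha)

        n_registered = len(self.series)
        n_with_flare = sum(1 for eps in episodes.values() if eps)
        eligible = eligibility_filter(rows, self.min_days)
        log.append(
            {
                "filter": f"min_days>={self.min_days}",
                "n_before": n_registered,
                "n_after": len(eligible),
            }
        )
        clusterable = eligibility_filter(
            eligible, 1, require_diff_variables=self.clustering_variables
        )
        log.append(
            {
                "filter": "complete difference features",
                "n_before": len(eligible),
                "n_after": len(clusterable),
            }
        )

        features = feature_frame(rows, self.clustering_variables)
        normalized: NormalizedFeatureMatrix | None = None
        ap_result: APResult | None = None
        labels: dict[str, int] = {}
        if len(clusterable) >= 2:
            diff_cols = [f"{v}_diff" for v in self.clustering_variables]
            diff_matrix = feature_frame(clusterable, self.clustering_variables)[diff_cols]
            normalized = normalize_features(diff_matrix, scheme=self.normalization)
            ap_result = cluster_feature_matrix(normalized.values, self.ap_config)
            labels = _group_labels(normalized.participant_ids, ap_result)
        else:
            warnings.warn(
                "fewer than 2 participants eligible for clustering; "
                "cluster tables will be empty",
                stacklevel=2,
            )

        table2 = table3 = table4 = None
        duration_comparison = None
        if labels and len(set(labels.values())) >= 2:
            table2, table3 = compare_cluster_features(
                clusterable, labels, REPORT_VARIABLE_ORDER
            )
            if self.baseline is not None:
                table4 = compare_cluster_baselines(self.baseline, labels)
            duration_comparison = _duration_contrast(episodes, labels)

        return FlareAnalysisResults(
            model=self,
            flare_states=states,
            episodes=episodes,
            episode_summary=episode_summary,
            feature_rows=rows,
            features=features,
            table1=table1,
            normalized=normalized,
            ap_result=ap_result,
            labels=labels,
            table2=table2,
            table3=table3,
            table4=table4,
            duration_comparison=duration_comparison,
            cohort_counts={
                "n_registered": n_registered,
                "n_with_flare": n_with_flare,
                "pct_with_flare": (
                    100.0 * n_with_flare / n_registered if n_registered else None
                ),
                "n_eligible_min_days": len(eligible),
                "n_clustered": len(labels),
            },
            filter_log=log,
        )


def _group_labels(participant_ids: list[str], ap: APResult) -> dict[str, int]:
    """Map exemplar-index labels to group ids 0, 1, ... ordered by
    descending cluster size (ties broken by exemplar index), so group 0 is
    the largest phenotype."""
    sizes = {e: int((ap.labels == e).sum()) for e in ap.exemplars}
    order = sorted(ap.exemplars, key=lambda e: (-sizes[e], e))
    remap = {e: g for g, e in enumerate(order)}
    return {pid: remap[int(lab)] for pid, lab in zip(participant_ids, ap.labels)}


def _duration_contrast(
    episodes: Mapping[str, Sequence[FlareEpisode]], labels: Mapping[str, int]
) -> WelchTestResult:
    """Welch contrast of per-participant mean episode durations between the
    two largest clusters."""
    per_pid = {
        pid: float(np.mean([e.duration_days for e in eps]))
        for pid, eps in episodes.items()
        if eps and pid in labels
    }
    g0 = [v for pid, v in per_pid.items() if labels[pid] == 0]
    g1 = [v for pid, v in per_pid.items() if labels[pid] == 1]
    return welch_t_test(g0, g1, "episode_duration")


@dataclass
class FlareAnalysisResults:
    """Fitted results: episode tables, paired-test report, cluster labels
    and between-cluster contrasts."""

    model: FlareDiaryModel
    flare_states: dict
    episodes: dict[str, list[FlareEpisode]]
    episode_summary: EpisodeSummary
    feature_rows: list[FeatureRow]
    features: pd.DataFrame
    table1: pd.DataFrame
    normalized: NormalizedFeatureMatrix | None
    ap_result: APResult | None
    labels: dict[str, int]
    table2: pd.DataFrame | None
    table3: pd.DataFrame | None
    table4: pd.DataFrame | None
    duration_comparison: WelchTestResult | None
    cohort_counts: dict
    filter_log: list[dict]

    # ------------------------------------------------------------------
    @property
    def n_clusters(self) -> int:
        return len(self.ap_result.exemplars) if self.ap_result else 0

    @property
    def cluster_sizes(self) -> list[int]:
        if not self.labels:
            return []
        counts: dict[int, int] = {}
        for g in self.labels.values():
            counts[g] = counts.get(g, 0) + 1
        return [counts[g] for g in sorted(counts)]

    def episode_table(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": pid,
                "start": e.start_date.isoformat(),
                "end": e.end_date.isoformat(),
                "duration_days": e.duration_days,
                "n_recorded_flare_days": e.n_recorded_flare_days,
                "bridged_gap_count": e.bridged_gap_count,
                "touches_boundary": e.touches_boundary,
            }
            for pid, eps in self.episodes.items()
            for e in eps
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "participant_id", "start", "end", "duration_days",
                "n_recorded_flare_days", "bridged_gap_count", "touches_boundary",
            ],
        )

    def labels_table(self) -> pd.DataFrame:
        if not self.labels or self.normalized is None or self.ap_result is None:
            return pd.DataFrame(columns=["participant_id", "cluster_id", "is_exemplar"])
        pids = self.normalized.participant_ids
        exemplar_pids = {pids[e] for e in self.ap_result.exemplars}
        return pd.DataFrame(
            {
                "participant_id": pids,
                "cluster_id": [self.labels[p] for p in pids],
                "is_exemplar": [p in exemplar_pids for p in pids],
            }
        )

    def adjusted_rand(self) -> float | None:
        """Adjusted Rand index of the recovered clusters against the
        generator's true labels (synthetic cohorts only)."""
        if self.model.ground_truth is None or not self.labels:
            return None
        from sklearn.metrics import adjusted_rand_score

        pids = list(self.labels)
        true = self.model.ground_truth.labels(pids)
        found = [self.labels[p] for p in pids]
        return float(adjusted_rand_score(true, found))

    # ------------------------------------------------------------------
    def summary(self) -> str:
        c = self.cohort_counts
        s = self.episode_summary
        lines = [
            "Flare diary analysis",
            "====================",
            f"participants registered           {c['n_registered']}",
            (
                f"participants with >=1 flare       {c['n_with_flare']} "
                f"({c['pct_with_flare']:.1f}%)"
                if c["pct_with_flare"] is not None
                else "participants with >=1 flare       0"
            ),
            f"eligible (>= {self.model.min_days} entry days)        {c['n_eligible_min_days']}",
            f"clustered (complete features)     {c['n_clustered']}",
            "",
            f"flare episodes                    {s.n_flares_total}",
        ]
        if s.duration_mean is not None:
            sd = f"{s.duration_sd:.2f}" if s.duration_sd is not None else "NA"
            lines.append(
                f"episode duration, days            mean {s.duration_mean:.2f} "
                f"(S.d. {sd}, range {s.duration_min}-{s.duration_max})"
            )
        if s.frequency_interval_mean is not None:
            sd = (
                f"{s.frequency_interval_sd:.2f}"
                if s.frequency_interval_sd is not None
                else "NA"
            )
            lines.append(
                f"flare frequency, days/flare       mean {s.frequency_interval_mean:.2f} "
                f"(S.d. {sd}, range {s.frequency_interval_min:.0f}-{s.frequency_interval_max:.0f})"
            )
        lines.append("")
        lines.append("paired flare-on vs flare-off differences (P < %.2g flagged):" % self.model.alpha)
        t1 = self.table1.dropna(subset=["estimated_difference"])
        for variable, row in t1.iterrows():
            star = "*" if row["significant"] else " "
            lines.append(
                f"  {variable:<30s} {row['estimated_difference']:+.3f} "
                f"[{row['ci_low']:+.3f}, {row['ci_high']:+.3f}]  n={int(row['n']):<4d}{star}"
            )
        if self.ap_result is not None:
            lines.append("")
            lines.append(
                f"affinity propagation: {self.n_clusters} cluster(s), sizes "
                f"{self.cluster_sizes}, converged={self.ap_result.converged} "
                f"after {self.ap_result.n_iterations} iterations"
            )
            if self.duration_comparison is not None:
                d = self.duration_comparison
                lines.append(
                    f"episode duration by cluster: {d.mean_a:.2f} vs {d.mean_b:.2f} days "
                    f"(Welch p = {d.p_value:.4g})"
                )
            ari = self.adjusted_rand()
            if ari is not None:
                lines.append(f"adjusted Rand vs ground truth: {ari:.3f}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, output_dir: str | Path) -> dict[str, Path]:
        """Write all report artifacts (CSV tables + report.json)."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        self.episode_table().to_csv(out / "episodes.csv", index=False)
        paths["episodes"] = out / "episodes.csv"
        self.features.to_csv(out / "features.csv")
        paths["features"] = out / "features.csv"
        self.table1.to_csv(out / "table1.csv")
        paths["table1"] = out / "table1.csv"
        for name, table in (("table2", self.table2), ("table3", self.table3), ("table4", self.table4)):
            if table is not None:
                table.to_csv(out / f"{name}.csv")
                paths[name] = out / f"{name}.csv"
        self.labels_table().to_csv(out / "labels.csv", index=False)
        paths["labels"] = out / "labels.csv"
        (out / "report.json").write_text(
            json.dumps(self.report_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        paths["report"] = out / "report.json"
        return paths

    def report_dict(self) -> dict:
        s = self.episode_summary
        d = self.duration_comparison
        report = {
            "version": _pkg_version,
            "config": {
                "flare_threshold": self.model.flare_threshold,
                "min_days": self.model.min_days,
                "clustering_variables": self.model.clustering_variables,
                "normalization": self.model.normalization,
                "frequency_method": self.model.frequency_method,
                "alpha": self.model.alpha,
                "ap": dataclasses.asdict(self.model.ap_config),
            },
            "cohort_counts": self.cohort_counts,
            "filter_log": self.filter_log,
            "episode_summary": dataclasses.asdict(s),
            "clusters": {
                "n_clusters": self.n_clusters,
                "sizes": self.cluster_sizes,
                "converged": self.ap_result.converged if self.ap_result else None,
                "n_iterations": self.ap_result.n_iterations if self.ap_result else None,
                "net_similarity": self.ap_result.net_similarity if self.ap_result else None,
                "preference": self.ap_result.preference if self.ap_result else None,
            },
            "duration_comparison": dataclasses.asdict(d) if d is not None else None,
            "adjusted_rand": self.adjusted_rand(),
        }
        return report
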