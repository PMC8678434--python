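"""Synthetic diary cohorts with planted flare phenotypes.

The generator emulates the structure of a smartphone symptom diary for
axial spondyloarthritis: each participant scores 8 fixed petals (including
the flare petal) plus 2 chosen optional petals daily on a 1–5 Likert scale
(1 = least healthy), with irregular adherence. Participants belong to one
of two latent phenotype clusters that differ in flare-episode duration and
in how strongly each symptom shifts during flare. Flare/non-flare dynamics
follow an alternating renewal process: flare-off run lengths and flare
durations are (shifted) geometric, giving cluster-specific mean durations
and a common ~35-day onset-to-onset cadence.

Symptom scores arise from a latent-Gaussian model: participant baseline
(population mean + between-participant deviation) plus the cluster's flare
shift on flare days plus daily noise, rounded to the nearest integer and
clipped to 1..5. Days are masked completely at random (optionally more
often during flare, to probe adherence bias), and individual petals are
additionally masked at a small rate. The flare petal encodes the latent
state with configurable fidelity so that threshold binarization recovers
it. Everything is deterministic given the seed.
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalogue import DEFAULT_CATALOGUE, OPTIONAL_VARIABLES, PetalCatalogue
from .data import BaselineRecord, DailyEntry, ParticipantSeries
from .io import write_baseline, write_daily_entries

STUDY_START = _dt.date(2018, 4, 5)

#: Population flare-off Likert means for the symptom petals. The
#: anti-inflammatory petal is kept on the 1–5 scale of the data model and
#: given a mid-scale baseline (its published summaries sit on an
#: incompatible ~0–1 scale); optional petals share a generic mid-high
#: baseline.
DEFAULT_BASELINE_MEANS: dict[str, float] = {
    "pain": 3.79,
    "fatigue": 3.50,
    "sleep quality": 3.40,
    "recommended exercise": 3.60,
    "mood": 3.35,
    "anti-inflammatory use": 2.60,
    "stress": 4.00,
    **{v: 3.50 for v in OPTIONAL_VARIABLES},
}

#: Per-cluster latent flare shifts (flare-on minus flare-off) for every
#: petal; cluster 0 flares are milder but longer, cluster 1 flares shorter
#: but more intense.
DEFAULT_CLUSTER_SHIFTS: tuple[dict[str, float], dict[str, float]] = (
    {
        "pain": -0.694,
        "fatigue": -0.368,
        "sleep quality": -0.151,
        "recommended exercise": -0.274,
        "mood": -0.251,
        "anti-inflammatory use": 0.131,
        "stress": -0.101,
        "caffeine intake": -0.015,
        "hot flushes": -0.408,
        "adherence to medication": -0.008,
        "screen time": -0.124,
        "confidence in self-management": -0.330,
        "eyesight": -0.077,
        "hydration": -0.103,
        "chest pain": -0.227,
        "flare of psoriasis": -0.024,
        "impact of menstrual cycle": -0.115,
        "red painful eyes": -0.094,
        "smoking habits": 0.132,
        "blood in stool": 0.0,
    },
    {
        "pain": -0.984,
        "fatigue": -1.111,
        "sleep quality": -0.438,
        "recommended exercise": -0.422,
        "mood": -0.800,
        "anti-inflammatory use": 0.128,
        "stress": -0.980,
        "caffeine intake": -0.122,
        "hot flushes": -0.348,
        "adherence to medication": -0.032,
        "screen time": -0.619,
        "confidence in self-management": -0.779,
        "eyesight": -0.362,
        "hydration": 0.046,
        "chest pain": -0.956,
        "flare of psoriasis": 0.0,
        "impact of menstrual cycle": -0.399,
        "red painful eyes": 0.043,
        "smoking habits": 0.0,
        "blood in stool": 0.224,
    },
)

#: Per-cluster baseline covariate models: continuous -> (mean, sd) per
#: cluster; binary -> probability per cluster; plus per-covariate missing
#: probabilities reflecting that clinic-derived measures are often absent.
DEFAULT_CONTINUOUS_COVARIATES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "basmi": ((3.173, 2.069), (3.533, 2.082)),
    "basdai": ((3.680, 1.733), (3.852, 2.081)),
    "basfi": ((3.627, 2.568), (3.715, 2.214)),
    "eq5d": ((0.618, 0.191), (0.659, 0.240)),
    "pain_discomfort": ((2.585, 0.663), (2.400, 0.940)),
    "anxiety_depression": ((1.906, 1.005), (1.600, 0.754)),
    "patient_global": ((4.018, 2.057), (3.429, 2.420)),
    "asqol": ((8.060, 4.716), (7.935, 5.234)),
    "work_productivity_impairment": ((3.640, 2.691), (4.000, 3.162)),
    "activity_impairment": ((4.240, 2.722), (3.950, 2.964)),
}

DEFAULT_BINARY_COVARIATES: dict[str, tuple[float, float]] = {
    "employed": (0.592, 0.650),
    "female": (0.354, 0.303),
    "hla_b27_positive": (0.818, 0.813),
    "bdmard_ever": (0.427, 0.515),
    "chronic_widespread_pain": (0.188, 0.333),
}

DEFAULT_SMOKER_PROBS: tuple[tuple[float, float, float], tuple[float, float, float]] = (
    (0.154, 0.431, 0.415),
    (0.000, 0.333, 0.667),
)

DEFAULT_COVARIATE_MISSING: dict[str, float] = {
    "basmi": 0.39,
    "basdai": 0.28,
    "basfi": 0.32,
    "eq5d": 0.44,
    "pain_discomfort": 0.44,
    "anxiety_depression": 0.44,
    "patient_global": 0.40,
    "asqol": 0.38,
    "work_productivity_impairment": 0.71,
    "activity_impairment": 0.46,
    "employed": 0.47,
    "female": 0.0,
    "hla_b27_positive": 0.07,
    "smoker": 0.33,
    "bdmard_ever": 0.0,
    "chronic_widespread_pain": 0.0,
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full parameterisation of the generative model. Defaults emulate the
    clustered study cohort: 129 participants split 96:33 across the two
    phenotypes, ~157 logged days each, flares every ~35 days lasting 7.2 vs
    3.5 days on average."""

    n_participants: int = 129
    cluster_weights: tuple[float, ...] = (96.0, 33.0)
    followup_mean_days: float = 185.0
    followup_cv: float = 1.27
    followup_min_days: int = 12
    followup_max_days: int = 720
    flare_duration_mean: tuple[float, ...] = (7.2, 3.5)
    flare_gap_mean: tuple[float, ...] = (27.8, 31.5)
    episode_tail: str = "geometric"  # or "negative_binomial"
    nb_shape: float = 0.5
    baseline_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_MEANS)
    )
    cluster_shifts: tuple[dict[str, float], ...] = DEFAULT_CLUSTER_SHIFTS
    daily_noise_sd: float = 0.8
    baseline_heterogeneity_sd: float = 0.5
    shift_heterogeneity_sd: float = 0.15
    shared_daily_factor_sd: float = 0.0
    missing_day_prob: float = 0.15
    missing_day_prob_flare_extra: float = 0.0
    missing_petal_prob: float = 0.02
    flare_fidelity: float = 0.995
    flare_threshold: int = 3
    #: solve for the latent shift whose expected rounded-and-clipped Likert
    #: difference equals the configured value, so cluster mean difference
    #: features are calibrated to the configured shifts despite boundary
    #: compression of the 1-5 scale
    calibrate_shifts: bool = True

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if any(w <= 0 for w in self.cluster_weights):
            raise ValueError("cluster weights must be positive")
        n_clusters = len(self.cluster_weights)
        if not (
            len(self.flare_duration_mean)
            == len(self.flare_gap_mean)
            == len(self.cluster_shifts)
            == n_clusters
        ):
            raise ValueError("per-cluster parameter lengths must match weights")
        if any(m < 1 for m in self.flare_duration_mean):
            raise ValueError("flare duration means must be >= 1 day")
        if any(m < 1 for m in self.flare_gap_mean):
            raise ValueError("flare gap means must be >= 1 day")
        for p in (
            self.missing_day_prob,
            self.missing_petal_prob,
            self.flare_fidelity,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.episode_tail not in ("geometric", "negative_binomial"):
            raise ValueError("episode_tail must be geometric or negative_binomial")
        if not 1 <= self.flare_threshold <= 5:
            raise ValueError("flare_threshold must be in 1..5")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cluster_shifts"] = [dict(s) for s in self.cluster_shifts]
        return d


@dataclass
class ParticipantTruth:
    cluster: int
    first_date: _dt.date
    followup_days: int
    flare_days: np.ndarray  # boolean latent flare state per follow-up day
    episode_starts: list[_dt.date]
    episode_durations: list[int]
    shifts: dict[str, float]


@dataclass
class GroundTruth:
    """Latent state of the generated cohort, recorded before missingness."""

    participants: dict[str, ParticipantTruth]

    def labels(self, participant_ids: list[str]) -> np.ndarray:
        return np.asarray(
            [self.participants[p].cluster for p in participant_ids], dtype=int
        )


def _expected_likert(mean: float, sd: float) -> float:
    """E[clip(round(X), 1, 5)] for X ~ N(mean, sd^2): the observed score is
    1 + sum_k 1[X >= k - 0.5] for k = 2..5."""
    from scipy.stats import norm

    return 1.0 + float(sum(norm.sf((k - 0.5 - mean) / sd) for k in range(2, 6)))


def _calibrated_shift(
    target: float, base: float, sd_off: float, sd_on: float
) -> float:
    """Latent shift whose expected realised Likert difference (flare-on
    minus flare-off) equals ``target`` given rounding and 1-5 clipping."""
    if target == 0.0:
        return 0.0
    from scipy.optimize import brentq

    off = _expected_likert(base, sd_off)

    def gap(shift: float) -> float:
        return _expected_likert(base + shift, sd_on) - off - target

    lo, hi = -6.0, 6.0
    if gap(lo) > 0 or gap(hi) < 0:  # target unattainable within the scale
        return float(np.clip(target, lo, hi))
    return float(brentq(gap, lo, hi, xtol=1e-10))


def _run_length(rng: np.random.Generator, mean: float, tail: str, nb_shape: float) -> int:
    """A run length on {1, 2, ...} with the requested mean."""
    if mean <= 1.0:
        return 1
    if tail == "geometric":
        return int(rng.geometric(1.0 / mean))
    # shifted negative binomial: 1 + NB(shape, p) with mean 1 + shape(1-p)/p
    p = nb_shape / (nb_shape + mean - 1.0)
    return 1 + int(rng.negative_binomial(nb_shape, p))


def _latent_flare_sequence(
    rng: np.random.Generator, n_days: int, gap_mean: float, dur_mean: float,
    tail: str, nb_shape: float,
) -> np.ndarray:
    state = np.zeros(n_days, dtype=bool)
    t = int(rng.integers(0, max(int(gap_mean), 1)))  # random phase into first gap
    while t < n_days:
        dur = _run_length(rng, dur_mean, tail, nb_shape)
        state[t : t + dur] = True
        t += dur + _run_length(rng, gap_mean, tail, nb_shape)
    return state


def generate_cohort(
    config: SyntheticCohortConfig = SyntheticCohortConfig(),
    seed: int = 0,
    catalogue: PetalCatalogue = DEFAULT_CATALOGUE,
) -> tuple[list[ParticipantSeries], list[BaselineRecord], GroundTruth]:
    """Generate a full synthetic cohort: diaries, baselines and truth."""
    config.validate()
    rng = np.random.default_rng(seed)
    weights = np.asarray(config.cluster_weights, dtype=float)
    weights = weights / weights.sum()
    sigma2 = float(np.log1p(config.followup_cv**2))
    mu = float(np.log(config.followup_mean_days) - sigma2 / 2.0)

    symptom_vars = [v for v in catalogue.fixed_variables if v != "flare"]
    sd_off = float(np.hypot(config.daily_noise_sd, config.baseline_heterogeneity_sd))
    sd_on = float(np.hypot(sd_off, config.shift_heterogeneity_sd))
    latent_shifts: list[dict[str, float]] = []
    for shifts_c in config.cluster_shifts:
        if config.calibrate_shifts:
            latent_shifts.append(
                {
                    v: _calibrated_shift(t, config.baseline_means[v], sd_off, sd_on)
                    for v, t in shifts_c.items()
                }
            )
        else:
            latent_shifts.append(dict(shifts_c))
    series_list: list[ParticipantSeries] = []
    baseline_list: list[BaselineRecord] = []
    truth: dict[str, ParticipantTruth] = {}

    for i in range(config.n_participants):
        pid = f"P{i + 1:04d}"
        cluster = int(rng.choice(len(weights), p=weights))
        span = int(np.clip(
            round(float(rng.lognormal(mu, np.sqrt(sigma2)))),
            config.followup_min_days,
            config.followup_max_days,
        ))
        first_date = STUDY_START + _dt.timedelta(days=int(rng.integers(0, 540)))
        flare = _latent_flare_sequence(
            rng, span,
            config.flare_gap_mean[cluster], config.flare_duration_mean[cluster],
            config.episode_tail, config.nb_shape,
        )

        optional = list(rng.choice(len(catalogue.optional_variables), size=2, replace=False))
        chosen = [catalogue.optional_variables[j] for j in sorted(optional)]
        variables = symptom_vars + chosen

        shifts: dict[str, float] = {}
        scores = np.empty((len(variables), span), dtype=int)
        shared = (
            rng.normal(0.0, config.shared_daily_factor_sd, size=span)
            if config.shared_daily_factor_sd > 0
            else np.zeros(span)
        )
        for vi, v in enumerate(variables):
            base = config.baseline_means[v] + rng.normal(0.0, config.baseline_heterogeneity_sd)
            shift = latent_shifts[cluster].get(v, 0.0) + rng.normal(
                0.0, config.shift_heterogeneity_sd
            )
            shifts[v] = shift
            latent = (
                base
                + shift * flare
                + shared
                + rng.normal(0.0, config.daily_noise_sd, size=span)
            )
            scores[vi] = np.clip(np.rint(latent), 1, 5).astype(int)

        # flare petal: encodes the latent state, flipped with prob 1-fidelity
        faithful = rng.random(span) < config.flare_fidelity
        report_on = np.where(faithful, flare, ~flare)
        t_ = config.flare_threshold
        on_scores = rng.integers(1, t_ + 1, size=span)
        off_scores = rng.integers(t_ + 1, 6, size=span)
        flare_scores = np.where(report_on, on_scores, off_scores)

        p_missing = np.full(span, config.missing_day_prob)
        p_missing[flare] = np.clip(
            p_missing[flare] + config.missing_day_prob_flare_extra, 0.0, 1.0
        )
        day_present = rng.random(span) >= p_missing
        petal_present = rng.random((len(variables) + 1, span)) >= config.missing_petal_prob

        entries: list[DailyEntry] = []
        for t in range(span):
            if not day_present[t]:
                continue
            day_scores: dict[str, int] = {}
            for vi, v in enumerate(variables):
                if petal_present[vi, t]:
                    day_scores[v] = int(scores[vi, t])
            if petal_present[len(variables), t]:
                day_scores["flare"] = int(flare_scores[t])
            if not day_scores:
                continue
            entries.append(
                DailyEntry(pid, first_date + _dt.timedelta(days=t), dict(sorted(day_scores.items())))
            )
        series_list.append(
            ParticipantSeries(pid, entries, chosen_optional=frozenset(chosen))
        )

        starts, durations = _episodes_from_state(flare)
        truth[pid] = ParticipantTruth(
            cluster=cluster,
            first_date=first_date,
            followup_days=span,
            flare_days=flare,
            episode_starts=[first_date + _dt.timedelta(days=int(s)) for s in starts],
            episode_durations=[int(d) for d in durations],
            shifts=shifts,
        )
        baseline_list.append(_sample_baseline(rng, pid, cluster))

    return series_list, baseline_list, GroundTruth(truth)


def _episodes_from_state(flare: np.ndarray) -> tuple[list[int], list[int]]:
    padded = np.concatenate(([False], flare, [False])).astype(int)
    edges = np.diff(padded)
    starts = list(np.flatnonzero(edges == 1))
    ends = list(np.flatnonzero(edges == -1))
    return starts, [e - s for s, e in zip(starts, ends)]


def _sample_baseline(rng: np.random.Generator, pid: str, cluster: int) -> BaselineRecord:
    miss = DEFAULT_COVARIATE_MISSING
    continuous: dict[str, float | None] = {}
    for name, per_cluster in DEFAULT_CONTINUOUS_COVARIATES.items():
        mean, sd = per_cluster[cluster % len(per_cluster)]
        value = float(rng.normal(mean, sd))
        continuous[name] = None if rng.random() < miss.get(name, 0.0) else round(value, 3)
    binary: dict[str, int | None] = {}
    for name, probs in DEFAULT_BINARY_COVARIATES.items():
        value = int(rng.random() < probs[cluster % len(probs)])
        binary[name] = None if rng.random() < miss.get(name, 0.0) else value
    if binary.get("female") is not None:
        binary["male"] = 1 - binary["female"]
    else:
        binary["male"] = None
    smoker_probs = DEFAULT_SMOKER_PROBS[cluster % len(DEFAULT_SMOKER_PROBS)]
    category = int(rng.choice(3, p=np.asarray(smoker_probs) / sum(smoker_probs)))
    smoker_missing = rng.random() < miss.get("smoker", 0.0)
    for j, name in enumerate(("current_smoker", "ex_smoker", "never_smoker")):
        binary[name] = None if smoker_missing else int(category == j)
    return BaselineRecord(pid, continuous, binary)


def null_config(**overrides) -> SyntheticCohortConfig:
    """A single-phenotype cohort with no flare effect on any symptom: one
    cluster, zero shift vector. Flare dynamics still alternate."""
    defaults = dict(
        cluster_weights=(1.0,),
        flare_duration_mean=(4.3,),
        flare_gap_mean=(31.0,),
        cluster_shifts=({v: 0.0 for v in DEFAULT_BASELINE_MEANS},),
        shift_heterogeneity_sd=0.0,
    )
    defaults.update(overrides)
    return SyntheticCohortConfig(**defaults)


def emit_fixture_suite(output_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the canonical small fixtures used by tests and examples.

    * ``bridge_pattern.csv`` — one participant exercising the one-missing-day
      bridge rule (flare-on, missing, flare-on) plus a two-day gap that must
      not be bridged;
    * ``duplicate_rows.csv`` — a tiny feature matrix with exact duplicate
      rows (the tie-degenerate clustering case);
    * ``null_diary.csv``/``null_baseline.csv`` — a small no-effect cohort;
    * ``cohort_diary.csv``/``cohort_baseline.csv``/``cohort_manifest.json``
      — a two-phenotype cohort at the default parameterisation (scaled to 40
      participants to stay small), manifest recording config + seed.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    bridge = out / "bridge_pattern.csv"
    d0 = STUDY_START
    rows = ["participant_id,date,variable,score"]
    pattern = {0: 1, 2: 1, 3: 5, 5: 1, 8: 1}  # day offset -> flare score
    for off, score in pattern.items():
        date = (d0 + _dt.timedelta(days=off)).isoformat()
        rows.append(f"B001,{date},flare,{score}")
        rows.append(f"B001,{date},pain,{2 if score <= 3 else 4}")
    bridge.write_text("\n".join(rows) + "\n", encoding="utf-8")
    paths["bridge"] = bridge

    dup = out / "duplicate_rows.csv"
    dup.write_text(
        "participant_id,pain_diff,fatigue_diff\n"
        "D001,-1.0,-1.0\nD002,-1.0,-1.0\nD003,1.0,1.0\nD004,1.0,1.0\n",
        encoding="utf-8",
    )
    paths["duplicate_rows"] = dup

    null_cfg = null_config(n_participants=20, followup_mean_days=60.0)
    series, baseline, _ = generate_cohort(null_cfg, seed=seed)
    write_daily_entries(series, out / "null_diary.csv")
    write_baseline(baseline, out / "null_baseline.csv")
    paths["null_diary"] = out / "null_diary.csv"
    paths["null_baseline"] = out / "null_baseline.csv"

    cohort_cfg = SyntheticCohortConfig(
        n_participants=40, cluster_weights=(30.0, 10.0), followup_mean_days=90.0
    )
    series, baseline, _ = generate_cohort(cohort_cfg, seed=seed + 1)
    write_daily_entries(series, out / "cohort_diary.csv")
    write_baseline(baseline, out / "cohort_baseline.csv")
    manifest = {"seed": seed + 1, "config": cohort_cfg.to_dict()}
    (out / "cohort_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8"
    )
    paths["cohort_diary"] = out / "cohort_diary.csv"
    paths["cohort_baseline"] = out / "cohort_baseline.csv"
    paths["cohort_manifest"] = out / "cohort_manifest.json"
    return paths
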