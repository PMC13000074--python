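"""Raw ICU event streams -> model-ready windowed tensors.

The pipeline stages, in their fixed contract order:

1. :func:`remove_outliers` — drop events outside inclusive clinical
   plausibility bounds.
2. :func:`aggregate_windows` — summarize events into half-open 4-hour
   windows ``[4t, 4(t+1))``: minimum for GCS subscores, maximum for PEEP and
   vasopressor rate, sum for IV fluid, mean for everything else.
3. :func:`forward_fill` — carry the last observation forward across at most
   6 windows (24 h); never across longer gaps, never before the first
   observation.
4. :func:`filter_missingness` — drop features missing in more than 60% of
   cohort cells, then patients with more than 30% missing cells (strict
   inequalities; feature filtering strictly precedes patient filtering).
5. :func:`split_cohort` — random 70/15/15 patient-level partition.
6. :func:`compute_stats` — training-split means/SDs and medians.
7. :func:`derive_labels` — remaining length of stay (days), next-window
   mechanical-ventilation / renal-replacement labels, 90-day mortality.
8. :func:`impute_and_flag` — training-median imputation plus binary flags
   for pre-imputation missing weight/height.
9. :func:`normalize` — z-score encoder inputs with training statistics.

:func:`preprocess` chains all stages. IV fluid and vasopressor are carried
as per-window treatment actions, and PEEP/RRT documentation only as label
sources; none of them enter the encoder input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (
    DEMOGRAPHIC_FEATURES,
    MISSING_FLAG_FEATURES,
    WINDOW_HOURS,
    FeatureSpec,
    default_feature_specs,
)

BINARY_FEATURES = ("gender",) + MISSING_FLAG_FEATURES


@dataclass
class TimeStepTensor:
    """One patient's windowed feature matrix plus labels and actions.

    ``features`` is (n_windows x n_features); NaN marks a missing cell.
    ``observed_mask`` is 1 where the cell was measured or forward-filled
    (i.e. known before imputation). ``rrt_next``/``mv_next`` are NaN at the
    final window, where the next-step outcome is undefined.
    """

    patient_id: int
    feature_names: list[str]
    features: np.ndarray
    observed_mask: np.ndarray
    n_windows: int
    fluid_total: np.ndarray  # mL per window
    vaso_max: np.ndarray  # ug/kg/min NE-equivalent
    peep_documented: np.ndarray  # bool per window (label source)
    rrt_documented: np.ndarray
    died_90d: int | None = None
    remaining_los_days: np.ndarray | None = None
    rrt_next: np.ndarray | None = None
    mv_next: np.ndarray | None = None
    features_raw: np.ndarray | None = None  # clinical scale, post-imputation
    measured_mask: np.ndarray | None = None  # 1 = actually measured (pre-fill)

    def copy(self) -> "TimeStepTensor":
        return TimeStepTensor(
            patient_id=self.patient_id,
            feature_names=list(self.feature_names),
            features=self.features.copy(),
            observed_mask=self.observed_mask.copy(),
            n_windows=self.n_windows,
            fluid_total=self.fluid_total.copy(),
            vaso_max=self.vaso_max.copy(),
            peep_documented=self.peep_documented.copy(),
            rrt_documented=self.rrt_documented.copy(),
            died_90d=self.died_90d,
            remaining_los_days=None if self.remaining_los_days is None else self.remaining_los_days.copy(),
            rrt_next=None if self.rrt_next is None else self.rrt_next.copy(),
            mv_next=None if self.mv_next is None else self.mv_next.copy(),
            features_raw=None if self.features_raw is None else self.features_raw.copy(),
            measured_mask=None if self.measured_mask is None else self.measured_mask.copy(),
        )


@dataclass
class NormalizationStats:
    """Training-split feature statistics (never computed on val/test)."""

    mean: pd.Series
    sd: pd.Series
    median: pd.Series
    degenerate: list[str] = field(default_factory=list)  # SD == 0 features


@dataclass
class ExclusionReport:
    dropped_features: pd.Series  # feature -> cohort missing fraction
    excluded_patients: pd.Series  # patient_id -> missing fraction
    outlier_removals: pd.Series | None = None  # variable -> rows removed


def remove_outliers(
    events: pd.DataFrame, specs: dict[str, FeatureSpec]
) -> tuple[pd.DataFrame, pd.Series]:
    """Drop events outside the registered inclusive bounds.

    Returns the surviving events and a per-variable removal count.
    """
    unknown = sorted(set(events["variable"]) - set(specs))
    if unknown:
        raise ValueError(f"unregistered variables: {unknown}")
    lo = events["variable"].map({k: s.outlier_min for k, s in specs.items()})
    hi = events["variable"].map({k: s.outlier_max for k, s in specs.items()})
    ok = (events["value"] >= lo) & (events["value"] <= hi)
    removed = events.loc[~ok, "variable"].value_counts()
    counts = removed.reindex(sorted(specs), fill_value=0)
    return events.loc[ok].reset_index(drop=True), counts


def aggregate_windows(
    events: pd.DataFrame,
    admissions: pd.DataFrame,
    specs: dict[str, FeatureSpec] | None = None,
) -> list[TimeStepTensor]:
    """Aggregate outlier-cleaned events into per-patient 4-h window tensors.

    Windows are half-open ``[4t, 4(t+1))`` hours and cover the stay
    (``n_windows = ceil(los_hours / 4)``). Encoder-input cells with no
    event are left missing (NaN); fluid/vasopressor actions default to 0
    (nothing administered); PEEP/RRT presence is recorded as documentation
    flags for label derivation. Demographics from the admission table are
    broadcast to every window.
    """
    specs = specs or default_feature_specs()
    enc_feats = [s.name for s in specs.values() if s.role == "encoder_input"]
    columns = list(DEMOGRAPHIC_FEATURES) + enc_feats

    adm = admissions.set_index("patient_id")
    ev = events.copy()
    ev["window"] = np.floor(ev["time_offset_hours"].to_numpy() / WINDOW_HOURS).astype(int)
    los = adm["los_hours"].reindex(ev["patient_id"]).to_numpy()
    beyond = ev["time_offset_hours"].to_numpy() >= los
    if beyond.any():
        warnings.warn(
            f"dropping {int(beyond.sum())} events recorded after discharge",
            stacklevel=2,
        )
        ev = ev.loc[~beyond]

    tensors: list[TimeStepTensor] = []
    grouped = dict(list(ev.groupby("patient_id")))
    for pid, row in adm.iterrows():
        T = max(1, math.ceil(row["los_hours"] / WINDOW_HOURS))
        X = np.full((T, len(columns)), np.nan)
        fluid = np.zeros(T)
        vaso = np.zeros(T)
        peep_doc = np.zeros(T, bool)
        rrt_doc = np.zeros(T, bool)
        g = grouped.get(pid)
        if g is not None:
            for (var, w), vals in g.groupby(["variable", "window"])["value"]:
                spec = specs[var]
                if spec.role == "action_source":
                    if var == "iv_fluid":
                        fluid[w] = vals.sum()
                    else:
                        vaso[w] = vals.max()
                elif spec.role == "outcome_source":
                    (peep_doc if var == "peep" else rrt_doc)[w] = True
                elif spec.role == "encoder_input":
                    agg = getattr(vals, spec.aggregation)()
                    X[w, columns.index(var)] = agg
        for j, d in enumerate(DEMOGRAPHIC_FEATURES):
            X[:, j] = row[d]
        tensors.append(
            TimeStepTensor(
                patient_id=int(pid),
                feature_names=columns,
                features=X,
                observed_mask=(~np.isnan(X)).astype(float),
                n_windows=T,
                fluid_total=fluid,
                vaso_max=vaso,
                peep_documented=peep_doc,
                rrt_documented=rrt_doc,
                died_90d=int(row["died_90d"]) if "died_90d" in row else None,
                measured_mask=(~np.isnan(X)).astype(float),
            )
        )
    return tensors


def forward_fill(tensor: TimeStepTensor, max_gap_windows: int = 6) -> TimeStepTensor:
    """Propagate the last observed value over at most ``max_gap_windows``.

    Filled cells count as observed (mask 1) but never act as fill sources
    themselves — the gap is always measured from the original observation,
    so re-running the fill is a no-op. Gaps longer than the cap stay
    missing, and nothing is filled before a feature's first observation.
    """
    out = tensor.copy()
    X, M = out.features, out.observed_mask
    meas = out.measured_mask if out.measured_mask is not None else M.copy()
    out.measured_mask = meas
    T, F = X.shape
    for j in range(F):
        last_val, last_t = np.nan, -10 * max_gap_windows
        for t in range(T):
            if meas[t, j] == 1:
                last_val, last_t = X[t, j], t
            elif t - last_t <= max_gap_windows and not np.isnan(last_val):
                X[t, j] = last_val
                M[t, j] = 1.0
    return out


def filter_missingness(
    tensors: list[TimeStepTensor],
    feature_threshold: float = 0.60,
    patient_threshold: float = 0.30,
) -> tuple[list[TimeStepTensor], ExclusionReport]:
    """Exclude sparse features, then sparse patients (strict ``>``).

    Missingness is computed on post-forward-fill cells. Feature filtering is
    cohort-wide and strictly precedes patient filtering; this ordering is
    part of the contract.
    """
    if not tensors:
        raise ValueError("no tensors supplied")
    names = tensors[0].feature_names
    miss = np.zeros(len(names))
    cells = 0
    for t in tensors:
        miss += (t.observed_mask == 0).sum(axis=0)
        cells += t.n_windows
    frac = pd.Series(miss / cells, index=names)
    dropped = frac[frac > feature_threshold]
    keep_idx = [i for i, n in enumerate(names) if n not in dropped.index]
    if not keep_idx:
        raise RuntimeError("all features exceed the missingness threshold")

    kept: list[TimeStepTensor] = []
    excluded = {}
    for t in tensors:
        out = t.copy()
        out.feature_names = [names[i] for i in keep_idx]
        out.features = out.features[:, keep_idx]
        out.observed_mask = out.observed_mask[:, keep_idx]
        if out.measured_mask is not None:
            out.measured_mask = out.measured_mask[:, keep_idx]
        pfrac = float((out.observed_mask == 0).mean())
        if pfrac > patient_threshold:
            excluded[t.patient_id] = pfrac
        else:
            kept.append(out)
    report = ExclusionReport(
        dropped_features=dropped,
        excluded_patients=pd.Series(excluded, dtype=float),
    )
    return kept, report


def compute_stats(train_tensors: list[TimeStepTensor]) -> NormalizationStats:
    """Per-feature mean/SD/median over observed training cells only."""
    names = train_tensors[0].feature_names
    cols = {n: [] for n in names}
    for t in train_tensors:
        for j, n in enumerate(names):
            obs = t.features[t.observed_mask[:, j] == 1, j]
            cols[n].append(obs)
    mean, sd, med, degenerate = {}, {}, {}, []
    for n in names:
        v = np.concatenate(cols[n]) if cols[n] else np.array([])
        if v.size == 0:
            mean[n], sd[n], med[n] = 0.0, 1.0, 0.0
            degenerate.append(n)
            continue
        mean[n] = float(v.mean())
        s = float(v.std(ddof=0))
        med[n] = float(np.median(v))
        if s == 0.0:
            degenerate.append(n)
            s = 1.0
        sd[n] = s
    return NormalizationStats(
        mean=pd.Series(mean), sd=pd.Series(sd), median=pd.Series(med), degenerate=degenerate
    )


def impute_and_flag(
    tensors: list[TimeStepTensor], stats: NormalizationStats
) -> list[TimeStepTensor]:
    """Fill remaining missing cells with the *training* median and append
    binary weight/height pre-imputation missingness flags."""
    out = []
    for t in tensors:
        c = t.copy()
        flags = []
        for base in ("weight", "height"):
            j = c.feature_names.index(base)
            flags.append(float((c.observed_mask[:, j] == 0).all()))
        for j, n in enumerate(c.feature_names):
            if n not in stats.median.index:
                raise KeyError(f"no training median for feature {n!r}")
            hole = c.observed_mask[:, j] == 0
            c.features[hole, j] = stats.median[n]
        T = c.n_windows
        flag_cols = np.tile(np.array(flags), (T, 1))
        c.features = np.hstack([c.features, flag_cols])
        c.observed_mask = np.hstack([c.observed_mask, np.ones_like(flag_cols)])
        if c.measured_mask is not None:
            c.measured_mask = np.hstack([c.measured_mask, np.ones_like(flag_cols)])
        c.feature_names = c.feature_names + list(MISSING_FLAG_FEATURES)
        out.append(c)
    return out


def derive_labels(
    tensor: TimeStepTensor, admission_row: pd.Series | None = None
) -> TimeStepTensor:
    """Attach per-window labels.

    remaining LOS (days) decreases by 4/24 per window; next-window MV is
    inferred from PEEP documentation and next-window RRT from RRT
    documentation; both are undefined (NaN) at the final window. 90-day
    mortality comes from the admission table.
    """
    out = tensor.copy()
    T = out.n_windows
    out.remaining_los_days = (T - np.arange(T)) * (WINDOW_HOURS / 24.0)
    mv = np.full(T, np.nan)
    rr = np.full(T, np.nan)
    if T > 1:
        mv[:-1] = out.peep_documented[1:].astype(float)
        rr[:-1] = out.rrt_documented[1:].astype(float)
    out.mv_next = mv
    out.rrt_next = rr
    if admission_row is not None:
        out.died_90d = int(admission_row["died_90d"])
    return out


def normalize(
    tensors: list[TimeStepTensor], stats: NormalizationStats
) -> list[TimeStepTensor]:
    """Z-score encoder inputs with training statistics.

    Binary features (gender, missingness flags) pass through untouched;
    degenerate (SD = 0) features use divisor 1. The clinical-scale matrix is
    preserved in ``features_raw`` for cluster summary tables.
    """
    out = []
    for t in tensors:
        c = t.copy()
        c.features_raw = c.features.copy()
        for j, n in enumerate(c.feature_names):
            if n in BINARY_FEATURES:
                continue
            c.features[:, j] = (c.features[:, j] - stats.mean[n]) / stats.sd[n]
        out.append(c)
    return out


def split_cohort(
    patient_ids,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint patient-level train/val/test partition with rounded sizes."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = np.asarray(list(patient_ids))
    if len(ids) < 3:
        raise ValueError("need at least 3 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = round(fractions[0] * len(ids))
    n_val = round(fractions[1] * len(ids))
    train = np.sort(ids[perm[:n_train]])
    val = np.sort(ids[perm[n_train : n_train + n_val]])
    test = np.sort(ids[perm[n_train + n_val :]])
    return train, val, test


def preprocess(
    events: pd.DataFrame,
    admissions: pd.DataFrame,
    specs: dict[str, FeatureSpec] | None = None,
    split_seed: int = 0,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> tuple[dict[str, list[TimeStepTensor]], NormalizationStats, ExclusionReport]:
    """Run the full preprocessing chain; returns split tensors, training
    statistics, and the exclusion report."""
    specs = specs or default_feature_specs()
    clean, removed = remove_outliers(events, specs)
    tensors = aggregate_windows(clean, admissions, specs)
    tensors = [forward_fill(t) for t in tensors]
    tensors, report = filter_missingness(tensors)
    report.outlier_removals = removed

    ids = [t.patient_id for t in tensors]
    train_ids, val_ids, test_ids = split_cohort(ids, fractions, split_seed)
    by_id = {t.patient_id: t for t in tensors}
    adm = admissions.set_index("patient_id")

    splits: dict[str, list[TimeStepTensor]] = {}
    stats = compute_stats([by_id[i] for i in train_ids])
    for name, id_set in (("train", train_ids), ("val", val_ids), ("test", test_ids)):
        ts = [derive_labels(by_id[i], adm.loc[i]) for i in id_set]
        ts = impute_and_flag(ts, stats)
        ts = normalize(ts, stats)
        splits[name] = ts
    return splits, stats, report
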