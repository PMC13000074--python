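"""Synthetic ICU cohort generator with known latent sub-phenotype structure.

Simulates variable-length multivariate ICU stays so the whole phenotyping
pipeline can be exercised and scored against ground truth without access to
credentialed clinical databases. Patients evolve through a first-order
Markov chain over six latent states qualitatively mirroring sepsis course
archetypes (admission, renal failure, respiratory failure, shock,
recovering, partially recovered) with absorbing discharge/death
pseudo-states. Each 4-hour window the active state drives

* Gaussian emissions of ~33 labs/vitals/scores (clinical units), clipped to
  the plausibility bounds of the feature registry, with a small rate of
  gross artifact values so outlier removal has genuine work to do;
* state-dependent documentation of PEEP (mechanical ventilation) and RRT,
  which downstream become the next-step prediction labels;
* a behaviour treatment policy emitting IV fluid volume (mL/window) and a
  norepinephrine-equivalent vasopressor rate (ug/kg/min);
* a per-step death hazard. When the administered treatment falls in the
  state's planted optimal action bin, the hazard is multiplied by a factor
  <= 1 and a small probability mass is shifted toward recovery, giving the
  treatment a real causal effect for the policy-evaluation experiment.

Structured missingness is applied by independently dropping events with
per-feature rates. All randomness flows through one ``numpy`` Generator, so
identical (config, seed) pairs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import FeatureSpec, default_feature_specs

STATE_NAMES = (
    "admission",
    "renal",
    "respiratory",
    "shock",
    "recovering",
    "partial_recovered",
)
DISCHARGE, DEATH = "discharge", "death"
WINDOW_HOURS = 4.0


class ConfigError(ValueError):
    """Invalid simulator configuration; message names the offending field."""


@dataclass
class SynthConfig:
    """Full generative description of a synthetic cohort.

    ``transition_probs`` has one row per latent state over columns
    ``states + [discharge, death]``; the death column is the per-step death
    hazard of that state. ``treatment_match_multiplier`` scales the hazard
    when the window's treatment matches ``optimal_action``;
    ``match_transition_boost`` additionally moves that much probability mass
    toward recovery (recovering state + discharge) on matched windows.
    """

    n_patients: int
    n_states: int = 6
    admission_state: int = 0
    state_names: tuple[str, ...] = STATE_NAMES
    transition_probs: np.ndarray = field(default=None)  # (S, S+2)
    emission_means: pd.DataFrame = field(default=None)  # states x features
    emission_sds: pd.DataFrame = field(default=None)  # states x features
    missing_rates: pd.Series = field(default=None)  # per feature
    behaviour_policy_params: pd.DataFrame = field(default=None)
    optimal_action: np.ndarray = field(default=None)  # (S, 2) = (fluid_bin, vaso_bin)
    treatment_match_multiplier: np.ndarray = field(default=None)  # (S,), in (0, 1]
    match_transition_boost: float = 0.30
    # mismatched treatment in a non-shock state shifts this much probability
    # mass toward relapse into shock (0 disables)
    mismatch_relapse: float = 0.0
    # progressive deterioration: the shock-state death hazard escalates with
    # the number of consecutive windows already spent in shock
    shock_hazard_escalation: float = 0.15
    shock_hazard_cap: float = 0.70
    # observable frailty: every death hazard is scaled by
    # exp(beta * z_age - beta^2/2), so older patients die more often and
    # admission age is genuinely prognostic
    age_mortality_beta: float = 0.7
    peep_prob: np.ndarray = field(default=None)  # (S,)
    rrt_prob: np.ndarray = field(default=None)  # (S,)
    fluid_edges: np.ndarray = field(default=None)  # 3 nonzero-quartile edges
    vaso_edges: np.ndarray = field(default=None)
    max_windows: int = 30
    artifact_rate: float = 0.004
    demog_missing_prob: float = 0.05
    age_mean: float = 65.0
    age_sd: float = 14.0
    weight_mean: float = 80.0
    weight_sd: float = 16.0
    height_mean: float = 172.0
    height_sd: float = 10.0
    p_male: float = 0.55
    seed: int = 0

    def validate(self) -> None:
        if self.n_states < 2:
            raise ConfigError("n_states: must be >= 2")
        if self.n_patients < 1:
            raise ConfigError("n_patients: must be >= 1")
        if not 0 <= self.admission_state < self.n_states:
            raise ConfigError("admission_state: out of range")
        tp = np.asarray(self.transition_probs, float)
        if tp.shape != (self.n_states, self.n_states + 2):
            raise ConfigError("transition_probs: wrong shape")
        if (tp < 0).any():
            raise ConfigError("transition_probs: negative entry")
        if np.abs(tp.sum(axis=1) - 1.0).max() > 1e-12:
            raise ConfigError("transition_probs: rows must sum to 1 within 1e-12")
        if (np.asarray(self.emission_sds) <= 0).any():
            raise ConfigError("emission_sds: must be strictly positive")
        mr = self.missing_rates
        if ((mr < 0) | (mr > 1)).any():
            raise ConfigError("missing_rates: must lie in [0, 1]")
        m = np.asarray(self.treatment_match_multiplier, float)
        if ((m <= 0) | (m > 1)).any():
            raise ConfigError("treatment_match_multiplier: must lie in (0, 1]")
        if not 0 <= self.match_transition_boost < 1:
            raise ConfigError("match_transition_boost: must lie in [0, 1)")
        bp = self.behaviour_policy_params
        if (bp[["fluid_sd", "vaso_sd"]].to_numpy() < 0).any():
            raise ConfigError("behaviour_policy_params: noise scales must be >= 0")
        oa = np.asarray(self.optimal_action)
        if oa.shape != (self.n_states, 2) or (oa < 0).any() or (oa > 4).any():
            raise ConfigError("optimal_action: must be (n_states, 2) bins in 0..4")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a generated cohort."""

    latent_state: pd.DataFrame  # patient_id, window, state
    died_90d: pd.Series  # per patient_id
    optimal_action: np.ndarray  # (S, 2)
    matched_fraction: pd.Series  # per patient_id, share of matched windows
    config: SynthConfig


# ---------------------------------------------------------------------------
# default configuration: the study conditions
# ---------------------------------------------------------------------------

# state-specific emission offsets in units of the feature's SD; unlisted
# (state, feature) pairs sit at the cohort baseline.
_BASELINES: dict[str, tuple[float, float]] = {
    # feature: (baseline mean, SD) in clinical units
    "heart_rate": (88, 14), "sbp": (122, 18), "mbp": (78, 12), "dbp": (60, 10),
    "spo2": (97, 2.2), "resp_rate": (19, 4.5), "temperature": (36.9, 0.7),
    "cvp": (8, 4), "albumin": (30, 6), "crp": (120, 70),
    "ast": (80, 55), "alt": (70, 48), "bicarbonate": (24.5, 3.5),
    "bilirubin": (14, 9), "bun": (10, 4.5), "calcium": (2.05, 0.18),
    "chloride": (104, 4.5), "potassium": (4.2, 0.45), "creatinine": (95, 45),
    "glucose": (7.2, 1.8), "hematocrit": (0.29, 0.04), "hemoglobin": (5.9, 0.9),
    "inr": (1.3, 0.3), "lactate": (1.7, 0.7), "pao2": (92, 18),
    "paco2": (42, 7), "ph": (7.40, 0.06), "platelets": (220, 80),
    "sodium": (140, 4.5), "wbc": (13, 4.5),
    "gcs_eye": (3.4, 0.7), "gcs_motor": (5.2, 1.0), "gcs_verbal": (2.6, 1.2),
    "peep": (8, 2.5), "rrt": (1.0, 0.01),
}

_STATE_SHIFTS: dict[str, dict[str, float]] = {
    # offsets in SD units
    "admission": {
        "temperature": 3.51, "heart_rate": 3.24, "wbc": 2.7, "glucose": 3.24,
        "crp": 1.76, "gcs_verbal": 1.35, "chloride": 2.03,
    },
    "renal": {
        "creatinine": 5.27, "bun": 4.59, "potassium": 2.16, "calcium": -1.35,
        "bicarbonate": -1.76,
    },
    "respiratory": {
        "pao2": -3.92, "paco2": 3.51, "spo2": -3.11, "resp_rate": 3.92,
        "gcs_verbal": -1.76, "peep": 1.35,
    },
    "shock": {
        "lactate": 4.05, "mbp": -3.24, "sbp": -2.7, "dbp": -2.43,
        "platelets": -2.7, "bilirubin": 2.7, "ph": -2.16, "inr": 2.03,
        "gcs_verbal": -1.35, "peep": 1.62, "heart_rate": 1.35,
    },
    "recovering": {
        "lactate": -1.62, "gcs_verbal": 3.11, "gcs_eye": 1.62, "gcs_motor": 1.62,
        "heart_rate": -2.7, "resp_rate": -2.7, "crp": -1.35,
        "temperature": -2.03, "glucose": -2.03, "sodium": 1.62,
    },
    "partial_recovered": {
        "creatinine": 1.62, "bun": 1.35, "hemoglobin": -4.05, "platelets": -2.03,
        "inr": 2.43, "wbc": 1.62, "gcs_verbal": 0.81, "bicarbonate": 2.03,
        "pao2": -1.62, "sodium": -2.03,
    },
}

# rows over (admission, renal, respiratory, shock, recovering,
# partial_recovered, discharge, death); death column = per-step hazard.
_DEFAULT_TRANSITIONS = np.array(
    [
        [0.322, 0.125, 0.135, 0.220, 0.140, 0.000, 0.052, 0.006],
        [0.000, 0.760, 0.000, 0.015, 0.090, 0.080, 0.052, 0.003],
        [0.000, 0.000, 0.744, 0.020, 0.090, 0.080, 0.062, 0.004],
        [0.000, 0.004, 0.004, 0.835, 0.004, 0.023, 0.000, 0.130],
        [0.000, 0.000, 0.000, 0.004, 0.550, 0.012, 0.432, 0.002],
        [0.000, 0.015, 0.015, 0.120, 0.090, 0.700, 0.030, 0.030],
    ]
)

_DEFAULT_BEHAVIOUR = pd.DataFrame(
    {
        "fluid_mean": [450.0, 150.0, 260.0, 850.0, 80.0, 260.0],
        "fluid_sd": [220.0, 130.0, 160.0, 320.0, 90.0, 160.0],
        "vaso_mean": [0.05, 0.02, 0.09, 0.38, 0.00, 0.09],
        "vaso_sd": [0.06, 0.04, 0.08, 0.16, 0.02, 0.08],
    },
    index=list(STATE_NAMES),
)

# planted per-state optimal treatment, as (fluid bin, vaso bin) of the
# generator's canonical 5x5 grid below (bin 0 = zero dose).
_DEFAULT_OPTIMAL = np.array([[3, 1], [1, 0], [2, 2], [3, 4], [1, 0], [2, 2]])
_DEFAULT_MULTIPLIER = np.array([0.25, 0.25, 0.25, 0.25, 0.25, 0.25])
_DEFAULT_PEEP_PROB = np.array([0.30, 0.05, 0.97, 0.85, 0.03, 0.80])
_DEFAULT_RRT_PROB = np.array([0.02, 0.95, 0.03, 0.45, 0.01, 0.85])
# frozen near the nonzero-dose quartiles of the default behaviour mixture
_DEFAULT_FLUID_EDGES = np.array([150.0, 300.0, 560.0])
_DEFAULT_VASO_EDGES = np.array([0.040, 0.090, 0.210])

_DEFAULT_MISSING = {
    "vitals": 0.06, "labs": 0.15, "gcs": 0.12,
    "albumin": 0.95, "crp": 0.96, "cvp": 0.95,
}


def default_missing_rates(specs: dict[str, FeatureSpec] | None = None) -> pd.Series:
    specs = specs or default_feature_specs()
    vitals = {"heart_rate", "sbp", "mbp", "dbp", "spo2", "resp_rate", "temperature"}
    rates = {}
    for name, s in specs.items():
        if name in ("albumin", "crp", "cvp"):
            rates[name] = _DEFAULT_MISSING[name]
        elif name in vitals:
            rates[name] = _DEFAULT_MISSING["vitals"]
        elif name.startswith("gcs"):
            rates[name] = _DEFAULT_MISSING["gcs"]
        elif s.role == "encoder_input":
            rates[name] = _DEFAULT_MISSING["labs"]
        else:  # treatment/outcome documentation is structurally complete
            rates[name] = 0.0
    return pd.Series(rates)


def default_config(n_patients: int = 1000, seed: int = 0, **overrides) -> SynthConfig:
    """The default study conditions (6 states, ~35% marginal mortality)."""
    feats = [f for f in _BASELINES]
    means = pd.DataFrame(
        {f: np.full(len(STATE_NAMES), float(_BASELINES[f][0])) for f in feats},
        index=list(STATE_NAMES),
    )
    sds = pd.DataFrame(
        {f: np.full(len(STATE_NAMES), float(_BASELINES[f][1])) for f in feats},
        index=list(STATE_NAMES),
    )
    for state, shifts in _STATE_SHIFTS.items():
        for f, k in shifts.items():
            if f in means.columns:
                means.loc[state, f] += k * _BASELINES[f][1]
    cfg = SynthConfig(
        n_patients=n_patients,
        transition_probs=_DEFAULT_TRANSITIONS.copy(),
        emission_means=means,
        emission_sds=sds,
        missing_rates=default_missing_rates(),
        behaviour_policy_params=_DEFAULT_BEHAVIOUR.copy(),
        optimal_action=_DEFAULT_OPTIMAL.copy(),
        treatment_match_multiplier=_DEFAULT_MULTIPLIER.copy(),
        peep_prob=_DEFAULT_PEEP_PROB.copy(),
        rrt_prob=_DEFAULT_RRT_PROB.copy(),
        fluid_edges=_DEFAULT_FLUID_EDGES.copy(),
        vaso_edges=_DEFAULT_VASO_EDGES.copy(),
        seed=seed,
    )
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def behaviour_policy(
    state: int | str, params: pd.DataFrame, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw one (fluid mL/window, vasopressor ug/kg/min) treatment.

    Gaussian around the state's configured means, clamped at zero (so states
    with small means produce genuine zero-dose windows).
    """
    if isinstance(state, (int, np.integer)):
        if not 0 <= state < len(params):
            raise ValueError(f"unknown state id {state}")
        row = params.iloc[int(state)]
    else:
        if state not in params.index:
            raise ValueError(f"unknown state id {state!r}")
        row = params.loc[state]
    fluid = row.fluid_mean + row.fluid_sd * rng.standard_normal()
    vaso = row.vaso_mean + row.vaso_sd * rng.standard_normal()
    return max(float(fluid), 0.0), max(float(vaso), 0.0)


def apply_missingness(
    events: pd.DataFrame, rates: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Independently drop each event with its feature's missingness rate."""
    present = events["variable"].unique()
    missing = [v for v in present if v not in rates.index]
    if missing:
        raise ValueError(f"missing_rates undefined for variables: {missing}")
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("missing_rates: must lie in [0, 1]")
    p = rates.reindex(events["variable"]).to_numpy()
    keep = rng.random(len(events)) >= p
    return events.loc[keep].reset_index(drop=True)


def _bin_dose(dose: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """5-level discretization: bin 0 = zero dose, bins 1..4 by the edges."""
    out = np.searchsorted(edges, dose, side="right") + 1
    out[dose <= 0] = 0
    return out


def _sample_paths(
    config: SynthConfig, rng: np.random.Generator, age_z: np.ndarray | None = None
):
    """Latent trajectories plus per-window treatments and match flags.

    ``age_z`` (per-patient standardized age) scales every death hazard by
    exp(beta * z - beta^2/2); None disables the frailty effect.
    """
    S = config.n_states
    rows = []  # (patient, window, state, fluid, vaso, matched)
    died = np.zeros(config.n_patients, bool)
    bp = config.behaviour_policy_params
    fl_mean = bp["fluid_mean"].to_numpy()
    fl_sd = bp["fluid_sd"].to_numpy()
    va_mean = bp["vaso_mean"].to_numpy()
    va_sd = bp["vaso_sd"].to_numpy()
    shock = 3 if config.n_states > 3 else None
    beta = config.age_mortality_beta
    if age_z is None:
        frailty = np.ones(config.n_patients)
    else:
        frailty = np.exp(beta * np.asarray(age_z) - beta**2 / 2.0)
    for pid in range(config.n_patients):
        s = config.admission_state
        run = 0  # consecutive windows already spent in the shock state
        for w in range(config.max_windows):
            fluid = max(fl_mean[s] + fl_sd[s] * rng.standard_normal(), 0.0)
            vaso = max(va_mean[s] + va_sd[s] * rng.standard_normal(), 0.0)
            fbin = _bin_dose(np.array([fluid]), config.fluid_edges)[0]
            vbin = _bin_dose(np.array([vaso]), config.vaso_edges)[0]
            matched = bool(
                fbin == config.optimal_action[s, 0]
                and vbin == config.optimal_action[s, 1]
            )
            rows.append((pid, w, s, fluid, vaso, matched))
            p = config.transition_probs[s].astype(float).copy()
            if s == shock and config.shock_hazard_escalation > 0:
                h0 = p[-1]
                h = min(h0 + config.shock_hazard_escalation * run, config.shock_hazard_cap)
                p[-1] = h
                p[:-1] *= (1.0 - h) / (1.0 - h0)
            if frailty[pid] != 1.0 and 0 < p[-1] < 1:
                h0 = p[-1]
                # survival-exponent form stays effective at high hazards
                h = 1.0 - (1.0 - h0) ** frailty[pid]
                p[-1] = h
                p[:-1] *= (1.0 - h) / (1.0 - h0)
            if matched:
                hazard = p[-1]
                p[-1] = hazard * config.treatment_match_multiplier[s]
                if 1.0 - hazard > 0:
                    p[:-1] *= (1.0 - p[-1]) / (1.0 - hazard)
                b = config.match_transition_boost
                donor = p[:S].sum() + p[S]  # non-death mass
                if donor > 0 and b > 0:
                    shift = min(b, p[:S].sum() * 0.9)
                    p[:S] *= 1.0 - shift / max(p[:S].sum(), 1e-12)
                    # recovery-directed mass: recovering state and discharge
                    # (already-recovering patients go straight to discharge)
                    if s == 4:
                        p[S] += shift
                    else:
                        p[4] += shift * 0.6
                        p[S] += shift * 0.4
            elif s != shock and config.mismatch_relapse > 0 and shock is not None:
                m = min(config.mismatch_relapse, p[:S].sum() * 0.5)
                p[:S] *= 1.0 - m / max(p[:S].sum(), 1e-12)
                p[shock] += m
            nxt = rng.choice(S + 2, p=p / p.sum())
            if nxt == S:  # discharge
                break
            if nxt == S + 1:  # death
                died[pid] = True
                break
            run = run + 1 if (nxt == shock and s == shock) else 0
            s = nxt
    frame = pd.DataFrame(
        rows, columns=["patient_id", "window", "state", "fluid", "vaso", "matched"]
    )
    return frame, died


_VITALS_2X = ("heart_rate", "sbp", "mbp", "dbp", "spo2", "resp_rate", "temperature")
_GCS_MAX = {"gcs_eye": 4, "gcs_motor": 6, "gcs_verbal": 5}


def generate_cohort(
    config: SynthConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a cohort; returns (event table, admission table, truth).

    Event table columns: patient_id, time_offset_hours, variable, value.
    Admission table columns: patient_id, los_hours, age, weight, height,
    gender, died_90d.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    specs = default_feature_specs()
    age = np.clip(
        config.age_mean + config.age_sd * rng.standard_normal(config.n_patients), 18, 100
    )
    age_z = (age - config.age_mean) / config.age_sd
    paths, died = _sample_paths(config, rng, age_z=age_z)
    n_rows = len(paths)
    state = paths["state"].to_numpy()
    win = paths["window"].to_numpy()
    pid = paths["patient_id"].to_numpy()

    chunks: list[pd.DataFrame] = []

    def emit(pids, times, variable, values):
        chunks.append(
            pd.DataFrame(
                {
                    "patient_id": pids,
                    "time_offset_hours": times,
                    "variable": variable,
                    "value": values,
                }
            )
        )

    means = config.emission_means
    sds = config.emission_sds
    for f in means.columns:
        if f in ("peep", "rrt"):
            continue
        reps = 2 if f in _VITALS_2X else 1
        for _ in range(reps):
            v = means[f].to_numpy()[state] + sds[f].to_numpy()[state] * rng.standard_normal(n_rows)
            lo, hi = specs[f].outlier_min, specs[f].outlier_max
            if f in _GCS_MAX:
                v = np.clip(np.round(v), 1, _GCS_MAX[f])
            else:
                v = np.clip(v, lo, hi)
            art = rng.random(n_rows) < config.artifact_rate
            v = np.where(art, hi * (1.5 + np.abs(rng.standard_normal(n_rows))), v)
            t = (win + rng.random(n_rows)) * WINDOW_HOURS
            emit(pid, t, f, v)

    # ventilation / renal-support documentation (state-dependent presence)
    for f, prob in (("peep", config.peep_prob), ("rrt", config.rrt_prob)):
        mask = rng.random(n_rows) < prob[state]
        if f == "peep":
            v = means[f].to_numpy()[state] + sds[f].to_numpy()[state] * rng.standard_normal(n_rows)
            v = np.clip(v, 0, specs["peep"].outlier_max)
        else:
            v = np.ones(n_rows)
        t = (win + rng.random(n_rows)) * WINDOW_HOURS
        emit(pid[mask], t[mask], f, v[mask])

    # treatments: fluid as two bolus events summing to the window total,
    # vasopressor as a single rate event (max-aggregated downstream)
    fluid = paths["fluid"].to_numpy()
    vaso = paths["vaso"].to_numpy()
    fpos = fluid > 0
    u = rng.uniform(0.2, 0.8, n_rows)
    t1 = (win + rng.uniform(0, 0.5, n_rows)) * WINDOW_HOURS
    t2 = (win + rng.uniform(0.5, 1.0, n_rows)) * WINDOW_HOURS
    emit(pid[fpos], t1[fpos], "iv_fluid", (fluid * u)[fpos])
    emit(pid[fpos], t2[fpos], "iv_fluid", (fluid * (1 - u))[fpos])
    vpos = vaso > 0
    emit(pid[vpos], ((win + rng.random(n_rows)) * WINDOW_HOURS)[vpos], "vasopressor", vaso[vpos])

    events = pd.concat(chunks, ignore_index=True)
    events = apply_missingness(events, config.missing_rates, rng)
    events = events.sort_values(
        ["patient_id", "time_offset_hours", "variable"], kind="mergesort"
    ).reset_index(drop=True)

    n_windows = paths.groupby("patient_id")["window"].max() + 1
    n_windows = n_windows.reindex(range(config.n_patients))
    los = n_windows.to_numpy() * WINDOW_HOURS - rng.uniform(0.0, 0.5, config.n_patients)
    # clamp any event past the (jittered) discharge time back inside the stay
    ev_los = los[events["patient_id"].to_numpy()]
    events["time_offset_hours"] = np.minimum(events["time_offset_hours"], ev_los - 1e-6)

    weight = config.weight_mean + config.weight_sd * rng.standard_normal(config.n_patients)
    height = config.height_mean + config.height_sd * rng.standard_normal(config.n_patients)
    weight[rng.random(config.n_patients) < config.demog_missing_prob] = np.nan
    height[rng.random(config.n_patients) < config.demog_missing_prob] = np.nan
    admissions = pd.DataFrame(
        {
            "patient_id": np.arange(config.n_patients),
            "los_hours": los,
            "age": age,
            "weight": np.clip(weight, 35, 250),
            "height": np.clip(height, 120, 220),
            "gender": (rng.random(config.n_patients) < config.p_male).astype(int),
            "died_90d": died.astype(int),
        }
    )
    matched_frac = paths.groupby("patient_id")["matched"].mean()
    truth = GroundTruth(
        latent_state=paths[["patient_id", "window", "state"]].copy(),
        died_90d=pd.Series(died.astype(int), index=range(config.n_patients)),
        optimal_action=config.optimal_action.copy(),
        matched_fraction=matched_frac,
        config=config,
    )
    return events, admissions, truth
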