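"""Synthetic study generation with known ground truth.

The generator emulates the study conditions the analysis assumes: ~47
subjects in a 2 x 2 within design (stimulation condition x testing day),
binomial recall out of 40, a left-skewed pitch-index distribution on
[-1, 1] (mean ~0.36, SD ~0.33), pedaling near 1 Hz with condition-
dependent variability (isochronous: positive speed bias, lower
dispersion), and subject covariates (sleep, musical training, languages,
sex, session order).

Recall is generated *through the fitted model's own design builder*: the
truth is a packed parameter vector for the same ``ModelSpec`` that the
pipeline fits, so recovery experiments compare estimates and truth on
identical coordinates.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from . import mfpsy, motor, pipeline
from .bglmm.model import BuiltModel, ModelSpec, build_model
from .bglmm.sampler import sample_posterior
from .bglmm.summaries import hdi

__all__ = [
    "TruthParams",
    "StudyBundle",
    "gen_subjects",
    "gen_recall",
    "gen_pedaling",
    "simulate_mf_responses",
    "generate_study",
    "recovery_experiment",
    "save_truth",
    "load_truth",
]


@dataclass
class TruthParams:
    """Generating parameters.

    Regression coefficients are on the *built design scale*: orthonormal
    factor contrasts (for 2-level factors the first sorted level carries
    +1/sqrt(2)) and standardized continuous covariates.  Consequences of
    the coding: ``day_beta > 0`` means better recall on day 1 (forgetting
    overnight); ``session_beta < 0`` means better recall in session 2;
    ``condition_beta > 0`` means better recall under isochronous
    stimulation.  Defaults anchor the response-scale magnitudes near one
    word of forgetting, 1.5 words of session gain, and half a word of
    condition advantage at the ~8.5/40 baseline.
    """

    # recall model (link scale, built-design coordinates)
    intercept: float = -1.30
    condition_beta: float = 0.04
    day_beta: float = 0.10
    cond_day_beta: float = 0.0
    session_beta: float = -0.18
    pitch_beta: float = 0.10
    pitch_cond_beta: float = 0.0
    pitch_day_beta: float = 0.0
    pitch_cond_day_beta: float = 0.0
    music_beta: float = 0.05
    sleep_between_beta: float = 0.05
    sleep_within_beta: float = 0.03
    sleep_within_day_beta: float = 0.0
    lang_beta: float = 0.15
    lang_simplex: tuple = (0.5, 0.3, 0.2)
    sd_intercept: float = 0.8
    sd_condition: float = 0.20
    sd_day: float = 0.15
    sd_sleep_c: float = 0.05
    # pitch-index population (Beta on [-1, 1], moment-matched)
    pitch_mean: float = 0.36
    pitch_sd: float = 0.33
    # pedaling
    target_speed_hz: float = 1.0
    iso_speed_bias: float = 0.07
    self_speed_bias: float = 0.04
    subject_speed_sd: float = 0.05
    cv_iso: float = 0.045
    cv_self: float = 0.07
    subject_cv_spread: float = 0.30
    # MF observer
    mf_weight: float = 0.8

    def validate(self):
        for f in ("sd_intercept", "sd_condition", "sd_day", "sd_sleep_c"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.target_speed_hz <= 0:
            raise ValueError("target_speed_hz must be > 0")
        for f in ("cv_iso", "cv_self"):
            if getattr(self, f) < 0:  # 0 = degenerate noiseless pedaling
                raise ValueError(f"{f} must be >= 0")
        if abs(sum(self.lang_simplex) - 1.0) > 1e-8:
            raise ValueError("lang_simplex must sum to 1")
        return self


@dataclass
class StudyBundle:
    study_table: pd.DataFrame
    truth: TruthParams
    seed: int
    theta_true: np.ndarray | None = None
    model: BuiltModel | None = None
    pedal_timestamps: pd.DataFrame | None = None
    mf_responses: pd.DataFrame | None = None
    mf_scores: pd.DataFrame | None = None


def save_truth(truth: TruthParams, path):
    d = asdict(truth)
    d["lang_simplex"] = list(d["lang_simplex"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def load_truth(path) -> TruthParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["lang_simplex"] = tuple(d["lang_simplex"])
    return TruthParams(**d)


# ---------------------------------------------------------------------------
# subjects


def _beta_params_on_interval(mean, sd):
    """Method-of-moments Beta(a, b) for a variable on [-1, 1]."""
    m = (mean + 1.0) / 2.0
    s = sd / 2.0
    if not 0 < m < 1:
        raise ValueError(f"mean {mean} outside (-1, 1)")
    nu = m * (1 - m) / s**2 - 1.0
    if nu <= 0:
        raise ValueError(
            f"infeasible mean/SD combination for the Beta family: mean={mean}, sd={sd}"
        )
    return m * nu, (1 - m) * nu


def gen_subjects(n: int, seed: int = 0, truth: TruthParams | None = None) -> pd.DataFrame:
    """Per-subject covariates: left-skewed pitch index, balanced sex,
    zero-inflated musical training, 0-3 foreign languages, habitual sleep."""
    if n < 2:
        raise ValueError("need at least 2 subjects")
    truth = truth or TruthParams()
    rng = np.random.default_rng(seed)
    a, b = _beta_params_on_interval(truth.pitch_mean, truth.pitch_sd)
    pitch = 2.0 * rng.beta(a, b, n) - 1.0
    sex = np.array(["f", "m"] * (n // 2 + 1))[:n]
    rng.shuffle(sex)
    plays = rng.random(n) < 0.5
    music = np.where(plays, np.round(rng.gamma(2.0, 4.0, n), 1), 0.0)
    langs = np.minimum(rng.poisson(1.2, n), 3)
    sleep_base = rng.normal(7.2, 0.7, n)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "pitch_index": pitch,
            "sex": sex,
            "music_years": music,
            "n_languages": langs,
            "sleep_base_h": sleep_base,
        }
    )


def _long_table(subjects: pd.DataFrame, seed: int) -> pd.DataFrame:
    """4 rows per subject: session 1/2 x day 1/2, condition order balanced."""
    rng = np.random.default_rng(seed)
    n = len(subjects)
    order = rng.permutation(n)
    iso_first = np.zeros(n, dtype=bool)
    iso_first[order[: n // 2 + n % 2]] = True
    rows = []
    for i, subj in subjects.reset_index(drop=True).iterrows():
        conds = (
            ["isochronous", "self_initiated"]
            if iso_first[i]
            else ["self_initiated", "isochronous"]
        )
        sleep = subj.sleep_base_h + rng.normal(0, 0.6, 2)
        for session in (1, 2):
            for day in (1, 2):
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "session": session,
                        "condition": conds[session - 1],
                        "day": day,
                        "trials": pipeline.N_TRIALS,
                        "pitch_index": subj.pitch_index,
                        "music_years": subj.music_years,
                        "n_languages": subj.n_languages,
                        "sleep_h": round(float(sleep[session - 1]), 2),
                        "sex": subj.sex,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recall


_BETA_FIELD_BY_COLUMN = {
    "Intercept": "intercept",
    "condition.c1": "condition_beta",
    "day.c1": "day_beta",
    "condition.c1:day.c1": "cond_day_beta",
    "session.c1": "session_beta",
    "pitch_index": "pitch_beta",
    "pitch_index:condition.c1": "pitch_cond_beta",
    "pitch_index:day.c1": "pitch_day_beta",
    "pitch_index:condition.c1:day.c1": "pitch_cond_day_beta",
    "music_years": "music_beta",
    "sleep_mean": "sleep_between_beta",
    "sleep_c": "sleep_within_beta",
    "sleep_c:day.c1": "sleep_within_day_beta",
    # linear (null-space) columns of smooths map to the same fields
    "s(pitch_index).lin": "pitch_beta",
    "s(music_years).lin": "music_beta",
    "s(sleep_mean).lin": "sleep_between_beta",
}

_RANDOM_SD_BY_COLUMN = {
    "Intercept": "sd_intercept",
    "condition.c1": "sd_condition",
    "day.c1": "sd_day",
    "sleep_c": "sd_sleep_c",
}


def true_theta(model: BuiltModel, truth: TruthParams, rng: np.random.Generator):
    """Pack a truth vector for a built recall model.

    Fixed columns are looked up by name (unknown columns get 0); smooth
    wiggliness is zero (only the linear null-space part carries effect);
    the monotonic simplex and scale come from the truth; group effects are
    drawn from independent normals with the truth SDs (non-centered:
    z standard normal, Cholesky diagonal = SDs).
    """
    th = np.zeros(model.n_params)
    beta = np.array(
        [
            getattr(truth, _BETA_FIELD_BY_COLUMN[c]) if c in _BETA_FIELD_BY_COLUMN else 0.0
            for c in model.colnames
        ]
    )
    th[model.slices["beta"]] = beta
    for i, s in enumerate(model.smooths):
        th[model.slices[("smooth", i, "z")]] = 0.0
        th[model.slices[("smooth", i, "log_tau")]] = np.log(1e-8)
    for i, m in enumerate(model.monos):
        th[model.slices[("mono", i, "beta")]] = truth.lang_beta
        zeta = np.asarray(truth.lang_simplex[: m.D], dtype=float)
        zeta = zeta / zeta.sum()
        th[model.slices[("mono", i, "u")]] = np.log(zeta[:-1]) - np.log(zeta[-1])
    for i, rb in enumerate(model.randoms):
        sds = np.array(
            [
                max(getattr(truth, _RANDOM_SD_BY_COLUMN.get(w, "sd_intercept")), 1e-8)
                if w in _RANDOM_SD_BY_COLUMN
                else 1e-8
                for w in rb.w_names
            ]
        )
        th[model.slices[("rand", i, "log_d")]] = np.log(sds)
        th[model.slices[("rand", i, "z")]] = rng.standard_normal(rb.J * rb.q)
    return th


def gen_recall(
    table: pd.DataFrame,
    truth: TruthParams,
    seed: int,
    spec: ModelSpec | None = None,
):
    """Sample recall counts through the recall model's own linear-predictor
    builder (generator and fitting spec share one code path).

    Returns ``(table, theta_true, model)`` with the ``recalled`` column
    filled in.
    """
    truth.validate()
    spec = spec or pipeline.memory_model_spec("linear")
    table = pipeline.add_sleep_components(table)
    table = table.copy()
    table["recalled"] = 0  # placeholder so the model can be built
    model = build_model(spec, table)
    rng = np.random.default_rng(seed)
    th = true_theta(model, truth, rng)
    eta = model.eta(th, include_random=True)
    y = rng.binomial(table["trials"].to_numpy(), expit(eta))
    table["recalled"] = y
    model = build_model(spec, table)  # rebuilt with the realized response
    return table, th, model


# ---------------------------------------------------------------------------
# pedaling


def gen_pedaling(
    subjects: pd.DataFrame,
    truth: TruthParams,
    seed: int,
    n_revolutions: int = 1560,
    conditions_by_session: dict | None = None,
) -> pd.DataFrame:
    """Revolution timestamps per subject x session: lognormal durations
    with subject- and condition-specific level and dispersion.  The
    isochronous condition carries the configured positive speed bias and
    the lower dispersion."""
    truth.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for i, subj in subjects.reset_index(drop=True).iterrows():
        mult = np.exp(rng.normal(0.0, truth.subject_speed_sd))
        cv_mult = np.exp(rng.normal(0.0, truth.subject_cv_spread))
        sess_conds = (
            conditions_by_session[subj.subject_id]
            if conditions_by_session
            else {1: "isochronous", 2: "self_initiated"}
        )
        for session, cond in sess_conds.items():
            bias = truth.iso_speed_bias if cond == "isochronous" else truth.self_speed_bias
            speed = truth.target_speed_hz * (1.0 + bias) * mult
            sdlog = (truth.cv_iso if cond == "isochronous" else truth.cv_self) * cv_mult
            mean_dur = 1.0 / speed
            if sdlog > 0:
                d = np.exp(rng.normal(np.log(mean_dur) - 0.5 * sdlog**2, sdlog, n_revolutions))
            else:
                d = np.full(n_revolutions, mean_dur)
            t = np.cumsum(d)
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subj.subject_id,
                        "session": session,
                        "condition": cond,
                        "time_s": t,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def motor_summaries(timestamps: pd.DataFrame) -> pd.DataFrame:
    """Per subject x session summaries via the crossing-time metrics
    (shared code path with the measurement module), plus the observed SD
    of the instantaneous speed (passed to the speed model as known
    observation noise)."""
    out = motor.summaries_from_table(timestamps)
    sds = []
    for (subj, sess, cond), grp in timestamps.groupby(
        ["subject_id", "session", "condition"], sort=True
    ):
        d = np.diff(np.sort(grp["time_s"].to_numpy()))
        s = 1.0 / d
        sds.append(float(np.std(s, ddof=1)))
    out["speed_se"] = sds
    return out


# ---------------------------------------------------------------------------
# MF observer


def simulate_mf_responses(
    subjects: pd.DataFrame,
    battery: mfpsy.TestBattery,
    truth: TruthParams,
    seed: int,
) -> pd.DataFrame:
    """Bernoulli observer: P(spectral | pair) = invlogit(theta_subj +
    w * difficulty), theta mapped from the subject's latent pitch index and
    difficulty a standardized function of the pair's harmonic order and
    register (higher sounding harmonics and higher register push towards
    spectral listening)."""
    truth.validate()
    rng = np.random.default_rng(seed)
    man = mfpsy.battery_manifest(battery)
    raw = 0.5 * (man["first_n_min"] + man["second_n_min"]).to_numpy().astype(float)
    reg = np.log2(np.sqrt((man["first_f0"] * man["second_f0"]).to_numpy()))
    z = (raw - raw.mean()) / raw.std() + 0.5 * (reg - reg.mean()) / reg.std()
    difficulty = z / np.std(z)
    pairs = list(battery.pairs)
    rows = []
    for _, subj in subjects.iterrows():
        theta = logit((np.clip(subj.pitch_index, -0.995, 0.995) + 1.0) / 2.0)
        p_spec = expit(theta + truth.mf_weight * difficulty)
        take_spectral = rng.random(len(pairs)) < p_spec
        for p, spec_resp in zip(pairs, take_spectral):
            direction = p.delta_fsp if spec_resp else p.delta_f0
            answer = "second_higher" if direction > 0 else "first_higher"
            rows.append(
                {"subject_id": subj.subject_id, "pair_id": p.pair_id, "answer": answer}
            )
    return pd.DataFrame(rows)


def score_mf_responses(battery: mfpsy.TestBattery, responses: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for subj, grp in responses.groupby("subject_id", sort=True):
        answers = dict(zip(grp["pair_id"], grp["answer"]))
        res = mfpsy.score_responses(battery, answers)
        rows.append(
            {"subject_id": subj, "delta_p": res.delta_p, "n_classified": res.n_classified}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study + recovery


def generate_study(
    truth: TruthParams | None = None,
    n_subjects: int = 47,
    seed: int = 0,
    spec: ModelSpec | None = None,
    with_motor: bool = True,
    with_mf: bool = False,
    n_revolutions: int = 1560,
    battery: mfpsy.TestBattery | None = None,
) -> StudyBundle:
    """Generate a full synthetic study, regenerable byte-identically from
    (truth, seed)."""
    truth = (truth or TruthParams()).validate()
    ss = np.random.SeedSequence(seed)
    s_subj, s_tab, s_rec, s_ped, s_mf = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    ]
    subjects = gen_subjects(n_subjects, s_subj, truth)
    table = _long_table(subjects, s_tab)

    pedal = mf_resp = mf_scores = None
    if with_motor:
        cond_map = {
            subj: dict(
                grp.drop_duplicates("session").set_index("session")["condition"]
            )
            for subj, grp in table.groupby("subject_id")
        }
        pedal = gen_pedaling(subjects, truth, s_ped, n_revolutions, cond_map)
        summ = motor_summaries(pedal)
        table = table.merge(
            summ.drop(columns=["session"]),
            on=["subject_id", "condition"],
            how="left",
        )
        table.loc[table["condition"] == "self_initiated", "ibd_s"] = 0.0
    table, theta, model = gen_recall(table, truth, s_rec, spec=spec)
    if with_mf:
        battery = battery or mfpsy.build_battery(order_seed=0)
        mf_resp = simulate_mf_responses(subjects, battery, truth, s_mf)
        mf_scores = score_mf_responses(battery, mf_resp)
    return StudyBundle(
        study_table=table,
        truth=truth,
        seed=seed,
        theta_true=theta,
        model=model,
        pedal_timestamps=pedal,
        mf_responses=mf_resp,
        mf_scores=mf_scores,
    )


def recovery_experiment(
    truth: TruthParams | None = None,
    n_subjects: int = 47,
    reps: int = 20,
    fit_config: dict | None = None,
    seed: int = 0,
    variant: str = "basic",
    monitor: tuple = ("day.c1", "condition.c1", "session.c1"),
) -> pd.DataFrame:
    """Repeated generate-and-refit: per replicate and monitored parameter,
    the posterior median, 90% HDI coverage of the truth, pd, and whether
    the posterior majority sign agrees with the truth.  Failed fits are
    recorded (status column), never dropped silently."""
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    truth = (truth or TruthParams()).validate()
    fit_config = dict(fit_config or {"chains": 4, "iterations": 600})
    spec = pipeline.memory_model_spec(variant)
    rows = []
    for rep in range(reps):
        rep_seed = (seed * 7919 + rep * 104729) % (2**31)
        try:
            bundle = generate_study(
                truth, n_subjects, rep_seed, spec=spec, with_motor=False
            )
            draws = sample_posterior(
                spec,
                bundle.study_table,
                seed=(rep_seed + 13) % (2**31),
                **fit_config,
            )
            rhat_max = float(draws.diagnostics["rhat"].max())
            for name in monitor:
                tv = float(bundle.theta_true[bundle.model.param_index(name)])
                x = draws.param(name)
                lo, hi = hdi(x, 0.90)
                share_pos = float(np.mean(x > 0))
                pd_val = max(share_pos, 1 - share_pos)
                rows.append(
                    {
                        "rep": rep,
                        "parameter": name,
                        "truth": tv,
                        "estimate": float(np.median(x)),
                        "hdi90_lo": lo,
                        "hdi90_hi": hi,
                        "covered": bool(lo <= tv <= hi),
                        "pd": pd_val,
                        "sign_agrees": bool((share_pos > 0.5) == (tv > 0))
                        if tv != 0
                        else None,
                        "rhat_max": rhat_max,
                        "status": "ok",
                    }
                )
        except Exception as exc:  # record, do not drop
            for name in monitor:
                rows.append(
                    {
                        "rep": rep,
                        "parameter": name,
                        "truth": np.nan,
                        "estimate": np.nan,
                        "hdi90_lo": np.nan,
                        "hdi90_hi": np.nan,
                        "covered": False,
                        "pd": np.nan,
                        "sign_agrees": None,
                        "rhat_max": np.nan,
                        "status": f"error: {exc}",
                    }
                )
    return pd.DataFrame(rows)
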