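"""Synthetic number-judgment error-awareness task.

This module generates the three layers of a simulated experiment with
*known* ground truth, so that every downstream analysis stage can be
validated by parameter recovery:

1. **Trial sequences** honoring the task's design constraints: 1,000 trials
   (800 standard, 100 number-target, 100 repeat-target), numbers 34-76
   excluding the reference 55, no two target trials adjacent, 50%
   incongruent, and counterbalanced congruent/incongruent transitions.
   A trial is *congruent* when the physical font size (small/large) matches
   the numerical magnitude (below/above 55).

2. **Behavioral responses**: log-RT as a linear combination of coded task
   regressors plus Gaussian noise; accuracy from a logistic model that
   includes log-RT (speed-accuracy trade-off); a forced-choice accuracy
   judgment on every trial whose latency operationalizes (inverse)
   confidence; error awareness assigned via a logistic function of trial RT
   and a latent error-evidence variable (aware errors are slower); and an
   additive post-error slowing applied only after aware errors.

3. **Response-locked EEG epochs** on a 61-channel ring montage: a
   fronto-central negative component peaking ~70 ms (ERN-like) and a
   centro-parietal positive component peaking ~230 ms (Pe-like) whose
   single-trial amplitudes are modulated by awareness, confidence and their
   interaction; a theta/alpha-band oscillation whose intertrial phase
   jitter is tighter on aware than unaware errors; all embedded in
   spatially correlated 1/f-like noise.

A single integer seed expands into independent substreams per stage, so
regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import EpochSet
from .montage import Montage, ring_montage, gaussian_topography

__all__ = [
    "TaskDesign", "GroundTruth", "generate_trial_sequence",
    "simulate_behavior", "simulate_eeg", "simulate_subject",
    "check_sequence", "trial_duration_bounds", "component_topographies",
]


# ---------------------------------------------------------------------------
# design and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskDesign:
    """Structural parameters of the number-judgment task."""

    n_trials: int = 1000
    n_standard: int = 800
    n_number_target: int = 100
    n_repeat_target: int = 100
    number_low: int = 34
    number_high: int = 76
    reference_number: int = 55
    target_numbers: tuple[int, int] = (49, 62)
    jitter_levels_ms: tuple[int, ...] = (300, 350, 400, 450)
    stim_deadline_ms: int = 1200
    blank_ms: int = 500
    judgment_deadline_ms: int = 1200
    incongruent_fraction: float = 0.5
    colors: tuple[str, ...] = ("red", "yellow", "green", "blue")
    max_attempts: int = 100

    def __post_init__(self) -> None:
        if self.n_standard + self.n_number_target + self.n_repeat_target \
                != self.n_trials:
            raise ValueError("trial-type counts must sum to n_trials")
        n_targets = self.n_number_target + self.n_repeat_target
        if n_targets > (self.n_trials + 1) // 2:
            raise ValueError("too many targets for a non-adjacent placement")
        if not 0.0 <= self.incongruent_fraction <= 1.0:
            raise ValueError("incongruent_fraction must lie in [0, 1]")


def trial_duration_bounds(design: TaskDesign) -> tuple[int, int]:
    """(min, max) total trial duration in ms, assuming deadline-length
    stimulus and judgment phases: jitter + stimulus + blank + judgment."""
    fixed = design.stim_deadline_ms + design.blank_ms \
        + design.judgment_deadline_ms
    return (min(design.jitter_levels_ms) + fixed,
            max(design.jitter_levels_ms) + fixed)


@dataclass(frozen=True)
class GroundTruth:
    """Injected effect sizes; recorded alongside outputs for recovery tests.

    RT betas act on natural-log RT (ms) with the same regressor coding the
    behavioral GLM uses (trial type / congruency / jitter coded -1/+1;
    distance, confidence and trial number centered, which shifts only the
    intercept).  Accuracy betas act on logit P(correct).  EEG amplitudes
    are in microvolts at the topography peak.
    """

    # -- behavior: log-RT model ------------------------------------------
    rt_betas: dict = field(default_factory=lambda: {
        "intercept": float(np.log(420.0)),  # ~420 ms baseline RT
        "trial_type": 0.031,      # targets slower (~+28 ms)
        "congruency": 0.006,      # incongruent slower (~+5 ms)
        "jitter": -0.030,         # long jitter faster (~-27 ms)
        "distance": -0.0045,      # numbers far from 55 judged faster
        "confidence": 0.040,      # slow previous judgment -> slower RT
        "trial_nr": -0.010,       # practice speed-up over the session
    })
    rt_noise_sd: float = 0.18     # log-RT residual SD
    pes_aware_ms: float = 11.5    # additive slowing after aware errors
    pes_unaware_ms: float = 0.0
    peri_aware_ms: float = 0.0    # congruency-effect change after aware errors

    # -- behavior: accuracy model ----------------------------------------
    acc_betas: dict = field(default_factory=lambda: {
        "intercept": 1.76,
        "trial_type": -1.02,      # targets much more error-prone
        "congruency": -0.10,
        "jitter": 0.0,
        "distance": 0.09,         # farther from 55 -> more accurate
        "confidence": 0.0,
        "log_rt": 1.20,           # slower -> more accurate
        "trial_nr": 0.0,
    })

    # -- awareness / judgment --------------------------------------------
    aware_intercept: float = 0.35     # ~58% aware at average RT/evidence
    aware_rt_slope: float = 0.9       # aware errors are slower
    aware_evidence_slope: float = 0.9
    p_correct_judged_correct: float = 0.93
    judgment_rt_log_mean: float = float(np.log(600.0))
    judgment_rt_log_sd: float = 0.25
    judgment_confidence_slope: float = 0.15  # strong evidence -> fast judgment
    miss_rate: float = 0.02
    multiple_rate: float = 0.01
    invalid_judgment_rate: float = 0.01

    # -- EEG --------------------------------------------------------------
    ern_base: float = 5.0         # ERN magnitude on errors (uV, negative-going)
    ern_correct_frac: float = 0.25
    ern_gain: float = 2.0         # awareness modulation (+1 aware / -1 unaware)
    ern_conf: float = 0.0         # per centered log judgment RT
    ern_interaction: float = 1.5
    pe_base: float = 6.0          # Pe magnitude on errors (uV, positive)
    pe_correct_frac: float = 0.2
    pe_gain: float = 3.0
    pe_conf: float = -2.3
    pe_interaction: float = -2.0
    ern_center_s: float = 0.070
    ern_width_s: float = 0.025
    pe_center_s: float = 0.230
    pe_width_s: float = 0.060
    osc_freq_hz: float = 9.0
    osc_amp: float = 3.0
    osc_center_s: float = 0.230
    osc_width_s: float = 0.080
    phase_lock_aware: float = 0.6     # phase-jitter SD (rad), aware errors
    phase_lock_unaware: float = 2.5
    noise_sd: float = 10.0            # uV per channel
    noise_spatial_scale: float = 0.35
    sfreq: float = 500.0
    resp_window: tuple[float, float] = (-0.5, 1.0)
    stim_window: tuple[float, float] = (-0.5, 2.5)

    seed: int = 0

    def validate(self) -> None:
        for name, val in {**self.rt_betas}.items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite RT beta {name}")
        if self.rt_noise_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if np.exp(self.rt_betas["intercept"]) + min(
                0.0, self.pes_aware_ms) <= 0:
            raise ValueError("parameters imply non-positive RT")


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("sequence", "behavior", "eeg")
    return {n: np.random.default_rng(s)
            for n, s in zip(names, ss.spawn(len(names)))}


# ---------------------------------------------------------------------------
# trial sequence
# ---------------------------------------------------------------------------

def _place_targets(design: TaskDesign, rng: np.random.Generator) -> np.ndarray:
    """Trial-type array with no two targets adjacent, repeat never first."""
    n = design.n_trials
    k = design.n_number_target + design.n_repeat_target
    types = np.full(n, "standard", dtype=object)
    if k == 0:
        return types
    for _ in range(design.max_attempts):
        # uniform sample of k pairwise non-adjacent positions out of n
        base = np.sort(rng.choice(n - k + 1, size=k, replace=False))
        positions = base + np.arange(k)
        labels = np.array(["number_target"] * design.n_number_target
                          + ["repeat_target"] * design.n_repeat_target,
                          dtype=object)
        rng.shuffle(labels)
        if positions[0] == 0 and labels[0] == "repeat_target":
            swap = np.flatnonzero(labels == "number_target")
            if swap.size == 0:
                continue  # resample: no number target to put first
            labels[[0, swap[0]]] = labels[[swap[0], 0]]
        types[positions] = labels
        return types
    raise RuntimeError("could not place targets without adjacency "
                       f"after {design.max_attempts} attempts")


def _congruency_sequence(design: TaskDesign,
                         rng: np.random.Generator) -> np.ndarray:
    """Half-incongruent sequence with counterbalanced transitions.

    Built from alternating runs.  With ``r`` runs there are ``r - 1``
    switch transitions and ``n - r`` stay transitions, so ``r`` is chosen
    to make the four transition counts (cc, ci, ic, ii) as equal as
    possible; run lengths are then drawn as uniform random compositions.
    """
    n = design.n_trials
    n_inc = int(round(design.incongruent_fraction * n))
    n_con = n - n_inc
    if n_con == 0 or n_inc == 0:
        seq = np.full(n, n_con == 0)
        return np.where(seq, "incongruent", "congruent")

    def spread(r: int, first_inc: bool) -> int:
        r1, r2 = (r + 1) // 2, r // 2
        nf, ns = (n_inc, n_con) if first_inc else (n_con, n_inc)
        if nf < r1 or ns < r2 or r2 < 1:
            return 10**9
        stays = [nf - r1, ns - r2]
        switches = [(r - 1 + 1) // 2, (r - 1) // 2]
        counts = stays + switches
        return max(counts) - min(counts)

    first_inc = bool(rng.integers(2))
    candidates = range(max(2, (n + 1) // 2 - 2), (n + 1) // 2 + 3)
    r = min(candidates, key=lambda rr: spread(rr, first_inc))
    if spread(r, first_inc) >= 10**9:
        raise RuntimeError("no counterbalanced run structure found")
    r1, r2 = (r + 1) // 2, r // 2
    nf, ns = (n_inc, n_con) if first_inc else (n_con, n_inc)

    def composition(total: int, parts: int) -> np.ndarray:
        if parts == 1:
            return np.array([total])
        cuts = np.sort(rng.choice(total - 1, size=parts - 1, replace=False))
        return np.diff(np.concatenate([[0], cuts + 1, [total]]))

    runs_f = composition(nf, r1)
    runs_s = composition(ns, r2)
    seq = []
    for i in range(r):
        length = runs_f[i // 2] if i % 2 == 0 else runs_s[i // 2]
        val = first_inc if i % 2 == 0 else not first_inc
        seq.extend([val] * int(length))
    seq = np.array(seq)
    return np.where(seq, "incongruent", "congruent")


def generate_trial_sequence(design: TaskDesign | None = None,
                            seed: int | np.random.Generator = 0
                            ) -> pd.DataFrame:
    """Stimulus-side trial table honoring all task constraints."""
    design = design or TaskDesign()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    types = _place_targets(design, rng)
    congruency = _congruency_sequence(design, rng)

    lo, hi, ref = design.number_low, design.number_high, design.reference_number
    specials = set(design.target_numbers) | {ref}
    standard_pool = np.array([x for x in range(lo, hi + 1)
                              if x not in specials])
    numbers = np.empty(design.n_trials, dtype=np.int64)
    prev = None
    for t in range(design.n_trials):
        if types[t] == "repeat_target":
            numbers[t] = prev
        elif types[t] == "number_target":
            choices = [x for x in design.target_numbers if x != prev]
            numbers[t] = rng.choice(choices)
        else:
            pool = standard_pool[standard_pool != prev] \
                if prev is not None else standard_pool
            numbers[t] = rng.choice(pool)
        prev = numbers[t]

    large = (numbers > ref) ^ (congruency == "incongruent")
    df = pd.DataFrame({
        "trial_nr": np.arange(1, design.n_trials + 1),
        "number": numbers,
        "trial_type": types,
        "font_size": np.where(large, "large", "small"),
        "color": rng.choice(design.colors, size=design.n_trials),
        "congruency": congruency,
        "jitter_ms": rng.choice(design.jitter_levels_ms,
                                size=design.n_trials),
        "distance": np.abs(numbers - ref),
    })
    violations = check_sequence(df, design)
    if violations:
        raise RuntimeError(f"generated sequence violates: {violations}")
    return df


def check_sequence(df: pd.DataFrame, design: TaskDesign) -> list[str]:
    """Exhaustive scan of a trial table against the design invariants."""
    problems = []
    counts = df["trial_type"].value_counts()
    for key, want in (("standard", design.n_standard),
                      ("number_target", design.n_number_target),
                      ("repeat_target", design.n_repeat_target)):
        if counts.get(key, 0) != want:
            problems.append(f"{key} count {counts.get(key, 0)} != {want}")
    is_target = (df["trial_type"] != "standard").to_numpy()
    if np.any(is_target[:-1] & is_target[1:]):
        problems.append("adjacent target trials")
    n_inc = int((df["congruency"] == "incongruent").sum())
    want_inc = design.incongruent_fraction * len(df)
    if abs(n_inc - want_inc) > 1:
        problems.append(f"incongruent count {n_inc} != {want_inc} +- 1")
    inc = (df["congruency"] == "incongruent").to_numpy()
    trans = np.array([
        np.sum(~inc[:-1] & ~inc[1:]), np.sum(~inc[:-1] & inc[1:]),
        np.sum(inc[:-1] & ~inc[1:]), np.sum(inc[:-1] & inc[1:]),
    ])
    if 0 < n_inc < len(df) and trans.max() - trans.min() > 2:
        problems.append(f"transition counts {trans.tolist()} not balanced")
    num = df["number"].to_numpy()
    rep = (df["trial_type"] == "repeat_target").to_numpy()
    if rep[0] or np.any(num[1:][rep[1:]] != num[:-1][rep[1:]]):
        problems.append("repeat target does not repeat previous number")
    std = (df["trial_type"] == "standard").to_numpy()
    if np.any(num[1:][std[1:]] == num[:-1][std[1:]]):
        problems.append("standard trial repeats previous number")
    ref = design.reference_number
    large = (df["font_size"] == "large").to_numpy()
    congr = (df["congruency"] == "congruent").to_numpy()
    if np.any(congr != (large == (num > ref))):
        problems.append("congruency inconsistent with font size / magnitude")
    return problems


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _centered(design: TaskDesign):
    """Centering constants used by the generative models (slopes are
    unaffected by centering; it only keeps the intercept interpretable)."""
    lo, hi, ref = design.number_low, design.number_high, design.reference_number
    dist_center = (1 + max(hi - ref, ref - lo)) / 2.0
    trialnr_center = float(np.mean(np.log(np.arange(1, design.n_trials + 1))))
    return dist_center, trialnr_center


def simulate_behavior(trials: pd.DataFrame, truth: GroundTruth | None = None,
                      design: TaskDesign | None = None,
                      seed: int | np.random.Generator | None = None
                      ) -> pd.DataFrame:
    """Fill response columns of a stimulus-side trial table.

    Trials are generated sequentially because several regressors carry over
    from the previous trial (judgment latency, previous accuracy /
    awareness for post-error slowing).
    """
    truth = truth or GroundTruth()
    truth.validate()
    design = design or TaskDesign()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(truth.seed if seed is None else seed)

    n = len(trials)
    dist_center, trialnr_center = _centered(design)
    rb, ab = truth.rt_betas, truth.acc_betas

    tt = np.where(trials["trial_type"] == "standard", -1.0, 1.0)
    cg = np.where(trials["congruency"] == "incongruent", 1.0, -1.0)
    jt = np.where(np.isin(trials["jitter_ms"],
                          np.sort(design.jitter_levels_ms)[2:]), 1.0, -1.0)
    dist = trials["distance"].to_numpy(float) - dist_center
    logtn = np.log(trials["trial_nr"].to_numpy(float)) - trialnr_center

    rt_noise = rng.normal(0.0, truth.rt_noise_sd, size=n)
    ev = rng.normal(0.0, 1.0, size=n)  # latent error evidence
    u_acc = rng.uniform(size=n)
    u_jcorr = rng.uniform(size=n)
    u_aware = rng.uniform(size=n)
    u_miss = rng.uniform(size=n)
    u_mult = rng.uniform(size=n)
    u_inv = rng.uniform(size=n)
    jrt_noise = rng.normal(0.0, truth.judgment_rt_log_sd, size=n)
    wrong_btn = rng.integers(0, 2, size=n)

    cols = {k: np.empty(n, dtype=object) for k in
            ("response", "accuracy", "judgment", "awareness")}
    rt_ms = np.full(n, np.nan)
    judgment_rt_ms = np.full(n, np.nan)
    prev_jrt = np.exp(truth.judgment_rt_log_mean)  # neutral for trial 1
    prev_aware = False
    prev_unaware = False

    for t in range(n):
        conf = np.log(prev_jrt) - truth.judgment_rt_log_mean
        log_rt = (rb["intercept"] + rb["trial_type"] * tt[t]
                  + rb["congruency"] * cg[t] + rb["jitter"] * jt[t]
                  + rb["distance"] * dist[t] + rb["confidence"] * conf
                  + rb["trial_nr"] * logtn[t] + rt_noise[t])
        rt = float(np.exp(log_rt))
        if prev_aware:
            rt += truth.pes_aware_ms + truth.peri_aware_ms * cg[t]
        elif prev_unaware:
            rt += truth.pes_unaware_ms
        rt_ms[t] = rt
        log_rt_c = np.log(rt) - rb["intercept"]

        if u_miss[t] < truth.miss_rate:
            cols["response"][t] = "miss"
        elif u_mult[t] < truth.multiple_rate:
            cols["response"][t] = "multiple"
        else:
            logit_acc = (ab["intercept"] + ab["trial_type"] * tt[t]
                         + ab["congruency"] * cg[t] + ab["jitter"] * jt[t]
                         + ab["distance"] * dist[t] + ab["confidence"] * conf
                         + ab["log_rt"] * log_rt_c + ab["trial_nr"] * logtn[t])
            correct = u_acc[t] < expit(logit_acc)
            number = trials["number"].iloc[t]
            is_target = tt[t] > 0
            right = ("button3" if is_target
                     else "button1" if number < design.reference_number
                     else "button2")
            if correct:
                cols["response"][t] = right
                cols["accuracy"][t] = "correct"
            else:
                wrongs = [b for b in ("button1", "button2", "button3")
                          if b != right]
                cols["response"][t] = wrongs[wrong_btn[t]]
                cols["accuracy"][t] = "error"

        valid_resp = cols["response"][t] not in ("miss", "multiple")
        if not valid_resp:
            cols["accuracy"][t] = "n/a"
            cols["judgment"][t] = "invalid"
            cols["awareness"][t] = "n/a"
            prev_aware = prev_unaware = False
            prev_jrt = np.exp(truth.judgment_rt_log_mean)
            rt_ms[t] = np.nan
            continue

        if u_inv[t] < truth.invalid_judgment_rate:
            cols["judgment"][t] = "invalid"
            cols["awareness"][t] = "n/a"
            prev_aware = prev_unaware = False
            prev_jrt = np.exp(truth.judgment_rt_log_mean)
            continue

        if cols["accuracy"][t] == "correct":
            said_error = u_jcorr[t] >= truth.p_correct_judged_correct
            cols["judgment"][t] = "said_error" if said_error \
                else "said_correct"
            cols["awareness"][t] = "n/a"
            prev_aware = prev_unaware = False
        else:
            z_rt = (np.log(rt) - rb["intercept"]) / max(truth.rt_noise_sd,
                                                        1e-9)
            logit_aw = (truth.aware_intercept
                        + truth.aware_rt_slope * z_rt
                        + truth.aware_evidence_slope * ev[t])
            aware = u_aware[t] < expit(logit_aw)
            cols["judgment"][t] = "said_error" if aware else "said_correct"
            cols["awareness"][t] = "aware_error" if aware \
                else "unaware_error"
            prev_aware, prev_unaware = aware, not aware

        # judgment latency: stronger subjective evidence -> faster judgment
        strength = abs(ev[t]) if cols["accuracy"][t] == "error" else \
            abs(ev[t]) + 0.5
        log_jrt = (truth.judgment_rt_log_mean
                   - truth.judgment_confidence_slope * (strength - 1.0)
                   + jrt_noise[t])
        judgment_rt_ms[t] = float(np.exp(log_jrt))
        prev_jrt = judgment_rt_ms[t]

    out = trials.copy()
    out["response"] = cols["response"]
    out["rt_ms"] = rt_ms
    out["accuracy"] = cols["accuracy"]
    out["judgment"] = cols["judgment"]
    out["judgment_rt_ms"] = judgment_rt_ms
    out["awareness"] = cols["awareness"]
    return out


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

ERN_TOPO_CENTER = (0.0, 0.08)    # slightly anterior of the vertex
PE_TOPO_CENTER = (0.0, -0.06)    # slightly posterior
TOPO_WIDTH = 0.45


def component_topographies(montage: Montage) -> dict[str, np.ndarray]:
    """Ground-truth spatial weight maps for the two injected components."""
    return {
        "ern": gaussian_topography(montage, ERN_TOPO_CENTER, TOPO_WIDTH),
        "pe": gaussian_topography(montage, PE_TOPO_CENTER, TOPO_WIDTH),
    }


def _pink_noise(rng: np.random.Generator, n_ch: int, n_times: int,
                n_trials: int, sfreq: float, sd: float,
                montage: Montage, spatial_scale: float) -> np.ndarray:
    """Spatially correlated 1/f-like noise, per-channel SD ``sd``."""
    white = rng.standard_normal((n_ch, n_trials, n_times))
    freqs = np.fft.rfftfreq(n_times, 1.0 / sfreq)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(freqs[nz])
    shape[0] = 0.0  # no DC drift
    spec = np.fft.rfft(white, axis=-1) * shape
    pink = np.fft.irfft(spec, n=n_times, axis=-1)
    # spatial mixing with unit-norm rows preserves per-channel variance
    d2 = np.sum((montage.positions[:, None, :]
                 - montage.positions[None, :, :]) ** 2, axis=-1)
    K = np.exp(-d2 / (2.0 * spatial_scale**2))
    K /= np.linalg.norm(K, axis=1, keepdims=True)
    mixed = np.einsum("ij,jrt->irt", K, pink)
    mixed *= sd / mixed.std(axis=(1, 2), keepdims=True)
    return np.transpose(mixed, (0, 2, 1))  # channels x time x trials


def simulate_eeg(trials: pd.DataFrame, truth: GroundTruth | None = None,
                 montage: Montage | None = None,
                 seed: int | np.random.Generator | None = None,
                 lock: str = "response") -> EpochSet:
    """Epoched EEG for every trial with a scoreable response.

    Response-locked epochs span ``truth.resp_window``; stimulus-locked
    epochs span ``truth.stim_window`` and embed the response-locked
    components at each trial's RT.  Trials without a response (misses /
    multiple presses) carry noise only and, for response locking, are
    dropped (their ``trial_index`` is simply absent).
    """
    truth = truth or GroundTruth()
    montage = montage or ring_montage()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(truth.seed if seed is None else seed)
    if lock not in ("response", "stimulus"):
        raise ValueError(f"unknown lock {lock!r}")

    has_resp = trials["rt_ms"].notna().to_numpy()
    if lock == "response":
        sub = trials.loc[has_resp]
    else:
        sub = trials
    n = len(sub)
    window = truth.resp_window if lock == "response" else truth.stim_window
    n_times = int(round((window[1] - window[0]) * truth.sfreq))
    times = window[0] + np.arange(n_times) / truth.sfreq

    aware = (sub["awareness"] == "aware_error").to_numpy()
    unaware = (sub["awareness"] == "unaware_error").to_numpy()
    error = (sub["accuracy"] == "error").to_numpy()
    aw_code = np.where(aware, 1.0, np.where(unaware, -1.0, 0.0))
    jrt = sub["judgment_rt_ms"].to_numpy(float)
    conf = np.where(np.isfinite(jrt),
                    np.log(np.where(np.isfinite(jrt), jrt, 1.0))
                    - truth.judgment_rt_log_mean, 0.0)

    amp_ern = np.where(
        error,
        truth.ern_base + truth.ern_gain * aw_code + truth.ern_conf * conf
        + truth.ern_interaction * aw_code * conf,
        truth.ern_base * truth.ern_correct_frac)
    amp_pe = np.where(
        error,
        truth.pe_base + truth.pe_gain * aw_code + truth.pe_conf * conf
        + truth.pe_interaction * aw_code * conf,
        truth.pe_base * truth.pe_correct_frac)
    amp_ern = np.where(has_resp[: n] if lock == "stimulus" else True,
                       amp_ern, 0.0)
    amp_pe = np.where(has_resp[: n] if lock == "stimulus" else True,
                      amp_pe, 0.0)

    # oscillation phase per trial: tightly locked on aware errors
    phase_sd = np.where(aware, truth.phase_lock_aware,
                        truth.phase_lock_unaware)
    phase = np.where(error, rng.normal(0.0, 1.0, size=n) * phase_sd,
                     rng.uniform(-np.pi, np.pi, size=n))

    if lock == "response":
        t_rel = np.broadcast_to(times, (n, n_times))
    else:
        rt_s = np.where(has_resp, trials["rt_ms"].to_numpy(float),
                        np.nan)[:n] / 1000.0
        t_rel = times[None, :] - np.where(np.isfinite(rt_s), rt_s, 1e9)[:, None]

    def gauss(center, width):
        return np.exp(-((t_rel - center) ** 2) / (2.0 * width**2))

    g_ern = -gauss(truth.ern_center_s, truth.ern_width_s)   # negative-going
    g_pe = gauss(truth.pe_center_s, truth.pe_width_s)
    env = gauss(truth.osc_center_s, truth.osc_width_s)
    osc = env * np.cos(2 * np.pi * truth.osc_freq_hz
                       * (t_rel - truth.osc_center_s) + phase[:, None])
    osc_amp = np.where(error, truth.osc_amp, 0.0)

    topo = component_topographies(montage)
    # signal[ch, time, trial]
    signal = (
        np.einsum("c,rt,r->ctr", topo["ern"], g_ern, amp_ern)
        + np.einsum("c,rt,r->ctr", topo["pe"], g_pe, amp_pe)
        + np.einsum("c,rt,r->ctr", topo["pe"], osc, osc_amp)
    )
    if truth.noise_sd > 0:
        signal += _pink_noise(rng, montage.n_channels, n_times, n,
                              truth.sfreq, truth.noise_sd, montage,
                              truth.noise_spatial_scale)
    return EpochSet(data=signal.astype(np.float32).astype(np.float64),
                    ch_names=list(montage.ch_names), sfreq=truth.sfreq,
                    window=window, lock=lock,
                    trial_index=sub["trial_nr"].to_numpy())


# ---------------------------------------------------------------------------
# convenience: one subject end-to-end
# ---------------------------------------------------------------------------

def simulate_subject(design: TaskDesign | None = None,
                     truth: GroundTruth | None = None,
                     seed: int | None = None, with_eeg: bool = True,
                     eeg_trials: str = "all", lock: str = "response",
                     montage: Montage | None = None):
    """Trial table (+ optional EEG) for one subject.

    ``eeg_trials='error'`` restricts the epoch set to error trials - the
    awareness-specific analyses (EEG GLM 2, decoding, ITPC) only consume
    error epochs, and skipping correct-trial synthesis is much cheaper.
    """
    design = design or TaskDesign()
    truth = truth or GroundTruth()
    rngs = _stage_rngs(truth.seed if seed is None else seed)
    trials = generate_trial_sequence(design, rngs["sequence"])
    trials = simulate_behavior(trials, truth, design, rngs["behavior"])
    if not with_eeg:
        return trials, None
    if eeg_trials == "error":
        mask = (trials["accuracy"] == "error").to_numpy()
        eeg_source = trials.loc[mask]
    else:
        eeg_source = trials
    epochs = simulate_eeg(eeg_source, truth, montage, rngs["eeg"], lock=lock)
    return trials, epochs
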