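"""Synthetic flanker-task EEG cohorts with controllable alpha–RT coupling.

Generates epoched multi-channel EEG for two groups of older adults — healthy
controls (HC) and mild cognitive impairment (MCI) — performing an Eriksen
flanker task.  Each trial carries an occipital alpha oscillation whose
amplitude is coupled to the trial's response time through a Gaussian copula,
so that the *true* Spearman correlation between single-trial alpha power and
RT is an input parameter.  This makes every downstream stage of the analysis
(spectrogram, median split, within-subject correlation, group statistics,
classification) testable against known ground truth without any recorded
dataset.

Coupling construction
---------------------
For a target Spearman correlation ``rho`` between per-trial alpha power and
RT, a latent standard-normal pair ``(u, v)`` is drawn with Pearson
correlation ``r = 2·sin(π·rho/6)`` (the Gaussian-copula inverse of the
Spearman target).  ``u`` maps through a lognormal quantile to the trial's
alpha amplitude ``a`` and ``v`` maps through the normal quantile to the
trial's RT.  Because Spearman correlation is invariant under strictly
increasing maps — and power ``a²`` is an increasing map of positive
amplitude — the generated pair ``(a², RT)`` has population Spearman
correlation exactly ``rho``.

RTs below a physiological floor (150 ms) are rejected and the whole latent
pair redrawn, which preserves the copula's rank structure (clipping would
create ties at the floor and bias the rank correlation).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("HC", "MCI")
CONDITIONS = ("congruent", "incongruent")

#: Occipital channels carrying full-amplitude alpha; the remaining channels
#: carry an attenuated copy so average re-referencing is non-degenerate.
OCCIPITAL = ("Oz", "O1", "O2")
DEFAULT_CHANNELS = ("Fz", "Cz", "Pz", "P3", "P4", "O1", "Oz", "O2")

#: Alpha gain on non-occipital channels (≤ 0.3 of the occipital amplitude).
NONOCCIPITAL_GAIN = 0.3

#: Neuropsychological battery: per-test (MCI mean, MCI SD, HC mean, HC SD,
#: higher_is_worse).  Means/SDs emulate a community MCI cohort vs.
#: demographically matched controls; timed tests (trail-making, Stroop) are
#: scored in seconds, so higher is worse.
NEUROPSYCH_TESTS: dict[str, tuple[float, float, float, float, bool]] = {
    "MMSE": (26.64, 1.50, 28.39, 1.20, False),
    "AVLT_delayed": (3.36, 2.72, 6.14, 1.96, False),
    "AVLT_total": (19.36, 9.80, 29.50, 6.70, False),
    "ROCFT_recall": (8.46, 6.70, 15.75, 5.83, False),
    "TMT_B": (230.46, 72.10, 153.25, 58.21, True),
    "Stroop": (95.89, 33.46, 83.64, 24.03, True),
    "TMT_A": (71.75, 22.04, 53.36, 14.55, True),
    "SDMT": (25.75, 11.80, 34.92, 10.31, False),
    "CVFT": (15.00, 4.82, 18.79, 5.49, False),
    "BNT": (20.11, 3.70, 24.75, 3.11, False),
    "ROCFT_copy": (29.82, 6.35, 33.71, 3.43, False),
    "CDT": (21.46, 6.27, 25.75, 4.46, False),
}

#: Five cognitive domains, two tests each (the memory domain's verbal
#: learning test contributes two scores).  MMSE is a screening score, not a
#: domain test.
COGNITIVE_DOMAINS: dict[str, tuple[str, ...]] = {
    "memory": ("AVLT_delayed", "AVLT_total", "ROCFT_recall"),
    "executive": ("TMT_B", "Stroop"),
    "attention": ("TMT_A", "SDMT"),
    "language": ("CVFT", "BNT"),
    "visuospatial": ("ROCFT_copy", "CDT"),
}


def default_norms() -> pd.DataFrame:
    """Normative mean/SD per test (healthy-control values stand in for
    population norms in the synthetic setting)."""
    rows = {
        name: {"mean": hc_m, "sd": hc_s, "higher_is_worse": worse}
        for name, (_, _, hc_m, hc_s, worse) in NEUROPSYCH_TESTS.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class SimulationParams:
    """Study-condition parameters for a two-group flanker-task cohort.

    Defaults emulate the target study: 28 subjects per group, 60 trials per
    congruency condition at 500 Hz, epochs −2000…+1000 ms around stimulus
    onset, RT means 498/538 ms (SD 55/58 ms) for congruent/incongruent,
    error rates 6/7 % (HC) and 5/10 % (MCI), and a weak positive alpha–RT
    coupling in HC (+0.10) that is absent/reversed in MCI (−0.03).
    """

    n_per_group: int = 28
    trials_per_condition: int = 60
    fs: float = 500.0
    epoch_window: tuple[float, float] = (-2000.0, 1000.0)
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    alpha_freq_range: tuple[float, float] = (9.0, 11.0)
    #: lognormal parameters of the per-trial alpha amplitude (µV)
    alpha_amp_mu: float = -0.15
    alpha_amp_sigma: float = 0.40
    #: lognormal sigma of a per-subject amplitude scale factor
    subject_amp_sigma: float = 0.30
    noise_exponent: float = 1.0
    #: RMS of the 1/f background noise per channel (µV)
    noise_amp: float = 2.0
    #: target Spearman correlation between true alpha power and RT, per group
    coupling_rho: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.10, "MCI": -0.03}
    )
    rt_mean: dict[str, float] = field(
        default_factory=lambda: {"congruent": 498.0, "incongruent": 538.0}
    )
    rt_sd: dict[str, float] = field(
        default_factory=lambda: {"congruent": 55.0, "incongruent": 58.0}
    )
    error_rate: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "HC": {"congruent": 0.06, "incongruent": 0.07},
            "MCI": {"congruent": 0.05, "incongruent": 0.10},
        }
    )
    rt_min: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.trials_per_condition < 4:
            raise ValueError("trials_per_condition must be >= 4")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for ch in OCCIPITAL:
            if list(self.channels).count(ch) != 1:
                raise ValueError(
                    f"channel list must contain {ch} exactly once"
                )
        for g, rho in self.coupling_rho.items():
            if not -1.0 < rho < 1.0:
                raise ValueError(f"coupling_rho[{g}]={rho} outside (-1, 1)")
        for cond, m in self.rt_mean.items():
            if m <= 0:
                raise ValueError(f"rt_mean[{cond}] must be positive")
        if self.epoch_window[1] <= self.epoch_window[0]:
            raise ValueError("epoch_window must be increasing")

    @property
    def n_samples(self) -> int:
        lo, hi = self.epoch_window
        return int(round((hi - lo) / 1000.0 * self.fs)) + 1

    def times_ms(self) -> np.ndarray:
        lo, _ = self.epoch_window
        return lo + np.arange(self.n_samples) * 1000.0 / self.fs

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        for key in ("epoch_window", "channels", "alpha_freq_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class EpochedRecording:
    """One subject's epoched EEG: trials × channels × samples (µV)."""

    data: np.ndarray
    fs: float
    times: np.ndarray  # ms, t = 0 at stimulus onset
    channel_names: tuple[str, ...]
    trial_table: pd.DataFrame
    subject_id: str = ""
    group: str = ""
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials × channels × samples")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.data.shape[2] != self.times.size:
            raise ValueError("sample axis does not match times")
        if len(self.trial_table) != self.data.shape[0]:
            raise ValueError("trial_table rows do not match trial axis")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochedRecording":
        return EpochedRecording(
            data=self.data.copy(),
            fs=self.fs,
            times=self.times.copy(),
            channel_names=tuple(self.channel_names),
            trial_table=self.trial_table.copy(),
            subject_id=self.subject_id,
            group=self.group,
            info=dict(self.info),
        )


def spearman_to_pearson_latent(rho: float) -> float:
    """Pearson correlation of the Gaussian copula that induces Spearman
    correlation ``rho`` on the margins: r = 2·sin(π·rho/6)."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


def simulate_trial_pairs(
    rho: float,
    n: int,
    rng: np.random.Generator,
    rt_mean: float,
    rt_sd: float,
    amp_mu: float = -0.15,
    amp_sigma: float = 0.40,
    rt_min: float = 150.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` coupled (alpha amplitude, RT) pairs.

    Returns (amplitudes µV, RTs ms).  Spearman(amplitude², RT) → ``rho`` in
    population.  Pairs whose RT falls below ``rt_min`` are redrawn wholesale.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    r = spearman_to_pearson_latent(rho)
    amps = np.empty(n)
    rts = np.empty(n)
    filled = 0
    while filled < n:
        need = n - filled
        u = rng.standard_normal(need)
        e = rng.standard_normal(need)
        v = r * u + np.sqrt(1.0 - r * r) * e
        rt = rt_mean + rt_sd * v
        ok = rt >= rt_min
        k = int(ok.sum())
        amps[filled : filled + k] = np.exp(amp_mu + amp_sigma * u[ok])
        rts[filled : filled + k] = rt[ok]
        filled += k
    return amps, rts


def _one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
    exponent: float, fs: float,
) -> np.ndarray:
    """Gaussian 1/f^exponent noise, unit RMS, independent across leading axes."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    return shaped / rms


def simulate_subject(
    params: SimulationParams,
    group: str,
    subject_seed: int | np.random.SeedSequence,
    subject_id: str = "",
) -> EpochedRecording:
    """Simulate one subject's epoched flanker-task EEG.

    The subject's alpha peak frequency is drawn uniformly from
    ``alpha_freq_range``; each trial's alpha amplitude and RT come from the
    group's copula.  Occipital channels carry the full alpha oscillation
    (active over the whole epoch), other channels an attenuated copy; every
    channel additionally receives independent 1/f noise.  The true per-trial
    amplitude is stored in the trial table for recovery tests.
    """
    params.validate()
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    rng = np.random.default_rng(subject_seed)

    f_alpha = rng.uniform(*params.alpha_freq_range)
    subj_scale = float(np.exp(params.subject_amp_sigma * rng.standard_normal()))
    rho = params.coupling_rho[group]

    n_cond = params.trials_per_condition
    n_trials = 2 * n_cond
    rows = []
    amps_all = np.empty(n_trials)
    rts_all = np.empty(n_trials)
    # interleave the two conditions in random presentation order
    order = rng.permutation(
        np.repeat(np.arange(2), n_cond)
    )
    per_cond_iters = {}
    for ci, cond in enumerate(CONDITIONS):
        amps, rts = simulate_trial_pairs(
            rho, n_cond, rng,
            rt_mean=params.rt_mean[cond], rt_sd=params.rt_sd[cond],
            amp_mu=params.alpha_amp_mu, amp_sigma=params.alpha_amp_sigma,
            rt_min=params.rt_min,
        )
        amps *= subj_scale
        err_p = params.error_rate[group][cond]
        correct = rng.random(n_cond) >= err_p
        per_cond_iters[ci] = iter(zip(amps, rts, correct))
    for i, ci in enumerate(order):
        a, rt, corr = next(per_cond_iters[ci])
        amps_all[i] = a
        rts_all[i] = rt
        rows.append(
            {
                "trial_id": i,
                "condition": CONDITIONS[ci],
                "rt": float(rt),
                "correct": bool(corr),
                "artifact": False,
                "true_alpha_amp": float(a),
            }
        )
    trial_table = pd.DataFrame(rows)

    times = params.times_ms()
    t_sec = times / 1000.0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
    # trials × samples alpha waveform, then broadcast over channels with gains
    wave = np.cos(2.0 * np.pi * f_alpha * t_sec[None, :] + phases[:, None])
    wave = wave * amps_all[:, None]
    gains = np.array(
        [1.0 if ch in OCCIPITAL else NONOCCIPITAL_GAIN for ch in params.channels]
    )
    data = wave[:, None, :] * gains[None, :, None]
    if params.noise_amp > 0:
        data = data + params.noise_amp * _one_over_f_noise(
            rng, (n_trials, len(params.channels)), params.n_samples,
            params.noise_exponent, params.fs,
        )

    return EpochedRecording(
        data=data,
        fs=params.fs,
        times=times,
        channel_names=tuple(params.channels),
        trial_table=trial_table,
        subject_id=subject_id,
        group=group,
        info={"alpha_peak_freq": float(f_alpha), "subject_scale": subj_scale},
    )


def simulate_neuropsych(
    rng: np.random.Generator, groups: list[str]
) -> pd.DataFrame:
    """Draw per-subject neuropsychological scores from group-specific normal
    distributions (complete table, no missing values)."""
    rows = []
    for i, g in enumerate(groups):
        row: dict[str, object] = {"subject": f"S{i:03d}", "group": g}
        for name, (mci_m, mci_s, hc_m, hc_s, _) in NEUROPSYCH_TESTS.items():
            m, s = (mci_m, mci_s) if g == "MCI" else (hc_m, hc_s)
            row[name] = float(m + s * rng.standard_normal())
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


def simulate_cohort(
    params: SimulationParams,
) -> tuple[list[EpochedRecording], pd.DataFrame]:
    """Simulate a full two-group cohort.

    Returns ``2·n_per_group`` recordings (HC first, then MCI) and a
    neuropsychological score table with one row per subject.  Deterministic
    given ``params.seed``: each subject receives a child seed spawned from
    the cohort seed, so per-subject generation order cannot change results.
    """
    params.validate()
    if params.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 for a cohort")
    root = np.random.SeedSequence(params.seed)
    n_total = 2 * params.n_per_group
    child_seeds = root.spawn(n_total + 1)
    groups = ["HC"] * params.n_per_group + ["MCI"] * params.n_per_group
    recordings = []
    for i, g in enumerate(groups):
        rec = simulate_subject(
            params, g, child_seeds[i], subject_id=f"S{i:03d}"
        )
        recordings.append(rec)
    neuro_rng = np.random.default_rng(child_seeds[n_total])
    neuropsych = simulate_neuropsych(neuro_rng, groups)
    return recordings, neuropsych


def classify_mci(scores: pd.Series | dict, norms: pd.DataFrame) -> str:
    """Label a subject MCI if any cognitive domain shows dysfunction.

    Dysfunction in a domain means a test score strictly beyond 1.5 SD of the
    normative mean in the *impaired* direction — below ``mean − 1.5·SD`` for
    tests where higher is better, above ``mean + 1.5·SD`` for timed tests
    where higher is worse.  A score exactly at the cutoff does not count.
    """
    if isinstance(scores, dict):
        scores = pd.Series(scores)
    for domain, tests in COGNITIVE_DOMAINS.items():
        for test in tests:
            if test not in scores or pd.isna(scores[test]):
                raise ValueError(f"missing score for test {test!r}")
            if test not in norms.index:
                raise ValueError(f"norms missing test {test!r}")
            m = norms.loc[test, "mean"]
            s = norms.loc[test, "sd"]
            worse = bool(norms.loc[test, "higher_is_worse"])
            if worse:
                if scores[test] > m + 1.5 * s:
                    return "MCI"
            else:
                if scores[test] < m - 1.5 * s:
                    return "MCI"
    return "HC"


# ---------------------------------------------------------------------------
# On-disk cohort layout: one directory per subject with meta.json (fs,
# channels, times, group; little-endian float64, C order, shape recorded),
# data.npy for the cube and trials.csv for the trial table; cohort-level
# neuropsych.csv.
# ---------------------------------------------------------------------------

def save_cohort(
    recordings: list[EpochedRecording],
    neuropsych: pd.DataFrame,
    outdir: str | Path,
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        sdir = outdir / rec.subject_id
        sdir.mkdir(exist_ok=True)
        meta = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "fs": rec.fs,
            "channels": list(rec.channel_names),
            "times_ms": rec.times.tolist(),
            "shape": list(rec.data.shape),
            "dtype": "<f8",
            "order": "C",
            "info": rec.info,
        }
        (sdir / "meta.json").write_text(json.dumps(meta))
        np.save(sdir / "data.npy", rec.data.astype("<f8"))
        rec.trial_table.to_csv(sdir / "trials.csv", index=False)
    neuropsych.to_csv(outdir / "neuropsych.csv")
    return outdir


def load_cohort(indir: str | Path) -> tuple[list[EpochedRecording], pd.DataFrame]:
    indir = Path(indir)
    recordings = []
    for sdir in sorted(p for p in indir.iterdir() if p.is_dir()):
        meta = json.loads((sdir / "meta.json").read_text())
        data = np.load(sdir / "data.npy")
        table = pd.read_csv(sdir / "trials.csv")
        recordings.append(
            EpochedRecording(
                data=data,
                fs=meta["fs"],
                times=np.asarray(meta["times_ms"]),
                channel_names=tuple(meta["channels"]),
                trial_table=table,
                subject_id=meta["subject_id"],
                group=meta["group"],
                info=meta.get("info", {}),
            )
        )
    neuropsych = pd.read_csv(indir / "neuropsych.csv", index_col=0)
    return recordings, neuropsych
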