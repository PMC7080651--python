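"""Epoch preprocessing and behavioral trial bookkeeping.

Mirrors a conventional EEG pipeline for an epoched flanker task: average
re-referencing, 1–30 Hz zero-phase FIR band-pass, prestimulus baseline
correction, then trial exclusion (no-response trials, per-condition ±2 SD RT
outliers, incorrect responses, externally flagged artifacts) and behavioral
summaries (per-condition RT mean/SD, error rate, flanker effects).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import CONDITIONS, EpochedRecording

#: Response window: the post-stimulus fixation lasts 2 s, so a response later
#: than 2000 ms after stimulus onset counts as no response (configurable).
DEFAULT_RT_WINDOW_MS = 2000.0


def rereference_average(rec: EpochedRecording) -> EpochedRecording:
    """Subtract the instantaneous across-channel mean from every channel."""
    if rec.data.shape[1] < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = rec.copy()
    out.data = out.data - out.data.mean(axis=1, keepdims=True)
    return out


@lru_cache(maxsize=8)
def design_bandpass(fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase band-pass kernel: cascaded windowed-sinc (Hamming) high-
    and low-pass filters.

    Transition bandwidths: ``min(max(0.25·lo, 2 Hz), lo)`` at the low edge
    and ``0.25·hi`` at the high edge; −6 dB points sit at the band edges.
    The two linear-phase kernels are convolved into one symmetric kernel.
    """
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"invalid band edges lo={lo}, hi={hi} at fs={fs}")
    l_trans = min(max(0.25 * lo, 2.0), lo)
    h_trans = 0.25 * hi
    # Hamming window: transition width ≈ 3.3 / (numtaps / fs)
    def _taps(trans: float) -> int:
        n = int(np.ceil(3.3 * fs / trans))
        return n + 1 if n % 2 == 0 else n
    hp = sps.firwin(_taps(l_trans), lo, pass_zero=False, window="hamming", fs=fs)
    lp = sps.firwin(_taps(h_trans), hi, pass_zero=True, window="hamming", fs=fs)
    return np.convolve(hp, lp)


def bandpass_fir(
    rec: EpochedRecording, lo: float = 1.0, hi: float = 30.0
) -> EpochedRecording:
    """Zero-phase FIR band-pass of every trial × channel trace.

    Epochs are reflect-padded by half the kernel length before convolution so
    the output has the same length with no phase shift (the kernel is
    symmetric).
    """
    h = design_bandpass(rec.fs, lo, hi)
    half = len(h) // 2
    n = rec.data.shape[-1]
    if half >= n:
        raise ValueError("epoch too short for the requested filter")
    padded = np.concatenate(
        [
            rec.data[..., 1 : half + 1][..., ::-1],
            rec.data,
            rec.data[..., -half - 1 : -1][..., ::-1],
        ],
        axis=-1,
    )
    filt = sps.fftconvolve(padded, h[None, None, :], mode="valid", axes=-1)
    out = rec.copy()
    out.data = filt
    return out


def baseline_correct(
    rec: EpochedRecording, window: tuple[float, float] = (-2000.0, 0.0)
) -> EpochedRecording:
    """Subtract, per trial × channel, the mean over the baseline window (ms)."""
    lo, hi = window
    if lo < rec.times[0] - 1e-9 or hi > rec.times[-1] + 1e-9:
        raise ValueError("baseline window outside epoch")
    mask = (rec.times >= lo) & (rec.times <= hi)
    out = rec.copy()
    out.data = out.data - out.data[..., mask].mean(axis=-1, keepdims=True)
    return out


def exclude_trials(
    table: pd.DataFrame,
    rt_window_ms: float = DEFAULT_RT_WINDOW_MS,
    min_trials: int = 4,
    outlier_sd: float | None = 2.0,
) -> pd.DataFrame:
    """Flag invalid, outlier and excluded trials; recompute ``included``.

    A trial is *valid* if it has a response within ``rt_window_ms``.  Per
    condition, the RT mean and SD over valid trials are computed once (a
    single pass, never iterated) and trials strictly outside the closed
    interval [mean − outlier_sd·SD, mean + outlier_sd·SD] are flagged as
    outliers.  A trial is *included* in EEG analyses iff it is valid,
    correct, artifact-free and not an outlier.  Idempotent: flags are
    recomputed from scratch.

    ``outlier_sd=None`` disables the RT trim (no trial is an outlier).
    Note the trim is a two-sided range restriction on RT: it shrinks the RT
    tails and therefore attenuates any true alpha–RT rank correlation, so
    parameter-recovery experiments run with the trim disabled.
    """
    out = table.copy()
    rt = out["rt"].to_numpy(dtype=float)
    valid = np.isfinite(rt) & (rt <= rt_window_ms)
    out["valid"] = valid
    outlier = np.zeros(len(out), dtype=bool)
    for cond in out["condition"].unique():
        m = (out["condition"] == cond).to_numpy() & valid
        if m.sum() == 0:
            raise ValueError(f"no valid trials in condition {cond!r}")
        if outlier_sd is not None:
            mu = rt[m].mean()
            sd = rt[m].std(ddof=1) if m.sum() > 1 else 0.0
            lo, hi = mu - outlier_sd * sd, mu + outlier_sd * sd
            outlier[m] = (rt[m] < lo) | (rt[m] > hi)
    out["outlier"] = outlier
    if "artifact" not in out:
        out["artifact"] = False
    out["included"] = (
        out["valid"] & out["correct"] & ~out["artifact"] & ~out["outlier"]
    )
    out["speed_bin"] = "unassigned"
    for cond in out["condition"].unique():
        n_inc = int((out["included"] & (out["condition"] == cond)).sum())
        if n_inc < min_trials:
            raise ValueError(
                f"only {n_inc} included trials in condition {cond!r} "
                f"(need >= {min_trials}); subject unusable"
            )
    return out


def behavioral_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition RT mean/SD (included trials) and error rate (all valid-
    response trials), plus flanker effects (incongruent − congruent).

    Returns a one-row DataFrame with columns
    ``RT_<cond>, sdRT_<cond>, ER_<cond>, flankerRT, flankerER``.
    """
    if "included" not in table:
        raise ValueError("run exclude_trials first")
    row: dict[str, float] = {}
    for cond in CONDITIONS:
        inc = table[(table["condition"] == cond) & table["included"]]
        if len(inc) == 0:
            raise ValueError(f"no included trials in condition {cond!r}")
        responded = table[(table["condition"] == cond) & table["valid"]]
        row[f"RT_{cond}"] = float(inc["rt"].mean())
        row[f"sdRT_{cond}"] = float(inc["rt"].std(ddof=1))
        row[f"ER_{cond}"] = float(1.0 - responded["correct"].mean())
    row["flankerRT"] = row["RT_incongruent"] - row["RT_congruent"]
    row["flankerER"] = row["ER_incongruent"] - row["ER_congruent"]
    return pd.DataFrame([row])
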