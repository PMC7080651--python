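"""Single-trial spectrograms via a windowed Fourier transform (WFT).

A fixed 300-ms Hanning taper slides over each trial in 2-ms steps; every
tapered segment is zero-padded to 500 samples before the DFT, so at a 500 Hz
sampling rate the frequency bins fall on an exact 1-Hz grid (spacing
``fs / pad_to``).  The spectrogram is ``P(t, f) = |F(t, f)|²`` in µV².
Prestimulus alpha power is the mean of P over an occipital region of
interest: −1000…−300 ms × 7…14 Hz at Oz/O1/O2 (all bounds inclusive).

Conventions
-----------
* The 150-sample window is centered on the output time ``t``: with the
  center at 0-based window index 75, the segment covers samples
  ``t − 75 … t + 74``.  Near epoch edges the segment is zero-padded; the
  default ROI never touches the edges.
* The Hanning taper uses the symmetric definition; no amplitude-gain
  compensation is applied, so absolute power is convention-dependent (every
  downstream statistic is scale-invariant within subject).
* Zeros are appended after the taper; since zero-padding placement only
  changes DFT phase, ``|F|²`` is unaffected by this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

from .simulate import OCCIPITAL, EpochedRecording


@dataclass
class AlphaROI:
    """Prestimulus alpha region of interest (inclusive bounds)."""

    t_min: float = -1000.0
    t_max: float = -300.0
    f_min: float = 7.0
    f_max: float = 14.0
    electrodes: tuple[str, ...] = OCCIPITAL


@dataclass
class TFMap:
    """Spectrogram cube: trials × channels × freqs × times, µV²."""

    power: np.ndarray
    freqs: np.ndarray  # Hz
    times: np.ndarray  # ms
    channel_names: tuple[str, ...]
    window_len: float = 300.0  # ms
    pad_to: int = 500  # samples
    fs: float = 500.0

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.ndim != 4:
            raise ValueError("power must be trials × channels × freqs × times")
        if self.power.shape[1] != len(self.channel_names):
            raise ValueError("channel axis mismatch")
        if self.power.shape[2] != self.freqs.size:
            raise ValueError("frequency axis mismatch")
        if self.power.shape[3] != self.times.size:
            raise ValueError("time axis mismatch")


def wft_segment_power(segment: np.ndarray, pad_to: int = 500) -> np.ndarray:
    """Power spectrum of one tapered segment zero-padded to ``pad_to``.

    Reference path used by the batched spectrogram: taper × segment, append
    zeros, DFT, squared magnitude.  Returns all ``pad_to // 2 + 1``
    nonnegative-frequency bins.
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.size
    if pad_to < n:
        raise ValueError("pad_to must be >= segment length")
    tapered = segment * hann(n, sym=True)
    return np.abs(np.fft.rfft(tapered, n=pad_to)) ** 2


def wft_spectrogram(
    rec: EpochedRecording,
    window_len: float = 300.0,
    pad_to: int = 500,
    t_step: float = 2.0,
    f_min: float = 1.0,
    f_max: float = 30.0,
    picks: tuple[str, ...] | None = None,
    t_range: tuple[float, float] | None = None,
) -> TFMap:
    """Windowed-Fourier spectrogram of every trial × channel.

    Parameters
    ----------
    window_len : taper length in ms (must be an integer number of samples).
    pad_to : DFT length after zero-padding; frequency spacing = fs / pad_to.
    t_step : output time step in ms (must be a multiple of the sample period).
    f_min, f_max : retained frequency range in Hz (inclusive).
    picks : restrict to these channels (order preserved as given).
    t_range : restrict output times to [t_range[0], t_range[1]] ms inclusive.

    The restriction arguments change only which (channel, time) cells are
    computed, not the values at the cells.
    """
    fs = rec.fs
    nwin = int(round(window_len / 1000.0 * fs))
    if pad_to < nwin:
        raise ValueError("pad_to must be >= window length in samples")
    step = t_step / 1000.0 * fs
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise ValueError("t_step must be a positive multiple of the sample period")
    step = int(round(step))

    if picks is None:
        ch_idx = np.arange(len(rec.channel_names))
        ch_names = tuple(rec.channel_names)
    else:
        name_to_i = {c: i for i, c in enumerate(rec.channel_names)}
        missing = [c for c in picks if c not in name_to_i]
        if missing:
            raise ValueError(f"channels not in recording: {missing}")
        ch_idx = np.array([name_to_i[c] for c in picks])
        ch_names = tuple(picks)

    centers = np.arange(0, rec.times.size, step)
    if t_range is not None:
        sel = (rec.times[centers] >= t_range[0] - 1e-9) & (
            rec.times[centers] <= t_range[1] + 1e-9
        )
        centers = centers[sel]
    out_times = rec.times[centers]

    df = fs / pad_to
    k_lo = int(np.ceil(f_min / df - 1e-9))
    k_hi = int(np.floor(f_max / df + 1e-9))
    freqs = np.arange(k_lo, k_hi + 1) * df

    half_l = nwin // 2  # center at 0-based window index nwin//2
    half_r = nwin - half_l - 1
    x = rec.data[:, ch_idx, :]
    n_tr, n_ch, n_samp = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (half_l, half_r)))
    # all length-nwin segments; segs[..., c, :] covers samples c-half_l..c+half_r
    all_segs = sliding_window_view(xp, nwin, axis=-1)
    if centers.size > 1 and np.all(np.diff(centers) == centers[1] - centers[0]):
        hop = int(centers[1] - centers[0])  # contiguous stride: keep the view
        segs = all_segs[:, :, centers[0] : centers[-1] + 1 : hop, :]
    else:
        segs = all_segs[:, :, centers, :]
    win = hann(nwin, sym=True)

    # DFT restricted to the requested bins via a complex projection matrix:
    # F[k] = sum_j win[j]·x[j]·exp(-2πi·k·j/pad_to).  Appended zeros
    # contribute nothing, so this equals the zero-padded DFT at those bins.
    j = np.arange(nwin)
    k = np.arange(k_lo, k_hi + 1)
    flat = segs.reshape(-1, nwin)
    if k.size <= 16:
        kernel = win[:, None] * np.exp(-2j * np.pi * np.outer(j, k) / pad_to)
        # two real matmuls instead of one complex one (flat is real)
        pw = (flat @ kernel.real) ** 2 + (flat @ kernel.imag) ** 2
    else:
        pw = np.empty((flat.shape[0], k.size))
        chunk = max(1, 50_000)
        for lo_i in range(0, flat.shape[0], chunk):
            block = flat[lo_i : lo_i + chunk] * win
            spec = np.fft.rfft(block, n=pad_to, axis=-1)[:, k_lo : k_hi + 1]
            pw[lo_i : lo_i + chunk] = np.abs(spec) ** 2
    power = pw.reshape(n_tr, n_ch, centers.size, k.size)
    power = np.moveaxis(power, -1, 2)  # → trials × ch × freqs × times

    return TFMap(
        power=power,
        freqs=freqs,
        times=out_times,
        channel_names=ch_names,
        window_len=window_len,
        pad_to=pad_to,
        fs=fs,
    )


def extract_alpha_power(tf: TFMap, roi: AlphaROI | None = None) -> np.ndarray:
    """Per-trial mean power over the ROI, averaged across ROI electrodes.

    For each ROI channel, the mean over all (t, f) grid points inside the
    inclusive ROI bounds; the three per-channel means are then averaged
    (equivalent to pooling, since the grids are identical).
    """
    roi = roi or AlphaROI()
    name_to_i = {c: i for i, c in enumerate(tf.channel_names)}
    missing = [c for c in roi.electrodes if c not in name_to_i]
    if missing:
        raise ValueError(f"ROI electrodes not in TFMap: {missing}")
    ch = [name_to_i[c] for c in roi.electrodes]
    tmask = (tf.times >= roi.t_min - 1e-9) & (tf.times <= roi.t_max + 1e-9)
    fmask = (tf.freqs >= roi.f_min - 1e-9) & (tf.freqs <= roi.f_max + 1e-9)
    if not tmask.any() or not fmask.any():
        raise ValueError("ROI does not intersect the TF grid")
    sub = tf.power[:, ch][:, :, fmask][:, :, :, tmask]
    return sub.mean(axis=(2, 3)).mean(axis=1)


def prestimulus_alpha_power(
    rec: EpochedRecording, roi: AlphaROI | None = None
) -> np.ndarray:
    """Convenience path: spectrogram restricted to the ROI channels/times,
    then ROI mean power per trial.  Identical values to running the full
    spectrogram and extracting, at a fraction of the cost."""
    roi = roi or AlphaROI()
    tf = wft_spectrogram(
        rec,
        picks=roi.electrodes,
        t_range=(roi.t_min, roi.t_max),
        f_min=roi.f_min,
        f_max=roi.f_max,
    )
    return extract_alpha_power(tf, roi)
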