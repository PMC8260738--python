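"""Per-epoch log band power from single-channel sleep EEG.

Power is estimated with one Hamming-windowed periodogram per 4-s epoch,
epochs advancing by 2 s (50% overlap), so the series of overlapping-epoch
periodograms forms a band-power time course. For each of the six canonical
bands the in-band power is integrated (density summed times the frequency
bin width) and log10-transformed. Band edges are inclusive on the lower
bound, exclusive on the upper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

#: Band name -> (low Hz inclusive, high Hz exclusive).
BANDS: dict[str, tuple[float, float]] = {
    "low_delta": (1.0, 2.0),
    "high_delta": (2.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 10.0),
    "sigma": (12.0, 14.0),
    "beta": (15.0, 25.0),
}
BAND_NAMES: tuple[str, ...] = tuple(BANDS)


class EEGError(ValueError):
    pass


@dataclass
class BandPowerSeries:
    """Epoch-center times (s) and an epochs x 6 matrix of log10 band power."""

    epoch_times: np.ndarray
    log_power: np.ndarray
    bands: tuple[str, ...] = BAND_NAMES

    def column(self, band: str) -> np.ndarray:
        return self.log_power[:, self.bands.index(band)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.log_power, columns=list(self.bands)).assign(time=self.epoch_times)

    @classmethod
    def from_frame(cls, df) -> "BandPowerSeries":
        return cls(
            epoch_times=df["time"].to_numpy(dtype=float),
            log_power=df[list(BAND_NAMES)].to_numpy(dtype=float),
        )


def epoch_band_power(
    signal: np.ndarray,
    fs: float,
    epoch_len: float = 4.0,
    overlap: float = 2.0,
    mask: np.ndarray | None = None,
) -> BandPowerSeries:
    """Welch-style sliding-epoch log10 band power of a single EEG channel.

    ``mask`` (optional, one bool per sample) marks artifact/arousal samples;
    epochs containing any masked sample are dropped, mirroring the removal
    of contaminated data points before spectral analysis.
    """
    signal = np.asarray(signal, dtype=float)
    top = max(hi for _, hi in BANDS.values())
    if fs < 2 * top:
        raise EEGError(f"sampling rate {fs} Hz below Nyquist for the {top} Hz band edge")
    nper = int(round(epoch_len * fs))
    step = int(round((epoch_len - overlap) * fs))
    if len(signal) < nper:
        raise EEGError("signal shorter than one epoch")
    n_epochs = (len(signal) - nper) // step + 1

    times, rows = [], []
    for e in range(n_epochs):
        lo = e * step
        seg = signal[lo : lo + nper]
        if mask is not None and np.any(np.asarray(mask, bool)[lo : lo + nper]):
            continue
        f, pxx = periodogram(seg, fs=fs, window="hamming", scaling="density")
        df = f[1] - f[0]
        if not np.any(pxx > 0):
            raise EEGError(f"all-zero epoch at index {e}: log power undefined")
        row = []
        for lo_hz, hi_hz in BANDS.values():
            sel = (f >= lo_hz) & (f < hi_hz)
            bp = pxx[sel].sum() * df
            if bp <= 0:
                raise EEGError(f"zero in-band power at epoch {e}, band {lo_hz}-{hi_hz} Hz")
            row.append(np.log10(bp))
        times.append(lo / fs + epoch_len / 2)
        rows.append(row)
    return BandPowerSeries(epoch_times=np.asarray(times), log_power=np.asarray(rows))


def read_eeg_csv(path) -> tuple[np.ndarray, float]:
    """Load a single-channel recording from a two-column (time, value) CSV.

    The sampling rate is inferred from the time column, which must be
    uniformly spaced.
    """
    import pandas as pd

    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) < 1 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise EEGError("time column must be uniformly spaced")
    return df.iloc[:, 1].to_numpy(dtype=float), 1.0 / dt[0]


def read_eeg_raw(path, sidecar) -> tuple[np.ndarray, float]:
    """Load raw float64 samples with a JSON sidecar holding {"fs": Hz}."""
    import json
    from pathlib import Path

    meta = json.loads(Path(sidecar).read_text())
    return np.fromfile(path, dtype="<f8"), float(meta["fs"])


def resample_to_scans(bp: BandPowerSeries, tr: float, n_scans: int) -> np.ndarray:
    """Linear interpolation of each band at scan onset times (0, tr, 2*tr, ...).

    Values beyond the epoch grid are held constant at the edge value.
    Returns an n_scans x 6 matrix in the canonical band order.
    """
    if n_scans <= 0:
        raise EEGError("n_scans must be positive")
    scan_times = np.arange(n_scans) * tr
    out = np.column_stack(
        [np.interp(scan_times, bp.epoch_times, bp.log_power[:, j]) for j in range(bp.log_power.shape[1])]
    )
    return out
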