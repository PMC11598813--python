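"""Synthetic single-lead ECG beats and annotated records.

Every downstream stage (segmentation, imaging, training, folding, metrics)
is testable offline against this generator.  A beat is a sum of five
Gaussian bumps — P, Q, R, S and T waves — at 360 Hz, 300 samples long with
the R peak forced to index 100, plus white noise at 20 dB SNR.  Class
identity follows the AAMI five-class convention:

  N  normal morphology;
  S  supraventricular ectopic — normal morphology whose identity is carried
     by a shortened preceding RR interval (60% of nominal), expressed at
     record level;
  V  ventricular ectopic — widened QRS, absent P wave, inverted T;
  F  fusion — the average of the N and V morphologies;
  Q  unknown — morphology randomized per beat.

Amplitudes are in arbitrary units; the imaging stage normalizes per beat.
This is deliberately not a physiological simulator: it exists to give the
classifier five separable classes with the right data plumbing (annotated
R peaks, RR intervals, class labels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BEAT_CLASSES",
    "SyntheticRecord",
    "generate_beat",
    "generate_record",
    "write_record_csv",
    "read_record_csv",
]

BEAT_CLASSES = ("N", "S", "V", "F", "Q")

FS_DEFAULT = 360
BEAT_LEN = 300
R_INDEX = 100
NOMINAL_RR_S = 0.8          # nominal beat-to-beat interval, seconds
S_RR_FRACTION = 0.6         # preceding-RR shortening that marks an S beat
SNR_DB = 20.0
JITTER = 0.10               # +-10% seeded jitter on amplitudes and widths

# (amplitude, center offset from the R peak in samples, width in samples)
# per wave, per class.  Amplitude 0 removes the wave (V has no P wave).
_WAVES = ("P", "Q", "R", "S", "T")
_MORPHOLOGY = {
    "N": {"P": (0.15, -55, 8), "Q": (-0.12, -8, 3), "R": (1.00, 0, 4),
          "S": (-0.25, 8, 4), "T": (0.35, 70, 16)},
    "V": {"P": (0.00, -55, 8), "Q": (-0.05, -14, 6), "R": (0.95, 0, 11),
          "S": (-0.50, 14, 9), "T": (-0.30, 75, 18)},
}
_MORPHOLOGY["S"] = _MORPHOLOGY["N"]  # S identity lives in the RR interval
_MORPHOLOGY["F"] = {
    w: tuple((a + b) / 2 for a, b in zip(_MORPHOLOGY["N"][w], _MORPHOLOGY["V"][w]))
    for w in _WAVES
}


@dataclass
class SyntheticRecord:
    """An annotated synthetic record mirroring the structure of an
    ambulatory-ECG database record: a sample stream plus R-peak indices and
    one class label per peak."""

    samples: np.ndarray
    r_peaks: np.ndarray
    labels: list
    fs: int = FS_DEFAULT
    seed: int | None = None
    truncated: np.ndarray = field(default=None)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        if np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")
        if len(self.labels) != len(self.r_peaks):
            raise ValueError("one label per R peak required")
        for lab in self.labels:
            if lab not in BEAT_CLASSES:
                raise ValueError(f"unknown beat class {lab!r}")
        trunc = ~((self.r_peaks >= R_INDEX)
                  & (self.r_peaks + (BEAT_LEN - R_INDEX) <= len(self.samples)))
        self.truncated = trunc

    def __len__(self) -> int:
        return len(self.r_peaks)


def _beat_waveform(cls: str, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(BEAT_LEN, dtype=np.float64)
    if cls == "Q":
        # unknown class: draw a fresh morphology every beat
        params = {
            "P": (rng.uniform(-0.3, 0.3), -55 + rng.uniform(-15, 15),
                  rng.uniform(3, 20)),
            "Q": (rng.uniform(-0.3, 0.1), -10 + rng.uniform(-5, 5),
                  rng.uniform(2, 8)),
            "R": (rng.uniform(0.6, 1.2), 0.0, rng.uniform(2, 16)),
            "S": (rng.uniform(-0.6, 0.1), 10 + rng.uniform(-5, 5),
                  rng.uniform(2, 12)),
            "T": (rng.uniform(-0.5, 0.5), 70 + rng.uniform(-15, 15),
                  rng.uniform(6, 24)),
        }
    else:
        params = {}
        for w in _WAVES:
            amp, off, width = _MORPHOLOGY[cls][w]
            params[w] = (
                amp * (1 + rng.uniform(-JITTER, JITTER)),
                off + (0.0 if w == "R" else rng.uniform(-2, 2)),
                width * (1 + rng.uniform(-JITTER, JITTER)),
            )
    x = np.zeros(BEAT_LEN)
    for amp, off, width in params.values():
        if amp != 0.0:
            x += amp * np.exp(-0.5 * ((t - (R_INDEX + off)) / width) ** 2)
    rms = np.sqrt(np.mean(x**2))
    x += rng.normal(0.0, rms * 10 ** (-SNR_DB / 20), BEAT_LEN)
    # the R peak is the annotated argmax by construction; enforce it against
    # rare noise excursions
    if np.argmax(x) != R_INDEX:
        x[R_INDEX] = x.max() + 0.01
    return x


def generate_beat(cls: str, rng_seed: int, fs: int = FS_DEFAULT) -> np.ndarray:
    """One 300-sample beat of class `cls` with its R peak at index 100.

    Deterministic for a given (cls, rng_seed).  `fs` only scales nothing
    here (the template is defined in samples at 360 Hz) but is validated for
    interface symmetry with record generation.
    """
    if cls not in BEAT_CLASSES:
        raise ValueError(f"unknown beat class {cls!r}; expected one of {BEAT_CLASSES}")
    if fs <= 0:
        raise ValueError("fs must be positive")
    return _beat_waveform(cls, np.random.default_rng(rng_seed))


def generate_record(n_beats: int, class_mix, rng_seed: int,
                    fs: int = FS_DEFAULT) -> SyntheticRecord:
    """Concatenate `n_beats` beats into an annotated record.

    Beat classes are drawn from `class_mix` (probabilities over N,S,V,F,Q);
    RR gaps are the nominal 0.8 s with +-10% jitter, except that every S
    beat is preceded by a 60%-of-nominal gap.  Overlapping beat tails are
    summed onto the canvas.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    mix = np.asarray(class_mix, dtype=np.float64)
    if mix.shape != (5,):
        raise ValueError("class_mix must have 5 entries (N,S,V,F,Q)")
    if np.any(mix < 0):
        raise ValueError("class_mix entries must be nonnegative")
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    rng = np.random.default_rng(rng_seed)
    labels = [BEAT_CLASSES[i] for i in rng.choice(5, size=n_beats, p=mix)]

    nominal = int(round(NOMINAL_RR_S * fs))
    r_peaks = np.empty(n_beats, dtype=np.int64)
    pos = R_INDEX + 50
    for b, lab in enumerate(labels):
        if b > 0:
            if lab == "S":
                gap = int(round(S_RR_FRACTION * nominal))
            else:
                gap = int(round(nominal * (1 + rng.uniform(-0.1, 0.1))))
            pos += max(gap, 1)
        r_peaks[b] = pos

    samples = np.zeros(r_peaks[-1] + (BEAT_LEN - R_INDEX) + 50)
    for r, lab in zip(r_peaks, labels):
        beat = _beat_waveform(lab, np.random.default_rng(rng.integers(2**31)))
        samples[r - R_INDEX : r - R_INDEX + BEAT_LEN] += beat
    return SyntheticRecord(samples=samples, r_peaks=r_peaks, labels=labels,
                           fs=fs, seed=rng_seed)


def write_record_csv(record: SyntheticRecord, prefix) -> dict:
    """Plain-text export: <prefix>.samples.csv (sample_index,amplitude),
    <prefix>.annotations.csv (sample_index,label), <prefix>.header.json."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": prefix.with_suffix(".samples.csv"),
        "annotations": prefix.with_suffix(".annotations.csv"),
        "header": prefix.with_suffix(".header.json"),
    }
    with open(paths["samples"], "w") as fh:
        fh.write("sample_index,amplitude\n")
        for i, v in enumerate(record.samples):
            fh.write(f"{i},{v:.6f}\n")
    with open(paths["annotations"], "w") as fh:
        fh.write("sample_index,label\n")
        for r, lab in zip(record.r_peaks, record.labels):
            fh.write(f"{r},{lab}\n")
    with open(paths["header"], "w") as fh:
        json.dump({"fs": record.fs, "seed": record.seed,
                   "n_samples": len(record.samples),
                   "n_beats": len(record)}, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}


def read_record_csv(prefix) -> SyntheticRecord:
    """Read a record written by write_record_csv (round-trips annotations
    exactly; amplitudes to 1e-6)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".header.json")) as fh:
        header = json.load(fh)
    samples = np.loadtxt(prefix.with_suffix(".samples.csv"),
                         delimiter=",", skiprows=1, usecols=1)
    r_peaks, labels = [], []
    with open(prefix.with_suffix(".annotations.csv")) as fh:
        next(fh)
        for line in fh:
            idx, lab = line.strip().split(",")
            r_peaks.append(int(idx))
            labels.append(lab)
    return SyntheticRecord(samples=samples, r_peaks=np.array(r_peaks, dtype=np.int64),
                           labels=labels, fs=header["fs"], seed=header.get("seed"))
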