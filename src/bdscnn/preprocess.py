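"""From annotated records to model inputs.

Segmentation takes 300 samples around each annotated R peak (100 left, 200
right); peaks without that much context are skipped and counted.  Each beat
is rasterized to a binary image: the trace is drawn as a connected 1-px
polyline on a tall canvas (amplitude minimum at the bottom row) and
downscaled by block-max — any trace pixel in a block sets the output pixel —
which preserves thin traces that area-averaging would erase at 32 px.

The preceding RR interval rides along as an auxiliary feature: normalized by
the record's median RR and quantized to a 4-bit unsigned code (8 = nominal),
it is appended to the flattened image features at the FC1 input.

Class balancing uses z-score augmentation: a minority-class beat is z-scored
and re-expressed with a seeded perturbed mean and standard deviation,
x' = sigma' * z + mu'.  Validation and test partitions are never augmented.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .synthetic import BEAT_CLASSES, BEAT_LEN, R_INDEX

logger = logging.getLogger(__name__)

__all__ = [
    "Beat",
    "SplitSpec",
    "segment_beats",
    "beat_to_image",
    "rr_code",
    "zscore_augment",
    "split_dataset",
    "write_pgm",
]

CANVAS_H = 128  # rasterization canvas height before block-max downscale


@dataclass
class Beat:
    samples: np.ndarray           # exactly 300 amplitudes
    rr_prev: float                # seconds; median-RR fallback for first beats
    label: str
    record_id: str = "rec0"
    rr_missing: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.shape != (BEAT_LEN,):
            raise ValueError(f"a beat has exactly {BEAT_LEN} samples")
        if self.label not in BEAT_CLASSES:
            raise ValueError(f"unknown beat class {self.label!r}")
        if not self.rr_missing and not self.rr_prev > 0:
            raise ValueError("rr_prev must be positive unless marked missing")


@dataclass(frozen=True)
class SplitSpec:
    scheme: str = "patient_specific"        # or "patient_wise"
    fractions: tuple = (0.70, 0.09, 0.21)   # train, val, test of the whole
    rng_seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("patient_specific", "patient_wise"):
            raise ValueError("scheme must be patient_specific or patient_wise")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def segment_beats(record, record_id: str | None = None) -> list:
    """One Beat per usable annotated R peak of `record`.

    `record` needs .samples, .r_peaks, .labels and .fs (SyntheticRecord or a
    CSV-read record).  rr_prev comes from consecutive annotated peaks; the
    first beat gets the record's median RR and is marked missing.
    """
    r_peaks = np.asarray(record.r_peaks)
    if len(r_peaks) == 0:
        raise ValueError("record has no annotated R peaks")
    rid = record_id or f"rec{getattr(record, 'seed', 0)}"
    n = len(record.samples)
    rr = np.diff(r_peaks) / record.fs
    median_rr = float(np.median(rr)) if len(rr) else float("nan")

    beats, skipped = [], 0
    for b, (r, lab) in enumerate(zip(r_peaks, record.labels)):
        if r < R_INDEX or r + (BEAT_LEN - R_INDEX) > n:
            skipped += 1
            continue
        first = b == 0
        beats.append(Beat(
            samples=record.samples[r - R_INDEX : r + (BEAT_LEN - R_INDEX)],
            rr_prev=median_rr if first else float(rr[b - 1]),
            label=lab,
            record_id=rid,
            rr_missing=first and not np.isfinite(median_rr),
        ))
    if skipped:
        logger.info("segment_beats(%s): skipped %d peak(s) without full context",
                    rid, skipped)
    return beats


def beat_to_image(beat, side: int = 32) -> np.ndarray:
    """Rasterize a beat to a side x side {0,1} image.

    The 300 samples are scaled to rows 0..CANVAS_H-1 of a 300-column canvas
    (row 0 at the top, minimum amplitude at the bottom row), consecutive
    samples are joined by vertical 1-px runs, and the canvas is reduced to
    side x side by block-max.  Deterministic; a flat-line beat maps to a
    single row.
    """
    if side < 8:
        raise ValueError("side must be >= 8 (minimum feature resolution)")
    x = beat.samples if isinstance(beat, Beat) else np.asarray(beat, dtype=np.float64)
    if x.shape != (BEAT_LEN,):
        raise ValueError(f"a beat has exactly {BEAT_LEN} samples")
    lo, hi = x.min(), x.max()
    if hi > lo:
        rows = np.rint((hi - x) / (hi - lo) * (CANVAS_H - 1)).astype(np.int64)
    else:
        rows = np.full(BEAT_LEN, CANVAS_H - 1, dtype=np.int64)  # flat line

    canvas = np.zeros((CANVAS_H, BEAT_LEN), dtype=np.uint8)
    canvas[rows, np.arange(BEAT_LEN)] = 1
    # join consecutive samples with a vertical run so the trace is connected
    for c in range(BEAT_LEN - 1):
        r0, r1 = sorted((rows[c], rows[c + 1]))
        canvas[r0 : r1 + 1, c] = 1

    row_bin = np.minimum(np.arange(CANVAS_H) * side // CANVAS_H, side - 1)
    col_bin = np.minimum(np.arange(BEAT_LEN) * side // BEAT_LEN, side - 1)
    img = np.zeros((side, side), dtype=np.uint8)
    np.maximum.at(img, (row_bin[:, None], col_bin[None, :]), canvas)
    return img


def rr_code(rr_prev: float, median_rr: float, bits: int = 4) -> np.ndarray:
    """Quantize rr_prev / median_rr to an unsigned `bits`-bit code (8 = nominal
    at 4 bits), returned MSB-first as 0/1 features."""
    if median_rr <= 0 or not np.isfinite(median_rr):
        ratio = 1.0
    else:
        ratio = rr_prev / median_rr
    code = int(np.clip(np.rint(ratio * (1 << (bits - 1))), 0, (1 << bits) - 1))
    return np.array([(code >> (bits - 1 - b)) & 1 for b in range(bits)],
                    dtype=np.uint8)


def zscore_augment(beats, target_per_class: int, rng_seed: int = 0) -> list:
    """Grow each under-represented class to `target_per_class` beats.

    New beats are x' = sigma' * z + mu' with z the z-scored source beat,
    mu' ~ U(mu +- 0.1 sigma) and sigma' ~ U(0.9, 1.1) * sigma.  Originals are
    kept unmodified; classes at or above target are left alone (never
    subsampled).  Requires at least one source beat per class present.
    """
    rng = np.random.default_rng(rng_seed)
    by_class: dict[str, list] = {}
    for b in beats:
        by_class.setdefault(b.label, []).append(b)
    out = list(beats)
    for cls, members in sorted(by_class.items()):
        need = target_per_class - len(members)
        for i in range(max(need, 0)):
            src = members[int(rng.integers(len(members)))]
            mu, sigma = src.samples.mean(), src.samples.std()
            if sigma == 0:
                out.append(replace(src))
                continue
            z = (src.samples - mu) / sigma
            mu_p = mu + rng.uniform(-0.1, 0.1) * sigma
            sigma_p = sigma * rng.uniform(0.9, 1.1)
            out.append(replace(src, samples=sigma_p * z + mu_p))
    return out


def _split_sizes(n: int, fractions) -> tuple[int, int, int]:
    # 70% train, then 30% / 70% of the remainder to val / test
    f_train = fractions[0]
    n_train = int(round(f_train * n))
    rest = n - n_train
    n_val = int(round(fractions[1] / (fractions[1] + fractions[2]) * rest))
    return n_train, n_val, rest - n_val


def split_dataset(beats, spec: SplitSpec):
    """(train, val, test) partitions of `beats` under `spec`.

    patient_specific: the split is drawn independently inside every
    record_id (70/9/21 net with default fractions).  patient_wise: whole
    record_ids go to exactly one partition, filled greedily to the beat
    fractions in seeded shuffle order.  Deterministic given the spec.
    """
    beats = list(beats)
    if not beats:
        raise ValueError("no beats to split")
    rng = np.random.default_rng(spec.rng_seed)
    by_record: dict[str, list[int]] = {}
    for idx, b in enumerate(beats):
        by_record.setdefault(b.record_id, []).append(idx)

    train_idx, val_idx, test_idx = [], [], []
    if spec.scheme == "patient_specific":
        for rid in sorted(by_record):
            idxs = np.array(by_record[rid])
            if len(idxs) < 2:
                warnings.warn(f"record {rid}: fewer than 2 beats, all to train")
                train_idx.extend(idxs.tolist())
                continue
            rng.shuffle(idxs)
            n_tr, n_va, _ = _split_sizes(len(idxs), spec.fractions)
            train_idx.extend(idxs[:n_tr].tolist())
            val_idx.extend(idxs[n_tr : n_tr + n_va].tolist())
            test_idx.extend(idxs[n_tr + n_va :].tolist())
    else:  # patient_wise
        rids = sorted(by_record)
        rng.shuffle(rids)
        total = len(beats)
        quota_train = spec.fractions[0] * total
        quota_val = (spec.fractions[0] + spec.fractions[1]) * total
        placed = 0
        for rid in rids:
            idxs = by_record[rid]
            if placed < quota_train:
                train_idx.extend(idxs)
            elif placed < quota_val:
                val_idx.extend(idxs)
            else:
                test_idx.extend(idxs)
            placed += len(idxs)

    return ([beats[i] for i in sorted(train_idx)],
            [beats[i] for i in sorted(val_idx)],
            [beats[i] for i in sorted(test_idx)])


def write_pgm(image: np.ndarray, path) -> None:
    """Binary image as plain-text PGM (P2) for eyeballing."""
    image = np.asarray(image)
    with open(path, "w") as fh:
        fh.write(f"P2\n{image.shape[1]} {image.shape[0]}\n1\n")
        for row in image:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
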