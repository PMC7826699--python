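"""Core data types and I/O for electronic-nose response samples.

An e-nose recording is a matrix of S sensor channels by T time points
(metal-oxide sensor conductivity ratios sampled at a fixed interval).
This module holds the sample/dataset containers, the per-sensor
zero-center normalization applied before modeling, plain-text readers
and writers, and seeded stratified splitting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

#: Sensor names of a 10-channel metal-oxide array (the usual PEN-3 layout).
DEFAULT_SENSOR_NAMES = (
    "W1C", "W5S", "W3C", "W6S", "W5C", "W1S", "W1W", "W2S", "W2W", "W3S",
)


class InvalidDataError(ValueError):
    """A sample contains non-finite or otherwise invalid values."""


class FormatError(ValueError):
    """An on-disk sample file or manifest violates the expected format."""


class StratificationError(ValueError):
    """A dataset cannot be stratified (some class has fewer than 2 samples)."""


@dataclass
class ResponseSample:
    """One e-nose recording: ``values`` is S (sensors) x T (time points).

    The canonical in-memory orientation is sensor-major (S x T); the
    on-disk format is time-major (T rows x S columns) for readability,
    and readers/writers transpose.
    """

    values: np.ndarray
    sensor_names: tuple[str, ...] = DEFAULT_SENSOR_NAMES
    sample_interval_s: float = 1.0
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sensor_names = tuple(self.sensor_names)
        if self.values.ndim != 2:
            raise InvalidDataError("sample values must be a 2-D matrix")
        s, t = self.values.shape
        if s < 1 or t < 2:
            raise InvalidDataError(f"need S >= 1 sensors and T >= 2 points, got {s}x{t}")
        if len(self.sensor_names) != s:
            raise InvalidDataError(
                f"{len(self.sensor_names)} sensor names for {s} sensor rows"
            )
        if len(set(self.sensor_names)) != len(self.sensor_names):
            raise InvalidDataError("duplicate sensor names")
        if self.sample_interval_s <= 0:
            raise InvalidDataError("sample_interval_s must be positive")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise InvalidDataError(
                f"non-finite value at sensor {self.sensor_names[i]!r}, index {j}"
            )

    @property
    def n_sensors(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizedSample(ResponseSample):
    """A zero-centered sample plus the per-sensor (mean, max, min) used.

    Each sensor row of a valid instance sums to ~0 and lies in [-1, 1].
    """

    #: per-sensor (mean, max, min) of the original trace, shape (S, 3)
    norm_stats: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))


@dataclass
class OdorDataset:
    """Ordered collection of samples sharing shape, sensors and class vocabulary."""

    samples: list[ResponseSample]
    class_names: list[str]

    def __post_init__(self) -> None:
        self.class_names = list(self.class_names)
        if len(set(self.class_names)) != len(self.class_names):
            raise InvalidDataError("duplicate class names")
        known = set(self.class_names)
        for k, s in enumerate(self.samples):
            if s.label not in known:
                raise InvalidDataError(f"sample {k} label {s.label!r} not in class_names")
        if self.samples:
            ref = self.samples[0]
            for k, s in enumerate(self.samples):
                if s.values.shape != ref.values.shape:
                    raise InvalidDataError(
                        f"sample {k} shape {s.values.shape} != {ref.values.shape}"
                    )
                if s.sensor_names != ref.sensor_names:
                    raise InvalidDataError(f"sample {k} sensor names differ")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_sensors(self) -> int:
        return self.samples[0].n_sensors

    @property
    def n_timepoints(self) -> int:
        return self.samples[0].n_timepoints

    def labels(self) -> np.ndarray:
        """Integer label vector indexed into ``class_names``."""
        index = {c: i for i, c in enumerate(self.class_names)}
        return np.array([index[s.label] for s in self.samples], dtype=int)

    def values_array(self) -> np.ndarray:
        """Stacked values, shape (n_samples, S, T)."""
        return np.stack([s.values for s in self.samples])


def zero_center(sample: ResponseSample) -> NormalizedSample:
    """Zero-center each sensor row: (x - mean(row)) / (max(row) - min(row)).

    The statistics are computed per sensor, per sample, over that sensor's
    T points.  A constant row (max == min) carries no discriminative signal
    and is mapped to zeros rather than dividing by zero.
    """
    x = sample.values
    mean = x.mean(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    lo = x.min(axis=1, keepdims=True)
    rng = hi - lo
    out = np.zeros_like(x)
    nonconst = (rng > 0).ravel()
    out[nonconst] = (x[nonconst] - mean[nonconst]) / rng[nonconst]
    stats = np.column_stack([mean.ravel(), hi.ravel(), lo.ravel()])
    return NormalizedSample(
        values=out,
        sensor_names=sample.sensor_names,
        sample_interval_s=sample.sample_interval_s,
        label=sample.label,
        norm_stats=stats,
    )


def zero_center_dataset(dataset: OdorDataset) -> OdorDataset:
    """Apply :func:`zero_center` to every sample."""
    return OdorDataset(
        samples=[zero_center(s) for s in dataset.samples],
        class_names=list(dataset.class_names),
    )


# ---------------------------------------------------------------------------
# On-disk format: one delimited text file per sample (header of sensor names,
# then T rows x S columns), plus a manifest with columns file,label and an
# optional "#classes:" directive fixing class order.

_FLOAT_FMT = "%.17g"  # full double precision so read(write(d)) == d exactly


def _detect_delim(line: str) -> str:
    return "\t" if "\t" in line else ","


def _read_sample_file(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty sample file")
    delim = _detect_delim(lines[0])
    names = tuple(tok.strip() for tok in lines[0].split(delim))
    n_cols = len(names)
    rows = []
    for ln_no, ln in enumerate(lines[1:], start=2):
        toks = ln.split(delim)
        if len(toks) != n_cols:
            raise FormatError(
                f"{path}: line {ln_no}: expected {n_cols} columns, got {len(toks)}"
            )
        try:
            rows.append([float(t) for t in toks])
        except ValueError as e:
            raise FormatError(f"{path}: line {ln_no}: {e}") from None
    if len(rows) < 2:
        raise FormatError(f"{path}: need at least 2 time points, got {len(rows)}")
    return np.asarray(rows, dtype=float).T, names  # transpose to S x T


def read_dataset(manifest_path: str | os.PathLike) -> OdorDataset:
    """Read a dataset from a manifest of ``file<delim>label`` lines.

    Class order follows an optional ``#classes:`` directive, else first
    appearance in the manifest.  Sample files are resolved relative to the
    manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    declared: list[str] | None = None
    entries: list[tuple[str, str]] = []
    with open(manifest_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = [ln for ln in lines if ln.strip()]
    for ln_no, ln in enumerate(body, start=1):
        if ln.startswith("#classes:"):
            declared = [c.strip() for c in ln[len("#classes:"):].split(",") if c.strip()]
            continue
        if ln.startswith("#"):
            continue
        delim = _detect_delim(ln)
        toks = [t.strip() for t in ln.split(delim)]
        if len(toks) != 2:
            raise FormatError(
                f"{manifest_path}: line {ln_no}: expected 'file{delim}label'"
            )
        if toks == ["file", "label"]:  # optional header row
            continue
        entries.append((toks[0], toks[1]))

    samples: list[ResponseSample] = []
    class_names: list[str] = list(declared) if declared else []
    expected_shape: tuple[int, int] | None = None
    for fname, label in entries:
        values, names = _read_sample_file(base / fname)
        if expected_shape is None:
            expected_shape = values.shape
        elif values.shape != expected_shape:
            raise FormatError(
                f"{base / fname}: shape {values.shape[::-1]} (rows x cols) does not "
                f"match first sample {expected_shape[::-1]}"
            )
        if declared is not None and label not in declared:
            raise FormatError(
                f"{manifest_path}: label {label!r} not in declared classes {declared}"
            )
        if label not in class_names:
            class_names.append(label)
        samples.append(ResponseSample(values=values, sensor_names=names, label=label))
    return OdorDataset(samples=samples, class_names=class_names)


def write_dataset(dataset: OdorDataset, dir_path: str | os.PathLike) -> Path:
    """Write one file per sample plus a manifest; inverse of :func:`read_dataset`.

    Returns the manifest path.  Values are written at full double precision
    so the round trip is exact.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(max(len(dataset.samples) - 1, 0))))
    manifest = dir_path / "manifest.csv"
    lines = []
    if dataset.class_names:
        lines.append("#classes: " + ",".join(dataset.class_names))
    lines.append("file,label")
    for k, s in enumerate(dataset.samples):
        fname = f"sample_{k:0{width}d}.csv"
        with open(dir_path / fname, "w") as fh:
            fh.write(",".join(s.sensor_names) + "\n")
            for row in s.values.T:  # time-major on disk
                fh.write(",".join(_FLOAT_FMT % v for v in row) + "\n")
        lines.append(f"{fname},{s.label}")
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def stratified_split(
    dataset: OdorDataset, test_fraction: float, seed: int
) -> tuple[OdorDataset, OdorDataset]:
    """Split into (train, test) preserving per-class proportions.

    Deterministic given ``seed``; disjoint and exhaustive.  Every class must
    have at least 2 samples.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    y = dataset.labels()
    counts = np.bincount(y, minlength=len(dataset.class_names))
    thin = [c for c, n in zip(dataset.class_names, counts) if n < 2]
    if thin:
        raise StratificationError(f"classes with < 2 samples: {thin}")
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    mk = lambda ix: OdorDataset(
        samples=[dataset.samples[i] for i in sorted(ix)],
        class_names=list(dataset.class_names),
    )
    return mk(train_idx), mk(test_idx)
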